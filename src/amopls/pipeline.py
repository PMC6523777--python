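"""One reproducible run: preprocess → decompose → fit → test → VIP² → enrich.

``run(config)`` executes every stage on files named in a :class:`RunConfig`,
writes each stage's tables under the output directory and finishes with a
JSON manifest (seed, thresholds, stage shapes, SHA-256 of every artifact) so
a run can be replayed and diffed byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import anova, enrichment, inference, mbopls, preprocess
from .io import (
    read_design,
    read_feature_table,
    read_gmt,
    write_feature_table,
    write_json,
)

__all__ = ["RunConfig", "run", "StageError"]


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name it happened in."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run (YAML round-trippable)."""

    feature_tables: list[str] = field(default_factory=list)
    platform_labels: list[str] = field(default_factory=list)
    design: str = ""
    proteins: str = ""  # optional TSV: protein_id, fold_change, p_value
    gmt: str = ""  # optional pathway sets
    out_dir: str = "run"
    qc_pattern: str = "QC"
    cv_threshold: float = 0.35
    vip2_threshold: float = 1.1
    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    vip_effect: str = "Concentration"
    uv_scaling: bool = True
    n_perm: int = 10_000
    n_ortho: int = 1
    seed: int = 0

    def __post_init__(self):
        for name in ("cv_threshold", "vip2_threshold", "fc_threshold", "p_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "files": {},
    }
    t0 = time.time()

    def stage(name):
        manifest["stages"][name] = {"t_start_s": round(time.time() - t0, 3)}
        return name

    s = stage("io_core")
    try:
        if not config.feature_tables:
            raise ValueError("no feature tables configured")
        labels = config.platform_labels or [""] * len(config.feature_tables)
        tables = [
            read_feature_table(p, platform_label=lab, qc_pattern=config.qc_pattern)
            for p, lab in zip(config.feature_tables, labels)
        ]
        design = read_design(config.design)
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(s, e) from e

    s = stage("preprocess")
    try:
        filtered = []
        reports = []
        for t in tables:
            ft, rep = preprocess.qc_cv_filter(t, config.cv_threshold)
            filtered.append(ft)
            reports.append(rep)
        merged, dup_report = preprocess.resolve_duplicates(filtered)
        merged = merged.reorder_samples(design.sample_ids)
        if config.uv_scaling:
            merged, _scale = preprocess.uv_scale(merged)
        write_feature_table(merged, out / "merged.tsv")
        write_json(
            {
                "cv_filter": [
                    {"before": r.counts_before, "after": r.counts_after}
                    for r in reports
                ],
                "duplicates": dup_report.duplicate_log,
            },
            out / "preprocess_report.json",
        )
    except Exception as e:
        raise StageError(s, e) from e

    s = stage("decompose")
    try:
        X = merged.biological().values
        decomp = anova.decompose(X, design)
        write_json(decomp.ss, out / "ss.json")
    except Exception as e:
        raise StageError(s, e) from e

    s = stage("fit")
    try:
        blocks = mbopls.build_blocks(decomp)
        Y = mbopls.build_dummy_response(design)
        model = mbopls.fit(blocks, Y, n_ortho=config.n_ortho)
        model.saliences.to_csv(out / "saliences.tsv", sep="\t")
    except Exception as e:
        raise StageError(s, e) from e

    s = stage("test")
    try:
        report = inference.effect_report(
            X, design, n_ortho=config.n_ortho, n_perm=config.n_perm, seed=config.seed
        )
        report.to_csv(out / "effect_report.tsv", sep="\t")
    except Exception as e:
        raise StageError(s, e) from e

    s = stage("vip")
    try:
        vt = inference.vip_table(model)
        vt.index = merged.feature_ids
        vt.to_csv(out / "vip2.tsv", sep="\t")
        selected = inference.select_features(
            vt, config.vip_effect, config.vip2_threshold
        )
        fid_to_ann = dict(zip(merged.feature_ids, merged.annotation))
        (out / "selected_metabolites.txt").write_text(
            "".join(f"{f}\t{fid_to_ann[f]}\n" for f in selected)
        )
    except Exception as e:
        raise StageError(s, e) from e

    s = stage("enrich")
    try:
        if config.proteins and config.gmt:
            import pandas as pd

            pt_df = pd.read_csv(config.proteins, sep=None, engine="python")
            from .io import ProteinTable

            pt = ProteinTable(
                pt_df.iloc[:, 0].astype(str).tolist(),
                pt_df.iloc[:, 1].to_numpy(float),
                pt_df.iloc[:, 2].to_numpy(float),
            )
            prot_hits = set(
                enrichment.select_proteins(pt, config.fc_threshold, config.p_threshold)
            )
            maps = read_gmt(config.gmt)
            metab_hits = {fid_to_ann[f] for f in selected if fid_to_ann[f]}
            metab_universe = {a for a in merged.annotation if a}
            prot_universe = set(pt.protein_ids)
            metab_res = enrichment.ora(metab_hits, metab_universe, maps)
            prot_res = enrichment.ora(prot_hits, prot_universe, maps)
            joint = enrichment.joint_table(metab_res, prot_res, top_n=10)
            joint.to_csv(out / "joint_enrichment.tsv", sep="\t")
        else:
            manifest["stages"][s]["skipped"] = "no proteins/gmt configured"
    except Exception as e:
        raise StageError(s, e) from e

    for f in sorted(out.glob("*")):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    manifest["wall_time_s"] = round(time.time() - t0, 3)
    manifest["versions"] = {"numpy": np.__version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return out
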