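"""Synthetic multifactorial, multi-platform datasets for the whole pipeline.

The generator emulates the structure of the reference study: a balanced
2 (maturation) × 2 (exposure duration) × 3 (toxicant concentration) design
with 3 replicates (36 biological samples), four LC-MS platform tables with
33/36/58/62 annotated features (189 total), pooled-QC re-injections with a
controllable CV distribution, plus a proteomics fold-change table and GMT
pathway sets with a planted signal.

Each modeled term gets a cell-constant random pattern, purified by the same
design projections the ANOVA step uses, so generator and decomposer agree on
what "the Maturation effect" is by construction. In calibration mode the
per-term patterns and the (residual-space-projected) noise are rescaled so
the realized SS fractions equal the requested targets exactly; when every
feature is responsive to every term the calibration is applied per feature
column, which additionally makes the fractions invariant under unit-variance
scaling and under dropping features.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .anova import effect_projections
from .io import FeatureTable, PathwaySet, ProteinTable, StudyDesign, term_label

__all__ = [
    "SyntheticSpec",
    "default_fractions",
    "generate",
    "generate_design",
    "generate_qc_stress_table",
    "generate_proteins",
    "generate_pathways",
]

DEFAULT_FACTORS = {
    "Maturation": ["immature", "mature"],
    "Exposure": ["24h", "10d"],
    "Concentration": ["0.0", "0.5", "1.0"],
}
DEFAULT_PLATFORMS = {"RPLC+": 33, "RPLC-": 36, "HILIC+": 58, "HILIC-": 62}


def default_fractions() -> dict[str, float]:
    """Per-term variance-fraction targets (percent) used as default calibration.

    The reference study's printed fractions (22.3, 15.3, 6.3, 13.5, 2.1,
    3.8 and residual 36.6) are rounded to one decimal and sum to 99.9%;
    exact calibration needs targets summing to 100, so the 0.1-point
    rounding deficit is spread equally over the seven terms (each target
    moves by 1/70 of a point, well inside the printed precision).
    """
    printed = {
        "Maturation": 22.3,
        "Exposure": 15.3,
        "Concentration": 6.3,
        "Maturation×Exposure": 13.5,
        "Maturation×Concentration": 2.1,
        "Exposure×Concentration": 3.8,
    }
    adj = (100.0 - (sum(printed.values()) + 36.6)) / 7.0
    return {k: v + adj for k, v in printed.items()}


@dataclass
class SyntheticSpec:
    """Everything that determines one synthetic dataset; ``seed`` fixes all
    randomness (two runs with the same spec are bit-identical)."""

    factors: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_FACTORS))
    replicates: int = 3
    platform_features: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORMS)
    )
    effects: list[tuple[str, ...]] = field(default_factory=list)
    effect_fractions: dict[str, float] = field(default_factory=default_fractions)
    responsive: dict[str, int] = field(default_factory=dict)  # term -> #features
    calibrate: bool = True
    effect_scale: float = 1.0  # per-term pattern amplitude when not calibrating
    noise_scale: float = 1.0
    n_qc: int = 8
    qc_cv_median: float = 0.10
    qc_cv_sigma: float = 0.4
    baseline_log_mean: float = float(np.log(1e5))
    baseline_log_sd: float = 1.0
    biological_cv: float = 0.2  # per-feature biological variation (per-feature mode)
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        fr = self.effect_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("variance fractions must be non-negative")
        if sum(fr.values()) > 100 + 1e-9:
            raise ValueError("variance fractions sum above 100%")

    @property
    def n_features(self) -> int:
        return sum(self.platform_features.values())

    @property
    def n_samples(self) -> int:
        n = self.replicates
        for lv in self.factors.values():
            n *= len(lv)
        return n


def generate_design(spec: SyntheticSpec) -> StudyDesign:
    names = list(spec.factors)
    cells = list(itertools.product(*(spec.factors[f] for f in names)))
    rows = [
        (cell, r) for cell in cells for r in range(1, spec.replicates + 1)
    ]
    width = len(str(len(rows)))
    sample_ids = [f"S{i+1:0{width}d}" for i in range(len(rows))]
    factors = {
        f: [cell[k] for cell, _ in rows] for k, f in enumerate(names)
    }
    return StudyDesign(sample_ids, factors, list(spec.effects))


def _pure_term_pattern(
    design: StudyDesign, term: tuple[str, ...], cols: np.ndarray, p: int, rng
) -> np.ndarray:
    """Cell-constant random pattern for one term, projected to the term's own
    subspace (grand mean and parent mains removed)."""
    codes, k = design.term_codes(term)
    raw = np.zeros((design.n_samples, p))
    raw[:, cols] = rng.standard_normal((k, cols.size))[codes]
    mains = [(f,) for f in term]
    proj = effect_projections(raw - raw.mean(axis=0), design, mains + ([term] if len(term) > 1 else []))
    return proj[term]


def generate(
    spec: SyntheticSpec, return_truth: bool = False
) -> tuple[dict[str, FeatureTable], StudyDesign] | tuple[
    dict[str, FeatureTable], StudyDesign, dict
]:
    """Per-platform feature tables (with QC rows appended) and the design.

    With ``return_truth=True`` a third element carries the ground truth of the
    simulation: the per-term responsive feature indices (keyed by term label,
    indices into the concatenated feature order) — the reference for
    feature-recovery benchmarks.
    """
    rng = np.random.default_rng(spec.seed)
    design = generate_design(spec)
    n, p = design.n_samples, spec.n_features

    term_cols: dict[str, np.ndarray] = {}
    per_feature_mode = True
    for term in design.effects:
        label = term_label(term)
        n_resp = spec.responsive.get(label)
        frac = spec.effect_fractions.get(label, 0.0)
        if n_resp is None:
            term_cols[label] = np.arange(p)
        else:
            if n_resp == 0 and frac > 0:
                raise ValueError(
                    f"target fraction {frac}% for {label} with zero responsive features"
                )
            term_cols[label] = rng.choice(p, size=n_resp, replace=False)
            per_feature_mode = False

    mats: dict[str, np.ndarray] = {}
    for term in design.effects:
        label = term_label(term)
        frac = spec.effect_fractions.get(label, 0.0)
        if spec.calibrate and frac == 0:
            continue
        M = _pure_term_pattern(design, term, term_cols[label], p, rng)
        if not spec.calibrate:
            M *= spec.effect_scale
        mats[label] = M

    E = rng.standard_normal((n, p)) * spec.noise_scale

    if spec.calibrate:
        # confine the noise to the residual subspace, then hit the targets exactly
        Ec = E - E.mean(axis=0)
        leak = effect_projections(Ec, design)
        for M in leak.values():
            Ec = Ec - M
        E = Ec
        resid_frac = 100.0 - sum(
            spec.effect_fractions.get(term_label(t), 0.0) for t in design.effects
        )
        if per_feature_mode:
            unit = design.n_samples - 1  # per-column total SS -> unit variance
            for label, M in mats.items():
                target = spec.effect_fractions[label] / 100.0 * unit
                ss = np.sum(M * M, axis=0)
                if (ss < 1e-30).any():
                    raise ValueError(f"degenerate pattern draw for {label}")
                M *= np.sqrt(target / ss)[None, :]
            ss = np.sum(E * E, axis=0)
            E *= np.sqrt(resid_frac / 100.0 * unit / ss)[None, :]
        else:
            total = p * (design.n_samples - 1)
            for label, M in mats.items():
                ss = float(np.sum(M * M))
                if ss < 1e-30:
                    raise ValueError(f"degenerate pattern draw for {label}")
                M *= np.sqrt(spec.effect_fractions[label] / 100.0 * total / ss)
            E *= np.sqrt(resid_frac / 100.0 * total / float(np.sum(E * E)))

    S = E.copy()
    for M in mats.values():
        S += M

    baseline = np.exp(
        rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=p)
    )
    if spec.calibrate and per_feature_mode:
        amp = spec.biological_cv * baseline  # S columns have unit variance
        X = baseline[None, :] + amp[None, :] * S
    else:
        X = baseline[None, :] + S

    # pooled-QC re-injections around the pool mean with lognormal CVs
    cv = np.exp(rng.normal(np.log(spec.qc_cv_median), spec.qc_cv_sigma, size=p))
    qc = baseline[None, :] * (
        1.0 + cv[None, :] * rng.standard_normal((spec.n_qc, p))
    )
    qc_ids = [f"QC{i+1:02d}" for i in range(spec.n_qc)]

    tables: dict[str, FeatureTable] = {}
    start = 0
    feat_no = 0
    for plat, count in spec.platform_features.items():
        cols = np.arange(start, start + count)
        start += count
        fids = []
        anns = []
        for _ in range(count):
            feat_no += 1
            fids.append(f"feat_{feat_no:04d}")
            anns.append(f"met_{feat_no:04d}")
        tables[plat] = FeatureTable(
            design.sample_ids + qc_ids,
            fids,
            np.vstack([X[:, cols], qc[:, cols]]),
            np.array([plat] * count, dtype=object),
            np.array(anns, dtype=object),
            np.array([False] * n + [True] * spec.n_qc),
        )
    if return_truth:
        truth = {"responsive": {k: np.sort(v) for k, v in term_cols.items()}}
        return tables, design, truth
    return tables, design


def generate_qc_stress_table(
    n_features: int = 2000,
    frac_unstable: float = 0.9,
    cv_stable: float = 0.05,
    cv_unstable: float = 1.2,
    n_qc: int = 8,
    n_bio: int = 12,
    seed: int = 0,
) -> FeatureTable:
    """Unfiltered-style table where ~``frac_unstable`` of features have QC CVs
    far above the 35% cut (emulates a raw peak table before repeatability
    filtering)."""
    rng = np.random.default_rng(seed)
    unstable = rng.random(n_features) < frac_unstable
    cv = np.where(unstable, cv_unstable, cv_stable)
    baseline = np.exp(rng.normal(np.log(1e5), 1.0, size=n_features))
    bio = baseline[None, :] * np.exp(rng.normal(0, 0.2, size=(n_bio, n_features)))
    qc = baseline[None, :] * (
        1.0 + cv[None, :] * rng.standard_normal((n_qc, n_features))
    )
    ids = [f"feat_{j+1:05d}" for j in range(n_features)]
    samples = [f"S{i+1:02d}" for i in range(n_bio)] + [
        f"QC{i+1:02d}" for i in range(n_qc)
    ]
    return FeatureTable(
        samples,
        ids,
        np.vstack([bio, qc]),
        np.array(["RPLC+"] * n_features, dtype=object),
        np.array([""] * n_features, dtype=object),
        np.array([False] * n_bio + [True] * n_qc),
    )


def generate_proteins(
    n: int = 2422,
    n_regulated: int = 50,
    fc_range: tuple[float, float] = (1.5, 3.0),
    seed: int = 0,
) -> ProteinTable:
    """Fold-change table with ``n_regulated`` truly regulated proteins.

    Regulated proteins get |log FC| uniform in ``log(fc_range)`` with random
    sign and small p-values; the rest sit near FC 1 with uniform p-values, so
    in expectation only the regulated ones pass the FC>1.2 & p<0.05 rule.
    """
    if n_regulated > n:
        raise ValueError("n_regulated exceeds n")
    rng = np.random.default_rng(seed)
    ids = [f"prot_{j+1:04d}" for j in range(n)]
    fc = np.exp(rng.normal(0.0, 0.05, size=n))
    p = rng.uniform(0.0, 1.0, size=n)
    reg = rng.choice(n, size=n_regulated, replace=False)
    lo, hi = np.log(fc_range[0]), np.log(fc_range[1])
    sign = rng.choice([-1.0, 1.0], size=n_regulated)
    fc[reg] = np.exp(sign * rng.uniform(lo, hi, size=n_regulated))
    p[reg] = 10.0 ** rng.uniform(-6.0, -2.0, size=n_regulated)
    return ProteinTable(ids, fc, p)


def generate_pathways(
    universe: list[str],
    hits: set[str],
    n_maps: int = 20,
    planted_map_size: int = 20,
    overlap: float = 0.6,
    map_size: int = 20,
    seed: int = 0,
) -> PathwaySet:
    """Random pathway maps plus one map ("planted") enriched in ``hits``.

    ``overlap`` is the fraction of the planted map drawn from the hit set;
    the remaining maps are uniform draws from the universe.
    """
    if planted_map_size > len(universe):
        raise ValueError("planted map larger than the universe")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    pathways: dict[str, set[str]] = {}
    for m in range(n_maps):
        members = rng.choice(universe, size=min(map_size, len(universe)), replace=False)
        pathways[f"map_{m+1:02d}"] = set(members.tolist())
    hit_list = sorted(hits)
    n_hit = min(int(round(overlap * planted_map_size)), len(hit_list))
    chosen = set(rng.choice(hit_list, size=n_hit, replace=False).tolist())
    non_hits = [u for u in universe if u not in hits]
    filler = rng.choice(non_hits, size=planted_map_size - n_hit, replace=False)
    pathways["planted"] = chosen | set(filler.tolist())
    return PathwaySet("synthetic", pathways)
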