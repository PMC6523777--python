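"""Shared data model and tabular I/O.

The workflow moves four kinds of objects between stages: intensity matrices
with per-feature platform/annotation metadata (:class:`FeatureTable`), the
experimental design (:class:`StudyDesign`), a proteomics fold-change table
(:class:`ProteinTable`) and pathway membership sets (:class:`PathwaySet`).
All of them are read and written as plain delimited text (TSV on output,
tab or comma accepted on input) or GMT, so every intermediate artifact of a
run stays human-inspectable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "StudyDesign",
    "ProteinTable",
    "PathwaySet",
    "term_label",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "write_design",
    "read_gmt",
    "write_gmt",
    "write_json",
]


def term_label(term: tuple[str, ...]) -> str:
    """Canonical printed name of a model term, e.g. ``Maturation×Exposure``."""
    return "×".join(term)


@dataclass
class FeatureTable:
    """Samples × features intensity matrix with feature/sample metadata.

    Parameters
    ----------
    sample_ids, feature_ids
        Ordered unique identifiers for rows and columns.
    values
        ``(n_samples, n_features)`` array of normalized intensities.
        Missing or non-finite values are rejected: the downstream model has
        no missing-data handling.
    platform
        Per-feature analytical platform label (e.g. ``RPLC+``).
    annotation
        Per-feature metabolite name; empty string for unannotated features.
    is_qc
        Per-sample flag marking pooled-QC re-injections.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    platform: np.ndarray
    annotation: np.ndarray
    is_qc: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.platform = np.asarray(self.platform, dtype=object)
        self.annotation = np.asarray(self.annotation, dtype=object)
        self.is_qc = np.asarray(self.is_qc, dtype=bool)
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} rows of values"
            )
        if len(self.feature_ids) != p:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {p} columns of values"
            )
        for name, arr, m in (
            ("platform", self.platform, p),
            ("annotation", self.annotation, p),
            ("is_qc", self.is_qc, n),
        ):
            if arr.shape != (m,):
                raise ValueError(f"{name} must have length {m}, got {arr.shape}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicated sample id: {dup!r}")
        dup = _first_duplicate(self.feature_ids)
        if dup is not None:
            raise ValueError(f"duplicated feature id: {dup!r}")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[i]!r}, feature {self.feature_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def biological(self) -> "FeatureTable":
        """Table restricted to non-QC samples."""
        keep = ~self.is_qc
        return FeatureTable(
            [s for s, k in zip(self.sample_ids, keep) if k],
            list(self.feature_ids),
            self.values[keep],
            self.platform,
            self.annotation,
            np.zeros(int(keep.sum()), dtype=bool),
        )

    def subset_features(self, idx) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            list(self.sample_ids),
            [self.feature_ids[i] for i in idx],
            self.values[:, idx],
            self.platform[idx],
            self.annotation[idx],
            self.is_qc,
        )

    def reorder_samples(self, sample_ids: list[str]) -> "FeatureTable":
        """Reorder biological rows to ``sample_ids``; QC rows keep their place at the end."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"samples not present in table: {missing[:5]}")
        qc_idx = [i for i, q in enumerate(self.is_qc) if q]
        idx = [pos[s] for s in sample_ids] + qc_idx
        return FeatureTable(
            [self.sample_ids[i] for i in idx],
            list(self.feature_ids),
            self.values[idx],
            self.platform,
            self.annotation,
            self.is_qc[idx],
        )


@dataclass
class StudyDesign:
    """Sample → factor-level mapping plus the list of modeled terms.

    ``factors`` maps factor name → per-sample level labels, aligned with
    ``sample_ids``. ``effects`` is the ordered list of model terms; each term
    is a tuple of 1–2 factor names. The constructor canonicalizes sample
    order (sorted ids), checks that the full factorial is balanced, and
    records the replicate count per cell.
    """

    sample_ids: list[str]
    factors: dict[str, list[str]]
    effects: list[tuple[str, ...]] = field(default_factory=list)
    replicates: int = field(init=False)

    def __post_init__(self):
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicated sample id in design: {dup!r}")
        n = len(self.sample_ids)
        for name, levels in self.factors.items():
            if len(levels) != n:
                raise ValueError(
                    f"factor {name!r} has {len(levels)} levels for {n} samples"
                )
            if any(lv is None or lv == "" for lv in levels):
                bad = self.sample_ids[
                    [i for i, lv in enumerate(levels) if lv in (None, "")][0]
                ]
                raise ValueError(f"sample {bad!r} has no level for factor {name!r}")
        # canonical order: sorted sample ids
        order = sorted(range(n), key=lambda i: self.sample_ids[i])
        self.sample_ids = [self.sample_ids[i] for i in order]
        self.factors = {
            name: [levels[i] for i in order] for name, levels in self.factors.items()
        }
        if not self.effects:
            names = list(self.factors)
            self.effects = [(f,) for f in names] + [
                pair for pair in itertools.combinations(names, 2)
            ]
        self.effects = [tuple(t) for t in self.effects]
        if len(set(self.effects)) != len(self.effects):
            raise ValueError("effects list contains a repeated term")
        for term in self.effects:
            if not 1 <= len(term) <= 2:
                raise ValueError(f"only main effects and two-way terms supported: {term}")
            for f in term:
                if f not in self.factors:
                    raise ValueError(f"unknown factor {f!r} in term {term}")
        self.replicates = self._check_balance()

    def _check_balance(self) -> int:
        cells: dict[tuple, int] = {}
        for i in range(self.n_samples):
            cell = tuple(self.factors[f][i] for f in self.factors)
            cells[cell] = cells.get(cell, 0) + 1
        n_cells = 1
        for f in self.factors:
            n_cells *= len(self.levels(f))
        counts = set(cells.values())
        if len(cells) != n_cells or len(counts) != 1:
            raise ValueError(
                "design is not a balanced full factorial; cell counts: "
                + ", ".join(f"{'/'.join(c)}: {k}" for c, k in sorted(cells.items()))
            )
        return counts.pop()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def levels(self, factor: str) -> list[str]:
        seen: dict[str, None] = {}
        for lv in self.factors[factor]:
            seen.setdefault(lv, None)
        return sorted(seen)

    def codes(self, factor: str) -> np.ndarray:
        """Integer level codes for one factor, in ``levels(factor)`` order."""
        lut = {lv: k for k, lv in enumerate(self.levels(factor))}
        return np.array([lut[lv] for lv in self.factors[factor]], dtype=int)

    def term_codes(self, term: tuple[str, ...]) -> tuple[np.ndarray, int]:
        """Integer cell codes for a term (joint cells for interactions)."""
        code = np.zeros(self.n_samples, dtype=int)
        size = 1
        for f in term:
            code = code * len(self.levels(f)) + self.codes(f)
            size *= len(self.levels(f))
        return code, size


@dataclass
class ProteinTable:
    """Per-protein treated/control fold-changes with test p-values."""

    protein_ids: list[str]
    fold_change: np.ndarray
    p_value: np.ndarray

    def __post_init__(self):
        self.fold_change = np.asarray(self.fold_change, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        n = len(self.protein_ids)
        if self.fold_change.shape != (n,) or self.p_value.shape != (n,):
            raise ValueError("fold_change / p_value length mismatch with protein_ids")
        if (self.fold_change <= 0).any():
            bad = self.protein_ids[int(np.argmax(self.fold_change <= 0))]
            raise ValueError(f"non-positive fold-change for protein {bad!r}")
        if ((self.p_value < 0) | (self.p_value > 1)).any():
            bad = self.protein_ids[int(np.argmax((self.p_value < 0) | (self.p_value > 1)))]
            raise ValueError(f"p-value outside [0,1] for protein {bad!r}")


@dataclass
class PathwaySet:
    """Named pathway → member-id sets (metabolites and/or proteins)."""

    name: str
    pathways: dict[str, set[str]]
    universe_hint: int | None = None

    def __post_init__(self):
        for pname, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pname!r} has no members")


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _read_delimited(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", comment=None, dtype=str)


def read_feature_table(path, platform_label: str = "", qc_pattern: str = "QC") -> FeatureTable:
    """Read a delimited feature table (first column sample ids, header feature ids).

    Lines starting with ``#platform`` / ``#annotation`` carry per-feature
    metadata (written by :func:`write_feature_table`); without them every
    feature gets ``platform_label`` and its own id as annotation. An optional
    ``is_qc`` column overrides the ``qc_pattern`` substring match.
    """
    meta: dict[str, list[str]] = {}
    header_lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, *rest = line.rstrip("\n").split("\t")
                meta[key.lstrip("#")] = rest
            else:
                header_lines.append(line)
    from io import StringIO

    sep = "\t" if "\t" in header_lines[0] else ","
    df = pd.read_csv(StringIO("".join(header_lines)), sep=sep, dtype=str)
    sample_col = df.columns[0]
    sample_ids = df[sample_col].tolist()
    if "is_qc" in df.columns:
        is_qc = df["is_qc"].str.lower().isin(["true", "1", "yes"]).to_numpy()
        df = df.drop(columns=["is_qc"])
    else:
        is_qc = np.array([qc_pattern in s for s in sample_ids])
    feature_ids = list(df.columns[1:])
    try:
        values = df[feature_ids].astype(float).to_numpy()
    except ValueError as e:
        raise ValueError(f"non-numeric cell in {path}: {e}") from None
    platform = np.array(
        meta.get("platform", [platform_label] * len(feature_ids)), dtype=object
    )
    annotation = np.array(meta.get("annotation", feature_ids), dtype=object)
    return FeatureTable(sample_ids, feature_ids, values, platform, annotation, is_qc)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a :class:`FeatureTable` as TSV with metadata comment lines."""
    with open(path, "w") as fh:
        fh.write("#platform\t" + "\t".join(map(str, table.platform)) + "\n")
        fh.write("#annotation\t" + "\t".join(map(str, table.annotation)) + "\n")
        fh.write("sample_id\tis_qc\t" + "\t".join(table.feature_ids) + "\n")
        for i, sid in enumerate(table.sample_ids):
            row = "\t".join(repr(float(v)) for v in table.values[i])
            fh.write(f"{sid}\t{str(bool(table.is_qc[i])).lower()}\t{row}\n")


def read_design(path, effects: list[tuple[str, ...]] | None = None) -> StudyDesign:
    """Read a design table: first column sample ids, one column per factor."""
    df = _read_delimited(path)
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"sample {df.iloc[i, 0]!r} is missing a level for factor {df.columns[j]!r}"
        )
    sample_ids = df.iloc[:, 0].tolist()
    factors = {c: df[c].tolist() for c in df.columns[1:]}
    return StudyDesign(sample_ids, factors, effects or [])


def write_design(design: StudyDesign, path) -> None:
    df = pd.DataFrame({"sample_id": design.sample_ids, **design.factors})
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path, name: str | None = None) -> PathwaySet:
    """Read GMT: one pathway per line, ``name<TAB>description<TAB>member...``."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs name, description, members")
            pname = parts[0]
            if pname in pathways:
                raise ValueError(f"{path}:{ln}: duplicated pathway name {pname!r}")
            members = {m for m in parts[2:] if m}
            pathways[pname] = members
    return PathwaySet(name or str(path), pathways)


def write_gmt(ps: PathwaySet, path) -> None:
    with open(path, "w") as fh:
        for pname, members in ps.pathways.items():
            fh.write(pname + "\t" + ps.name + "\t" + "\t".join(sorted(members)) + "\n")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
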