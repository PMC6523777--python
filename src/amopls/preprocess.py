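"""QC filtering, cross-platform de-duplication and unit-variance scaling.

Pooled-QC re-injections gauge technical repeatability: a feature whose QC
coefficient of variation (sample SD / mean, denominator n−1) exceeds the
threshold (35% in the reference workflow) is discarded. A metabolite
annotated on more than one LC-MS platform is kept once, on its most
repeatable platform. The surviving features are column-concatenated and
unit-variance scaled (statistics over biological samples only) into the
single matrix submitted to the AMOPLS model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable

__all__ = ["PreprocessReport", "qc_cv_filter", "resolve_duplicates", "uv_scale", "qc_cv"]

# platform priority for duplicate ties: descending annotation counts in the
# reference four-platform study
PLATFORM_PRIORITY = ["HILIC-", "HILIC+", "RPLC-", "RPLC+"]


@dataclass
class PreprocessReport:
    counts_before: dict[str, int] = field(default_factory=dict)
    counts_after: dict[str, int] = field(default_factory=dict)
    removed: dict[str, str] = field(default_factory=dict)  # feature id -> reason
    duplicate_log: dict[str, str] = field(default_factory=dict)  # annotation -> decision
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None


def qc_cv(table: FeatureTable) -> np.ndarray:
    """Per-feature CV over the QC rows (sample SD with denominator n−1).

    Features with zero QC mean get CV = +inf so the filter drops them as
    degenerate.
    """
    qc = table.values[table.is_qc]
    if qc.shape[0] < 2:
        raise ValueError(f"need at least 2 QC samples, found {qc.shape[0]}")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, np.inf)
    return np.abs(cv)


def qc_cv_filter(
    table: FeatureTable, threshold: float = 0.35
) -> tuple[FeatureTable, PreprocessReport]:
    """Remove features whose QC CV is strictly above ``threshold``.

    A CV exactly at the threshold is kept (the rule removes features *above*
    it). QC rows stay in the returned table for reporting; downstream
    modeling uses only biological rows.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cv = qc_cv(table)
    keep = cv <= threshold
    report = PreprocessReport()
    for plat in sorted(set(table.platform)):
        mask = table.platform == plat
        report.counts_before[plat] = int(mask.sum())
        report.counts_after[plat] = int((mask & keep).sum())
    for j in np.where(~keep)[0]:
        reason = "degenerate" if not np.isfinite(cv[j]) else f"cv={cv[j]:.3f}"
        report.removed[table.feature_ids[j]] = reason
    return table.subset_features(np.where(keep)[0]), report


def resolve_duplicates(
    tables: list[FeatureTable],
) -> tuple[FeatureTable, PreprocessReport]:
    """Merge platform tables, keeping each annotation once.

    When an annotation appears on several platforms the copy with the lowest
    QC CV wins; ties go to the higher median intensity, then to the fixed
    platform priority. Unannotated features (empty annotation) are never
    deduplicated. All tables must share the same samples in the same order.
    """
    ref = tables[0].sample_ids
    for t in tables[1:]:
        if t.sample_ids != ref:
            raise ValueError("sample ids differ between platform tables")
    report = PreprocessReport()
    candidates: dict[str, list[tuple]] = {}
    for ti, t in enumerate(tables):
        has_qc = t.is_qc.sum() >= 2
        cv = qc_cv(t) if has_qc else np.full(t.n_features, np.nan)
        med = np.median(t.values, axis=0)
        for j in range(t.n_features):
            ann = t.annotation[j]
            key = ann if ann else f"__unann_{ti}_{j}"
            candidates.setdefault(key, []).append(
                (cv[j], -med[j], _priority(t.platform[j]), ti, j)
            )

    def rank(c):
        # CVs within 1e-9 are measurement-identical: quantize so the
        # median/priority tie-breaks are not defeated by float noise
        cv_j = round(c[0], 9) if np.isfinite(c[0]) else np.inf
        return (cv_j, c[1], c[2])

    keep: list[tuple[int, int]] = []
    for key, cands in candidates.items():
        best = min(cands, key=rank)
        keep.append((best[3], best[4]))
        if len(cands) > 1:
            t = tables[best[3]]
            report.duplicate_log[key] = (
                f"kept on {t.platform[best[4]]} "
                f"(qc_cv={best[0]:.3f}, median={-best[1]:.3g}) "
                f"among {len(cands)} platforms"
            )
    keep.sort()
    values = np.column_stack([tables[ti].values[:, j] for ti, j in keep])
    merged = FeatureTable(
        list(ref),
        [_unique_id(tables[ti], j, ti) for ti, j in keep],
        values,
        np.array([tables[ti].platform[j] for ti, j in keep], dtype=object),
        np.array([tables[ti].annotation[j] for ti, j in keep], dtype=object),
        tables[0].is_qc,
    )
    for t in tables:
        for plat in sorted(set(t.platform)):
            report.counts_before[plat] = report.counts_before.get(plat, 0) + int(
                (t.platform == plat).sum()
            )
    for plat in sorted(set(merged.platform)):
        report.counts_after[plat] = int((merged.platform == plat).sum())
    return merged, report


def _priority(platform: str) -> int:
    try:
        return PLATFORM_PRIORITY.index(platform)
    except ValueError:
        return len(PLATFORM_PRIORITY)


def _unique_id(table: FeatureTable, j: int, ti: int) -> str:
    fid = table.feature_ids[j]
    return f"{fid}@{table.platform[j]}" if table.platform[j] else f"{fid}#{ti}"


def uv_scale(table: FeatureTable) -> tuple[FeatureTable, PreprocessReport]:
    """Unit-variance scale each feature (mean 0, SD 1 over biological samples).

    QC rows are transformed with the same parameters. Constant columns are an
    error — they carry no usable variance.
    """
    bio = table.values[~table.is_qc]
    mean = bio.mean(axis=0)
    sd = bio.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(
            f"constant feature over biological samples: {table.feature_ids[zero[0]]!r}"
        )
    scaled = FeatureTable(
        list(table.sample_ids),
        list(table.feature_ids),
        (table.values - mean) / sd,
        table.platform,
        table.annotation,
        table.is_qc,
    )
    report = PreprocessReport(scale_mean=mean, scale_sd=sd)
    return scaled, report
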