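"""Design-based partition of the data matrix (the ANOVA step of AMOPLS).

For a balanced full factorial the centered data matrix splits uniquely into
mutually orthogonal pieces, one per modeled term plus a residual:

    X = 1·m' + Σ_f X_f + E

Main-effect rows are level means of the centered data; interaction rows are
cell means minus the contributing main effects. Orthogonality of the pieces
makes the sums of squares additive, so each term's share of total SS is the
"contribution" percentage reported for the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import StudyDesign, term_label

__all__ = ["AnovaDecomposition", "decompose", "contributions", "RESIDUAL"]

RESIDUAL = "Residuals"


@dataclass
class AnovaDecomposition:
    """Grand mean, per-term effect matrices, residual and sums of squares."""

    grand_mean: np.ndarray
    effect_matrices: dict[str, np.ndarray]  # term label -> (n, p)
    residual: np.ndarray
    ss: dict[str, float]  # term labels + RESIDUAL + "Total"
    design: StudyDesign

    @property
    def n_samples(self) -> int:
        return self.residual.shape[0]

    @property
    def n_features(self) -> int:
        return self.residual.shape[1]

    def reconstruct(self) -> np.ndarray:
        X = self.grand_mean + self.residual
        for M in self.effect_matrices.values():
            X = X + M
        return X


def _group_mean_rows(Xc: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Expand per-group means of Xc back to full rows (the averaging projector)."""
    sums = np.zeros((n_groups, Xc.shape[1]))
    np.add.at(sums, codes, Xc)
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    counts[counts == 0] = 1.0
    return (sums / counts[:, None])[codes]


def effect_projections(
    Xc: np.ndarray,
    design: StudyDesign,
    effects: list[tuple[str, ...]] | None = None,
) -> dict[tuple[str, ...], np.ndarray]:
    """Pure effect matrices for each term of an (already centered) matrix.

    Interactions subtract their parent main effects so each matrix carries
    only the term's own structure. Fast path shared by :func:`decompose`,
    the permutation test and the synthetic-data generator.
    """
    effects = list(design.effects if effects is None else effects)
    mains: dict[str, np.ndarray] = {}
    out: dict[tuple[str, ...], np.ndarray] = {}
    for term in effects:
        if len(term) == 1:
            codes, k = design.term_codes(term)
            M = _group_mean_rows(Xc, codes, k)
            mains[term[0]] = M
            out[term] = M
    for term in effects:
        if len(term) == 2:
            for f in term:
                if f not in mains:
                    raise ValueError(
                        f"interaction {term} requires main effect of {f!r} in the model"
                    )
            codes, k = design.term_codes(term)
            cell = _group_mean_rows(Xc, codes, k)
            out[term] = cell - mains[term[0]] - mains[term[1]]
    return {t: out[t] for t in effects}


def decompose(X: np.ndarray, design: StudyDesign) -> AnovaDecomposition:
    """Partition ``X`` (rows aligned to ``design.sample_ids``) by the design.

    The design must be a balanced full factorial (``StudyDesign`` enforces
    this); only then is the partition unique and the SS additive. Terms not
    in ``design.effects`` (e.g. the three-way interaction of the default
    three-factor model) are pooled into the residual.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] != design.n_samples:
        raise ValueError(
            f"X has {X.shape[0]} rows but design has {design.n_samples} samples"
        )
    grand = X.mean(axis=0, keepdims=True)
    Xc = X - grand
    mats = effect_projections(Xc, design)
    residual = Xc.copy()
    for M in mats.values():
        residual -= M
    ss: dict[str, float] = {}
    for term, M in mats.items():
        ss[term_label(term)] = float(np.sum(M * M))
    ss[RESIDUAL] = float(np.sum(residual * residual))
    ss["Total"] = float(np.sum(Xc * Xc))
    return AnovaDecomposition(
        grand_mean=grand,
        effect_matrices={term_label(t): M for t, M in mats.items()},
        residual=residual,
        ss=ss,
        design=design,
    )


def contributions(d: AnovaDecomposition) -> dict[str, float]:
    """Percent of total SS per term, residual included; sums to 100."""
    total = d.ss["Total"]
    if total <= 0:
        raise ValueError("total sum of squares is zero; nothing to apportion")
    out = {k: 100.0 * v / total for k, v in d.ss.items() if k != "Total"}
    return out
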