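"""Consensus kernel multiblock OPLS over the ANOVA blocks.

Each block Z_b (one effect matrix per modeled term plus the residual, or the
per-platform split in consensus mode) contributes a linear Gram kernel
K_b = Z_b Z_bᵀ, Frobenius-normalized so no block dominates by scale. The
consensus kernel is their unweighted mean. Predictive components are the
directions of the consensus kernel most covariant with the dummy-coded
design response Y: scores are eigenvectors of K Y Yᵀ K, i.e. left singular
vectors of K·Y, scaled by their singular values. Orthogonal components are
leading eigenvectors of the kernel projected onto the orthocomplement of
span([Y, T_pred]), so they are exactly uncorrelated with every design
contrast.

Block saliences λ_{b,c} = t_cᵀ K_b t_c / Σ_b' t_cᵀ K_b' t_c measure how much
of each latent component is carried by each block; they are the basis of the
effect↔component association and of the residual-structure ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anova import RESIDUAL, AnovaDecomposition
from .io import StudyDesign, term_label

__all__ = [
    "BlockSet",
    "DummyResponse",
    "AmoplsModel",
    "build_blocks",
    "build_dummy_response",
    "fit",
    "predictive_scores_plot_data",
]


@dataclass
class BlockSet:
    """Named blocks sharing the sample dimension, with normalized kernels."""

    blocks: dict[str, np.ndarray]
    kernels: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self):
        ns = {M.shape[0] for M in self.blocks.values()}
        if len(ns) != 1:
            raise ValueError(f"blocks disagree on sample count: {sorted(ns)}")
        self.kernels = {}
        for name, Z in self.blocks.items():
            K = Z @ Z.T
            norm = np.linalg.norm(K)
            if norm == 0:
                raise ValueError(f"block {name!r} is empty (all-zero matrix)")
            self.kernels[name] = K / norm

    @property
    def n_samples(self) -> int:
        return next(iter(self.blocks.values())).shape[0]


@dataclass
class DummyResponse:
    """Centered design-contrast response Y with per-term column slices.

    Each main factor contributes ``levels - 1`` orthonormal contrast columns
    (an orthonormal basis of its centered one-hot indicators); an interaction
    contributes the elementwise products of its parents' contrast columns,
    re-orthonormalized. For the default 2×2×3 model with all two-way terms,
    q = 1+1+2+1+2+2 = 9.
    """

    Y: np.ndarray
    term_slices: dict[str, slice]
    design: StudyDesign

    @property
    def q(self) -> int:
        return self.Y.shape[1]


def build_blocks(
    d: AnovaDecomposition, mode: str = "effects", augment_residual: bool = True
) -> BlockSet:
    """One block per ANOVA term + a pure-residual block, or per-platform blocks.

    Each effect block is the effect matrix *augmented with the residual*
    (X_f + E, the common ASCA-family practice): the residual subspace is
    exactly orthogonal to every design contrast, so pure effect blocks would
    give the residual zero salience on every predictive component and the
    residual-structure ratio would be degenerate. With augmentation a null
    effect's block is statistically indistinguishable from the residual block
    and its RSR sits near 1, which is the behaviour the ratio is built to
    expose. ``augment_residual=False`` restores pure effect blocks.

    ``mode='platforms'`` needs per-feature platform labels and is used only
    for the per-technique salience report; it splits the residual-free
    reconstruction by platform.
    """
    if mode == "effects":
        if augment_residual:
            blocks = {k: M + d.residual for k, M in d.effect_matrices.items()}
        else:
            blocks = dict(d.effect_matrices)
        blocks[RESIDUAL] = d.residual
        return BlockSet(blocks)
    if mode == "platforms":
        raise ValueError("platform mode requires build_platform_blocks(d, platform)")
    raise ValueError(f"unknown mode {mode!r}")


def build_platform_blocks(d: AnovaDecomposition, platform: np.ndarray) -> BlockSet:
    """Residual-free signal split by analytical platform (descriptive report)."""
    signal = sum(d.effect_matrices.values())
    blocks = {}
    for plat in sorted(set(platform)):
        cols = np.asarray(platform) == plat
        blocks[str(plat)] = signal[:, cols]
    return BlockSet(blocks)


def _factor_contrasts(design: StudyDesign, factor: str) -> np.ndarray:
    codes = design.codes(factor)
    k = len(design.levels(factor))
    H = np.zeros((design.n_samples, k))
    H[np.arange(design.n_samples), codes] = 1.0
    H -= H.mean(axis=0)
    # orthonormal basis of the centered indicators: rank k-1
    U, s, _ = np.linalg.svd(H, full_matrices=False)
    return U[:, : k - 1] * np.sign(s[: k - 1])[None, :]


def build_dummy_response(design: StudyDesign) -> DummyResponse:
    cols: list[np.ndarray] = []
    term_slices: dict[str, slice] = {}
    contrasts = {f: _factor_contrasts(design, f) for f in design.factors}
    start = 0
    for term in design.effects:
        if len(term) == 1:
            C = contrasts[term[0]]
        else:
            A, B = contrasts[term[0]], contrasts[term[1]]
            prods = [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
            C = np.column_stack(prods)
            C -= C.mean(axis=0)
            Q, R = np.linalg.qr(C)
            C = Q * np.sign(np.diag(R))[None, :]
        term_slices[term_label(term)] = slice(start, start + C.shape[1])
        start += C.shape[1]
        cols.append(C)
    Y = np.column_stack(cols)
    return DummyResponse(Y=Y, term_slices=term_slices, design=design)


@dataclass
class AmoplsModel:
    """Fitted AMOPLS model: scores, loadings, saliences, variance shares."""

    T_pred: np.ndarray  # (n, q)
    T_ortho: np.ndarray  # (n, n_ortho)
    P: np.ndarray  # (p, q + n_ortho) back-projected loadings
    saliences: pd.DataFrame  # (q + n_ortho) × blocks, rows sum to 1
    component_variances: np.ndarray  # consensus-kernel variance per component
    block_names: list[str]
    component_names: list[str]
    response: DummyResponse
    X: np.ndarray  # centered data the loadings refer to
    blockset: BlockSet

    @property
    def n_pred(self) -> int:
        return self.T_pred.shape[1]

    @property
    def design(self) -> StudyDesign:
        return self.response.design


def fit(blocks: BlockSet, Y: DummyResponse, n_ortho: int = 1) -> AmoplsModel:
    """Fit the consensus-kernel OPLS model.

    ``n_ortho`` may be an int or ``"auto"`` (add orthogonal components while
    each explains ≥1% of consensus-kernel variance, at most n − q − 1).
    """
    n = blocks.n_samples
    q = Y.q
    if q > n - 1:
        raise ValueError(f"q={q} design contrasts for only n={n} samples")
    kernels = blocks.kernels
    K = sum(kernels.values()) / len(kernels)

    # predictive components: eigenvectors of K Y Y' K == left sing. vectors of K Y
    U, s, _ = np.linalg.svd(K @ Y.Y, full_matrices=False)
    T_pred = U[:, :q] * s[:q][None, :]

    # orthogonal components: structured kernel variance orthogonal to Y and T_pred
    basis = np.linalg.qr(np.column_stack([Y.Y, U[:, :q]]))[0]
    proj = np.eye(n) - basis @ basis.T
    Kd = proj @ K @ proj
    evals, evecs = np.linalg.eigh(Kd)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    max_ortho = max(n - q - 1, 0)
    if n_ortho == "auto":
        share = evals / max(np.trace(K), 1e-300)
        k = int(np.sum(share[:max_ortho] >= 0.01))
    else:
        k = int(n_ortho)
        if k > max_ortho:
            raise ValueError(f"n_ortho={k} exceeds available rank {max_ortho}")
    T_ortho = evecs[:, :k] * np.sqrt(np.clip(evals[:k], 0, None))[None, :]

    T = np.column_stack([T_pred, T_ortho]) if k else T_pred
    comp_names = [f"tp{i+1}" for i in range(q)] + [f"to{i+1}" for i in range(k)]
    block_names = list(blocks.blocks)

    # back-projected variable loadings on the full (summed) data matrix
    X = sum(blocks.blocks.values())
    tt = np.sum(T * T, axis=0)
    tt_safe = np.where(tt > 0, tt, 1.0)
    P = X.T @ T / tt_safe[None, :]
    # sign convention: largest-|loading| entry of each component positive
    for c in range(T.shape[1]):
        j = int(np.argmax(np.abs(P[:, c])))
        if P[j, c] < 0:
            P[:, c] *= -1
            T[:, c] *= -1
    T_pred, T_ortho = T[:, :q], T[:, q:]

    # per-component block saliences
    sal = np.zeros((q + k, len(block_names)))
    for c in range(q + k):
        t = T[:, c]
        nt = np.linalg.norm(t)
        tn = t / nt if nt > 0 else t
        for b, name in enumerate(block_names):
            v = float(tn @ kernels[name] @ tn)
            if v < -1e-8:
                warnings.warn(
                    f"negative salience numerator for block {name!r}, clipped to 0"
                )
            sal[c, b] = max(v, 0.0)
    rows = sal.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    sal /= rows
    saliences = pd.DataFrame(sal, index=comp_names, columns=block_names)

    # consensus-kernel variance captured by each component (pred + ortho)
    comp_var = np.zeros(q + k)
    for c in range(q + k):
        t = T[:, c]
        nt = np.linalg.norm(t)
        tn = t / nt if nt > 0 else t
        comp_var[c] = float(tn @ K @ tn)

    return AmoplsModel(
        T_pred=T_pred,
        T_ortho=T_ortho,
        P=P,
        saliences=saliences,
        component_variances=comp_var,
        block_names=block_names,
        component_names=comp_names,
        response=Y,
        X=X,
        blockset=blocks,
    )


def dominant_block(model: AmoplsModel, component: str) -> str:
    """Block with maximal salience on one component (ties → first block)."""
    row = model.saliences.loc[component]
    return str(row.idxmax())


def predictive_scores_plot_data(
    model: AmoplsModel, effect: str, components: list[str] | None = None
) -> pd.DataFrame:
    """Score coordinates behind an effect's score plot (no rendering).

    Emits one row per biological sample with its level of ``effect`` and its
    scores on the effect's associated predictive components (those whose
    dominant block is the effect; falls back to the components where the
    effect's salience is largest if it never dominates).
    """
    labels = {term_label(t): t for t in model.design.effects}
    if effect not in labels:
        raise ValueError(f"unknown effect {effect!r}; have {list(labels)}")
    if components is None:
        comps = [
            c for c in model.component_names[: model.n_pred]
            if dominant_block(model, c) == effect
        ]
        if not comps:
            pred = model.saliences.iloc[: model.n_pred][effect]
            comps = [str(pred.idxmax())]
    else:
        comps = components
    term = labels[effect]
    level = [
        "/".join(model.design.factors[f][i] for f in term)
        for i in range(model.design.n_samples)
    ]
    data = {"sample_id": model.design.sample_ids, "level": level}
    for c in comps:
        data[c] = model.T_pred[:, model.component_names.index(c)]
    return pd.DataFrame(data)
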