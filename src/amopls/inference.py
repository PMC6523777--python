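"""Statistical readouts of a fitted AMOPLS model.

Four quantities summarize each modeled term:

* its **contribution** (percent of total SS, from the ANOVA step);
* the predictive **components associated** with it (those on which its block
  salience dominates);
* the **Residual Structure Ratio** RSR_b = s_b / s_E, where
  s_b = Σ_c v_c·λ_{b,c} sums block saliences over predictive components
  weighted by each component's consensus-kernel variance share v_c, and E is
  the residual block — so RSR is 1 for the residual by construction and >1
  when a block carries more predictive structure than noise;
* a **permutation p-value** (percent scale): the term's labels are reshuffled
  within strata of the remaining factors (preserving the balanced factorial),
  the whole decompose→fit→RSR pipeline is recomputed, and
  p = 100·(r+1)/(n_perm+1) with r = #{null RSR ≥ observed}.

Per-effect VIP² then ranks variables inside a significant term, normalized so
its mean over variables is 1; the study's selection rule keeps VIP² > 1.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anova, mbopls
from .anova import RESIDUAL
from .io import StudyDesign, term_label

__all__ = [
    "ComponentAssociation",
    "associate_components",
    "rsr",
    "permutation_test",
    "vip2",
    "vip_table",
    "select_features",
    "effect_report",
]


@dataclass
class ComponentAssociation:
    """Effect → predictive components; ``fallback`` marks effects whose
    salience never dominates a component (nearest-by-salience assignment)."""

    components: dict[str, list[str]]
    fallback: set[str]


def associate_components(model: mbopls.AmoplsModel) -> ComponentAssociation:
    pred_names = model.component_names[: model.n_pred]
    sal = model.saliences.loc[pred_names]
    owner = {c: str(sal.loc[c].idxmax()) for c in pred_names}  # ties -> first block
    mapping: dict[str, list[str]] = {b: [] for b in model.block_names}
    for c in pred_names:
        mapping[owner[c]].append(c)
    fallback: set[str] = set()
    for b in model.block_names:
        if b == RESIDUAL or mapping[b]:
            continue
        mapping[b] = [str(sal[b].idxmax())]
        fallback.add(b)
    return ComponentAssociation(components=mapping, fallback=fallback)


def _term_df(design: StudyDesign, term: tuple[str, ...]) -> int:
    df = 1
    for f in term:
        df *= len(design.levels(f)) - 1
    return df


def _ms_rsr(
    block_ss: dict[str, np.ndarray], resid_ss: np.ndarray, design: StudyDesign
) -> dict[str, float]:
    """Median over features of the augmented-block/residual mean-square ratio.

    ``block_ss[b]`` holds per-feature SS of the residual-augmented effect
    block (effect + residual are orthogonal in sample space, so this is
    ss_effect + ss_residual per feature).
    """
    df_e = design.n_samples - 1 - sum(_term_df(design, t) for t in design.effects)
    if df_e <= 0:
        raise ValueError("design leaves no residual degrees of freedom")
    if (resid_ss <= 0).any():
        raise ValueError("a feature has zero residual variance (noiseless input)")
    ms_e = resid_ss / df_e
    out: dict[str, float] = {}
    for t in design.effects:
        label = term_label(t)
        df_b = _term_df(design, t)
        ratio = (block_ss[label] / (df_b + df_e)) / ms_e
        out[label] = float(np.median(ratio))
    out[RESIDUAL] = 1.0
    return out


def rsr(model: mbopls.AmoplsModel) -> dict[str, float]:
    """Residual Structure Ratio per block; residual block ≡ 1 by construction.

    Each effect block of the model is the effect matrix augmented with the
    residual, so per feature j the block carries SS_{b,j} + SS_{E,j}. The
    ratio compares the block's mean square with the residual's,

        RSR_b = median_j [ (SS_{b,j}+SS_{E,j})/(df_b+df_E) ] / [ SS_{E,j}/df_E ],

    aggregated over features by the median, which is insensitive to the
    sample-space anisotropy of the noise (a handful of features aligned with
    the residual's top eigendirections cannot move it). A null effect's block
    is residual plus a small leakage term, so its RSR sits just below 1;
    structure pushes the ratio up monotonically with the effect's share of
    variance, and the residual block scores exactly 1.
    """
    design = model.design
    resid = model.blockset.blocks[RESIDUAL]
    resid_ss = np.sum(resid * resid, axis=0)
    block_ss = {}
    for t in design.effects:
        label = term_label(t)
        B = model.blockset.blocks[label]
        block_ss[label] = np.sum(B * B, axis=0)
    return _ms_rsr(block_ss, resid_ss, design)


def _decompose_rsr(X: np.ndarray, design: StudyDesign) -> dict[str, float]:
    """Fast path for the permutation loop: identical value to
    ``rsr(fit(build_blocks(decompose(X, design)), ...))`` — the statistic is a
    deterministic function of the ANOVA blocks, so the latent-variable fit can
    be skipped when only the RSR is needed."""
    d = anova.decompose(X, design)
    resid_ss = np.sum(d.residual * d.residual, axis=0)
    block_ss = {
        label: np.sum(M * M, axis=0) + resid_ss
        for label, M in d.effect_matrices.items()
    }
    return _ms_rsr(block_ss, resid_ss, design)


def _strata(design: StudyDesign, term: tuple[str, ...]) -> list[np.ndarray]:
    others = [f for f in design.factors if f not in term]
    if not others:
        return [np.arange(design.n_samples)]
    code = np.zeros(design.n_samples, dtype=int)
    for f in others:
        code = code * len(design.levels(f)) + design.codes(f)
    return [np.where(code == c)[0] for c in np.unique(code)]


def permutation_test(
    X: np.ndarray,
    design: StudyDesign,
    effect: str | tuple[str, ...],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation p-value (percent) for one term's RSR.

    The tested term's level assignments are shuffled within strata of the
    factors outside the term, so the permuted design stays a balanced full
    factorial; the full pipeline is refit each time. Deterministic given
    ``seed``. The smallest reachable value is 100/(n_perm+1).
    """
    term = effect if isinstance(effect, tuple) else _term_from_label(design, effect)
    label = term_label(term)
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    floor = 100.0 / (n_perm + 1)
    if floor > 5.0:
        warnings.warn(f"n_perm={n_perm} gives a p-value floor of {floor:.1f}%")
    rng = np.random.default_rng(seed)
    observed = _decompose_rsr(X, design)[label]
    strata = _strata(design, term)
    base_labels = {f: list(design.factors[f]) for f in term}
    r = 0
    for _ in range(n_perm):
        factors = dict(design.factors)
        shuffled = {f: list(base_labels[f]) for f in term}
        for idx in strata:
            perm = rng.permutation(idx)
            for f in term:
                col = shuffled[f]
                for i, j in zip(idx, perm):
                    col[i] = base_labels[f][j]
        for f in term:
            factors[f] = shuffled[f]
        perm_design = StudyDesign(
            list(design.sample_ids), factors, list(design.effects)
        )
        null = _decompose_rsr(X, perm_design)[label]
        if null >= observed:
            r += 1
    return 100.0 * (r + 1) / (n_perm + 1)


def _term_from_label(design: StudyDesign, label: str) -> tuple[str, ...]:
    for t in design.effects:
        if term_label(t) == label:
            return t
    raise ValueError(f"unknown effect {label!r}")


def vip2(model: mbopls.AmoplsModel, effect: str) -> np.ndarray:
    """Per-feature squared variable importance for one effect.

    VIP²_{j} = p · [Σ_c λ_{effect,c}·SS_c·w²_{j,c}] / [Σ_c λ_{effect,c}·SS_c]
    over predictive components c, with w_c the unit-normalized loading vector
    and SS_c the component's consensus-kernel variance. Mean over features
    is exactly 1. ``effect='Global'`` drops the salience weighting (overall
    importance across all effects).
    """
    q = model.n_pred
    pred_names = model.component_names[:q]
    if effect == "Global":
        lam = np.ones(q)
    else:
        if effect not in model.block_names:
            raise ValueError(f"unknown effect {effect!r}")
        lam = model.saliences.loc[pred_names, effect].to_numpy()
    ssc = np.asarray(model.component_variances[:q], dtype=float)
    weights = lam * ssc
    den = weights.sum()
    if den <= 0:
        raise ValueError(f"effect {effect!r} has zero salience on every component")
    W = model.P[:, :q].copy()
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    W = W / norms[None, :]
    p = W.shape[0]
    return p * (W**2 @ weights) / den


def vip_table(model: mbopls.AmoplsModel) -> pd.DataFrame:
    """VIP² for every effect block (residual excluded) plus the global column."""
    effects = [b for b in model.block_names if b != RESIDUAL]
    data = {e: vip2(model, e) for e in effects}
    data["Global"] = vip2(model, "Global")
    return pd.DataFrame(data)


def select_features(
    vip: pd.DataFrame, effect: str, threshold: float, feature_ids: list[str] | None = None
) -> list[str]:
    """Features with VIP² strictly above ``threshold``, sorted descending."""
    if threshold <= 0 and threshold != 0:
        raise ValueError("threshold must be positive")
    col = vip[effect]
    ids = feature_ids if feature_ids is not None else list(vip.index)
    order = np.argsort(-col.to_numpy(), kind="stable")
    return [ids[i] for i in order if col.iloc[i] > threshold]


def effect_report(
    X: np.ndarray,
    design: StudyDesign,
    n_ortho: int = 1,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Assemble the per-term summary table: contribution %, associated
    components with their salience %, RSR, and (optionally) permutation
    p-values in percent. The residual row has RSR 1 and no p-value."""
    d = anova.decompose(X, design)
    blocks = mbopls.build_blocks(d)
    Y = mbopls.build_dummy_response(design)
    model = mbopls.fit(blocks, Y, n_ortho=n_ortho)
    contrib = anova.contributions(d)
    ratios = rsr(model)
    assoc = associate_components(model)
    rows = []
    terms = [term_label(t) for t in design.effects] + [RESIDUAL]
    for label in terms:
        comps = assoc.components.get(label, [])
        sal_pct = [100.0 * model.saliences.loc[c, label] for c in comps]
        row = {
            "effect": label,
            "contribution_pct": contrib[label],
            "components": "+".join(comps),
            "component_salience_pct": "+".join(f"{s:.1f}" for s in sal_pct),
            "rsr": ratios[label],
            "p_value_pct": np.nan,
        }
        if n_perm and label != RESIDUAL:
            row["p_value_pct"] = permutation_test(
                X, design, label, n_perm=n_perm, seed=seed
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("effect")
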