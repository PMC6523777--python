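"""Joint metabolite–protein over-representation analysis.

Proteins are thresholded on fold-change and p-value (two-sided on the ratio
scale: max(FC, 1/FC) > 1.2 keeps down-regulation); each omics' hit list is
tested pathway-by-pathway with the upper-tail hypergeometric probability
P(X ≥ k) given the pathway size inside the declared universe, corrected with
Benjamini–Hochberg FDR; the joint table ranks pathways by the better of the
two omics' p-values and reports p/FDR/found-ratio side by side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import PathwaySet, ProteinTable

__all__ = ["select_proteins", "ora", "joint_table"]


def select_proteins(
    pt: ProteinTable, fc_threshold: float = 1.2, p_threshold: float = 0.05
) -> list[str]:
    """Proteins regulated beyond the fold-change and p-value thresholds.

    The rule is two-sided on the ratio scale: a protein passes when
    ``max(FC, 1/FC) > fc_threshold`` and ``p < p_threshold``.
    """
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    fc = np.maximum(pt.fold_change, 1.0 / pt.fold_change)
    keep = (fc > fc_threshold) & (pt.p_value < p_threshold)
    return [pid for pid, k in zip(pt.protein_ids, keep) if k]


def ora(hits: set[str], universe: set[str], pathways: PathwaySet) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` in each pathway.

    Pathway members are intersected with the universe before testing;
    p = P(X ≥ k) for X ~ Hypergeom(N=|universe|, K=|pathway ∩ universe|,
    n=|hits|), BH-FDR corrected across the tested pathways. Pathways with no
    member in the universe are reported with K=0, p=1.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits:
        raise ValueError("empty hit list")
    stray = hits - universe
    if stray:
        raise ValueError(f"hits outside the universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(hits)
    rows = []
    for name, members in pathways.pathways.items():
        inside = members & universe
        K = len(inside)
        k = len(inside & hits)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append({"pathway": name, "k": k, "K": K, "p_value": p})
    df = pd.DataFrame(rows).set_index("pathway")
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df["found"] = [f"{k}/{K}" for k, K in zip(df["k"], df["K"])]
    return df


def joint_table(
    metab: pd.DataFrame, prot: pd.DataFrame, top_n: int = 10
) -> pd.DataFrame:
    """Rank pathways by the better (min) of the two omics' p-values.

    Emits one row per pathway present in either omics, with p/FDR/found
    columns for both, sorted ascending by min-p; the top ``top_n`` rows.
    """
    all_paths = metab.index.union(prot.index)
    rows = []
    for name in all_paths:
        pm = metab["p_value"].get(name, np.nan)
        pp = prot["p_value"].get(name, np.nan)
        rows.append(
            {
                "pathway": name,
                "p_proteomics": pp,
                "fdr_proteomics": prot["fdr"].get(name, np.nan),
                "found_proteomics": prot["found"].get(name, ""),
                "p_metabolomics": pm,
                "fdr_metabolomics": metab["fdr"].get(name, np.nan),
                "found_metabolomics": metab["found"].get(name, ""),
                "min_p": np.nanmin([pm, pp]),
            }
        )
    df = pd.DataFrame(rows).set_index("pathway")
    df = df.sort_values(["min_p", "p_metabolomics"], kind="stable")
    return df.head(top_n)
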