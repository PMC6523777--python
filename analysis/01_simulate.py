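"""Generate the synthetic study: four platform tables, design, proteins, maps.

Emulates the reference experiment's structure — 36 biological samples
(2 maturation states × 2 exposure durations × 3 TMT concentrations × 3
replicates), 189 annotated features split 33/36/58/62 across RPLC+/RPLC-/
HILIC+/HILIC-, pooled-QC re-injections, per-term variance fractions
calibrated to the reported contributions, plus a 2422-protein fold-change
table and pathway maps with a planted joint signal.

Writes fixtures under results/fixtures/.
"""

import argparse
from pathlib import Path

import pandas as pd

from amopls import synthdata
from amopls.enrichment import select_proteins
from amopls.io import write_design, write_feature_table, write_gmt


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out-dir", type=Path, default=Path("results/fixtures"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    spec = synthdata.SyntheticSpec(seed=args.seed)
    tables, design = synthdata.generate(spec)
    for plat, table in tables.items():
        name = plat.replace("+", "pos").replace("-", "neg")
        write_feature_table(table, out / f"{name}.tsv")
    write_design(design, out / "design.tsv")

    proteins = synthdata.generate_proteins(n=2422, n_regulated=50, seed=args.seed + 1)
    pd.DataFrame(
        {
            "protein_id": proteins.protein_ids,
            "fold_change": proteins.fold_change,
            "p_value": proteins.p_value,
        }
    ).to_csv(out / "proteins.tsv", sep="\t", index=False)

    universe = [f"met_{i+1:04d}" for i in range(spec.n_features)]
    universe += proteins.protein_ids
    hits = set(select_proteins(proteins))
    maps = synthdata.generate_pathways(
        universe, hits, n_maps=20, planted_map_size=20, seed=args.seed + 2
    )
    write_gmt(maps, out / "maps.gmt")

    n_qc = int(tables["RPLC+"].is_qc.sum())
    print(f"design: {design.n_samples} biological samples, {design.replicates} replicates/cell")
    print(f"features: {spec.n_features} across {len(tables)} platforms, {n_qc} QC injections")
    print(f"proteins: {len(proteins.protein_ids)} quantified, {len(hits)} pass FC/p thresholds")
    print(f"pathways: {len(maps.pathways)} maps (one planted)")
    print(f"fixtures in {out}")


if __name__ == "__main__":
    main()
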