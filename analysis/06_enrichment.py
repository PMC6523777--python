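"""Joint metabolite-protein over-representation analysis.

Selects metabolites by concentration-effect VIP² > 1.1 and proteins by
fold-change > 1.2 with p < 0.05, tests both hit lists against the pathway
maps with the hypergeometric upper tail plus BH-FDR, and ranks maps by the
better of the two omics' p-values — the joint table that puts the two
platforms' evidence side by side.

Writes results/vip2.tsv, results/selected_metabolites.txt and
results/joint_enrichment.tsv.
"""

import argparse
from pathlib import Path

from amopls import anova, enrichment, inference, mbopls, synthdata
from amopls.preprocess import resolve_duplicates, uv_scale


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--vip-threshold", type=float, default=1.1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    tables, design = synthdata.generate(synthdata.SyntheticSpec(seed=args.seed))
    merged, _ = resolve_duplicates(list(tables.values()))
    scaled, _ = uv_scale(merged)
    d = anova.decompose(scaled.biological().values, design)
    model = mbopls.fit(mbopls.build_blocks(d), mbopls.build_dummy_response(design), 1)

    vt = inference.vip_table(model)
    vt.index = merged.feature_ids
    vt.to_csv(out / "vip2.tsv", sep="\t")
    selected = inference.select_features(vt, "Concentration", args.vip_threshold)
    ann = dict(zip(merged.feature_ids, merged.annotation))
    (out / "selected_metabolites.txt").write_text(
        "".join(f"{f}\t{ann[f]}\n" for f in selected)
    )
    print(
        f"{len(selected)} metabolites with concentration VIP² > "
        f"{args.vip_threshold} (of {merged.n_features})"
    )

    proteins = synthdata.generate_proteins(n=2422, n_regulated=50, seed=args.seed + 1)
    prot_hits = set(enrichment.select_proteins(proteins))
    print(f"{len(prot_hits)} proteins pass FC > 1.2 and p < 0.05 (of 2422)")

    metab_universe = {a for a in merged.annotation if a}
    metab_hits = {ann[f] for f in selected if ann[f]}
    universe = sorted(metab_universe) + proteins.protein_ids
    maps = synthdata.generate_pathways(
        universe, prot_hits | metab_hits, n_maps=20, seed=args.seed + 2
    )
    metab_res = enrichment.ora(metab_hits, metab_universe, maps)
    prot_res = enrichment.ora(prot_hits, set(proteins.protein_ids), maps)
    joint = enrichment.joint_table(metab_res, prot_res, top_n=10)
    joint.to_csv(out / "joint_enrichment.tsv", sep="\t")
    top = joint.index[0]
    print(
        f"top joint map: {top} (proteomics p={joint.loc[top, 'p_proteomics']:.3g}, "
        f"metabolomics p={joint.loc[top, 'p_metabolomics']:.3g})"
    )


if __name__ == "__main__":
    main()
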