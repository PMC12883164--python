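#!/usr/bin/env python
"""Link gene traits to transcriptional response.

Three views, mirroring the community- and genome-level analyses:
1. transcript-pool trait means per sample (genes weighted by normalized
   transcript counts), compared between arms by ANOVA;
2. per-gene multiple regression of LFC on trait predictors;
3. genome-level pathway fits: mean LFC vs mean FOP across genomes for the
   growth and stress pathways, with leave-one-out slope influence.

Writes results/sample_trait_means.tsv, results/trait_anova.tsv and
results/pathway_associations.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from genetraits import association, de, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--predictor", default="fop")
    ap.add_argument("--exclude", default="",
                    help="comma-separated genome ids excluded from pathway fits")
    args = ap.parse_args()
    data = Path(args.datadir)
    out = Path(args.outdir)
    exclusions = [x for x in args.exclude.split(",") if x]

    tt = pd.read_csv(out / "gene_traits.tsv", sep="\t").set_index("gene_id")
    det = pd.read_csv(out / "differential_expression.tsv", sep="\t",
                      index_col=0)
    cm = io.read_counts(data / "counts.tsv", data / "design.tsv")

    # 1. transcript-pool means per sample, ANOVA between arms
    sf = de.size_factors(cm.counts)
    norm = cm.counts / sf
    pooled = []
    for sample in norm.columns:
        st = tt.copy()
        st["weight"] = norm[sample].reindex(tt.index).fillna(0.0).values
        st["sample_id"] = sample
        st["treatment"] = cm.design.loc[sample, "treatment"]
        pooled.append(st)
    pooled = pd.concat(pooled).reset_index()
    means = association.weighted_summary(pooled, ["sample_id", "treatment"],
                                         weight_col="weight")
    means.to_csv(out / "sample_trait_means.tsv", sep="\t", index=False)
    anova_rows = []
    for trait in ("cai", "fop", "milc", "gc_fourfold", "gc_skew_fourfold",
                  "at_skew_fourfold", "aa_mean_cost"):
        cmpr = association.compare_groups(means, trait, "treatment")
        anova_rows.append({"trait": trait, "f": cmpr.f_statistic,
                           "p": cmpr.p_value})
        print(f"transcript-pool {trait}: control vs treatment "
              f"F={cmpr.f_statistic:.2f}, p={cmpr.p_value:.4f}")
    pd.DataFrame(anova_rows).to_csv(out / "trait_anova.tsv", sep="\t",
                                    index=False)

    # 2. per-gene regression of LFC on traits
    fit = association.regress_lfc_on_traits(det, tt, [args.predictor, "milc"])
    print(f"per-gene LFC ~ {args.predictor} + milc: R^2={fit.r_squared:.3f} "
          f"over {fit.n_points} genes")

    # 3. genome-level pathway fits
    rows = []
    for pathway in ("growth", "stress"):
        rel = association.pathway_level_relation(
            tt, det, pathway, predictor=args.predictor, exclusions=exclusions)
        coef = rel.coefficients.set_index("predictor").loc[args.predictor]
        rows.append({"pathway": pathway, "predictor": args.predictor,
                     "slope": coef["estimate"], "se": coef["se"],
                     "p_value": coef["p_value"], "r_squared": rel.r_squared,
                     "n_genomes": rel.n_points})
        print(f"{pathway}: slope {coef['estimate']:.3f} +/- {coef['se']:.3f} "
              f"(p={coef['p_value']:.4f}, n={rel.n_points} genomes)")
        if rel.influence is not None:
            top = rel.influence.loc[rel.influence["slope_change"].abs().idxmax()]
            print(f"  max leave-one-out influence: {top['taxon_id']} "
                  f"(slope change {top['slope_change']:+.3f})")
    pd.DataFrame(rows).to_csv(out / "pathway_associations.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
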