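"""Trait summarization and trait–expression association statistics.

Community trait averages are depth-weighted means: metagenome summaries
weight genes by DNA read coverage, metatranscriptome summaries by each
gene's normalized transcript count in the sample (depth of expression).
Group differences use one-way ANOVA with Tukey HSD pairwise comparisons;
trait–LFC links use ordinary least squares, per gene or — the analysis
with real signal — per genome, averaging traits and LFC over all genes of
a pathway within each genome and fitting across genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genetic_code import GeneticCode, default_code
from .traits import TRAIT_COLUMNS


def weighted_summary(
    traits: pd.DataFrame,
    grouping: list[str],
    weight_col: str = "depth",
    trait_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Depth-weighted trait means per group.

    Undefined (NaN) trait values are skipped with weight renormalization
    over the genes where the trait is defined; a group with zero total
    weight for a trait gets NaN.
    """
    trait_cols = trait_cols or [c for c in TRAIT_COLUMNS if c in traits.columns]
    if (traits[weight_col] < 0).any():
        raise ValueError("weights must be nonnegative")
    rows = []
    for keys, grp in traits.groupby(grouping, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(grouping, keys))
        row["n_genes"] = len(grp)
        row["total_weight"] = float(grp[weight_col].sum())
        for t in trait_cols:
            ok = grp[t].notna() & (grp[weight_col] > 0)
            w = grp.loc[ok, weight_col]
            row[t] = float((grp.loc[ok, t] * w).sum() / w.sum()) if w.sum() > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """One-way ANOVA plus Tukey HSD pairwise results for one trait."""

    trait: str
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, diff, p_adj


def compare_groups(
    values: pd.DataFrame,
    value_col: str,
    group_col: str,
) -> GroupComparison:
    """ANOVA omnibus test across groups with Tukey HSD pairwise differences."""
    df = values[[group_col, value_col]].dropna()
    groups = {g: sub[value_col].values for g, sub in df.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    small = [g for g, v in groups.items() if len(v) < 2]
    arrays = [v for g, v in sorted(groups.items()) if g not in small]
    names = [g for g in sorted(groups) if g not in small]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups with >= 2 replicates")
    f_stat, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "diff": float(np.mean(arrays[j]) - np.mean(arrays[i])),
                "p_adj": float(tk.pvalue[i, j]),
                "flagged_small_group": False,
            })
    for g in small:
        for other in names:
            rows.append({"group_a": g, "group_b": other, "diff": np.nan,
                         "p_adj": np.nan, "flagged_small_group": True})
    return GroupComparison(trait=value_col, f_statistic=float(f_stat),
                           p_value=float(p), pairwise=pd.DataFrame(rows))


@dataclass
class AssociationResult:
    """An OLS fit of expression change on gene traits.

    ``coefficients`` rows: predictor, estimate, se, p_value, plus an
    intercept row. ``influence`` (pathway fits) holds leave-one-out slope
    changes per point for the first predictor.
    """

    predictors: list[str]
    coefficients: pd.DataFrame
    r_squared: float
    n_points: int
    points: pd.DataFrame | None = None
    influence: pd.DataFrame | None = None
    excluded: list[str] = field(default_factory=list)


def _ols(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.DataFrame, float, object]:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.values) < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax() if len(X.columns) > 1 else (X.columns[0],) * 2
        raise ValueError(f"rank-deficient design; collinear predictors: {sorted(set(pair))}")
    fit = sm.OLS(y, Xc).fit()
    coefs = pd.DataFrame({
        "predictor": Xc.columns,
        "estimate": fit.params.values,
        "se": fit.bse.values,
        "p_value": fit.pvalues.values,
    })
    return coefs, float(fit.rsquared), fit


def regress_lfc_on_traits(
    de_table: pd.DataFrame,
    traits: pd.DataFrame,
    predictors: list[str],
    lfc_col: str = "lfc",
) -> AssociationResult:
    """Multiple linear regression of per-feature LFC on trait predictors.

    ``de_table`` and ``traits`` are joined on their index (feature id).
    """
    joined = traits.join(de_table[[lfc_col]], how="inner").dropna(
        subset=predictors + [lfc_col])
    if len(joined) < len(predictors) + 2:
        raise ValueError(
            f"only {len(joined)} matched features for {len(predictors)} predictors")
    coefs, r2, _ = _ols(joined[lfc_col].values, joined[predictors])
    return AssociationResult(predictors=predictors, coefficients=coefs,
                             r_squared=r2, n_points=len(joined))


def pathway_level_relation(
    traits: pd.DataFrame,
    de_table: pd.DataFrame,
    pathway_tag: str,
    predictor: str = "fop",
    genome_col: str = "taxon_id",
    exclusions: list[str] | None = None,
    min_genomes: int = 3,
) -> AssociationResult:
    """Genome-level trait vs expression fit for one pathway.

    Per genome, x = mean of ``predictor`` over the genome's pathway genes
    and y = mean LFC over those genes — one point per genome — then an OLS
    fit of y on x. Listed genomes are excluded from the fit but their
    points are still emitted; leave-one-out slope influence is reported so
    a single extreme genome dominating the relationship is visible.
    Refuses to fit (slope table empty) below ``min_genomes`` points.
    """
    exclusions = exclusions or []
    tagged = traits[traits["pathway_tags"].fillna("").str.split(";")
                    .apply(lambda tags: pathway_tag in tags)]
    merged = tagged.join(de_table[["lfc"]], how="inner").dropna(
        subset=[predictor, "lfc"])
    pts = merged.groupby(genome_col).agg(
        x=(predictor, "mean"), y=("lfc", "mean"), n_genes=("lfc", "size"),
    ).reset_index()
    fit_pts = pts[~pts[genome_col].isin(exclusions)]
    if len(fit_pts) < min_genomes:
        return AssociationResult(
            predictors=[predictor],
            coefficients=pd.DataFrame(columns=["predictor", "estimate", "se", "p_value"]),
            r_squared=float("nan"), n_points=len(fit_pts),
            points=pts, excluded=list(exclusions),
        )
    coefs, r2, _ = _ols(fit_pts["y"].values, fit_pts[["x"]].rename(columns={"x": predictor}))
    slope = coefs.loc[coefs["predictor"] == predictor, "estimate"].iloc[0]
    infl_rows = []
    if len(fit_pts) > min_genomes:
        for _, row in fit_pts.iterrows():
            sub = fit_pts[fit_pts[genome_col] != row[genome_col]]
            c_sub, _, _ = _ols(sub["y"].values,
                               sub[["x"]].rename(columns={"x": predictor}))
            s_sub = c_sub.loc[c_sub["predictor"] == predictor, "estimate"].iloc[0]
            infl_rows.append({genome_col: row[genome_col],
                              "slope_without": s_sub,
                              "slope_change": slope - s_sub})
    influence = pd.DataFrame(infl_rows) if infl_rows else None
    return AssociationResult(predictors=[predictor], coefficients=coefs,
                             r_squared=r2, n_points=len(fit_pts), points=pts,
                             influence=influence, excluded=list(exclusions))


def export_codon_matrix(
    genes_traits: pd.DataFrame,
    sequences: dict[str, str],
    pathway_tag: str | None = None,
    genome_col: str = "taxon_id",
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Genome x sense-codon frequency matrix for ordination input.

    Rows are genomes, columns the 61 sense codons; each row's frequencies
    are normalized within synonymous family blocks (family block sums are 1
    wherever the family is observed). Restricting to ``pathway_tag`` uses
    only that pathway's genes.
    """
    code = code or default_code()
    from .traits import profile  # late import; cheap

    df = genes_traits
    if pathway_tag is not None:
        df = df[df["pathway_tags"].fillna("").str.split(";")
                .apply(lambda tags: pathway_tag in tags)]
    sense = code.sense_codons
    rows = {}
    for genome, grp in df.groupby(genome_col):
        counts = dict.fromkeys(sense, 0.0)
        for gid in grp["gene_id"]:
            if gid not in sequences:
                continue
            for codon, n in profile(sequences[gid], code).O_c.items():
                counts[codon] += n
        freq = {}
        for aa, fam in code.families().items():
            fam_codons = sorted(fam.codons)
            tot = sum(counts[c] for c in fam_codons)
            for c in fam_codons:
                freq[c] = counts[c] / tot if tot > 0 else 0.0
        rows[genome] = freq
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(sense))
    out.index.name = genome_col
    return out.sort_index()
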