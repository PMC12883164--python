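# Methods

## Model and procedure

The package treats a microbial community metatranscriptome experiment as a
pipeline over four objects: coding sequences with taxon/function labels and
per-gene read depths; per-taxon reference codon frequencies; per-transcript
gene traits; and a genes × samples transcript count matrix with a two-arm
design. The scientific question is whether gene traits — codon optimization
relative to the taxon's genomic background, synonymous-site nucleotide
composition, and the cost of encoded amino acids — predict transcriptional
response to a perturbation.

### Genetic code and site classes

All calculations use NCBI translation table 11 (bacteria/archaea); its
sense/stop assignments equal the standard code, and the table is loadable
from a plain-text file for other codes. A codon position is
*fourfold-degenerate* ("synonymous site") when all three single-nucleotide
substitutions preserve the residue, *nonsynonymous* when all three change
it; remaining positions are *mixed* and enter the total-gene nucleotide
pool but neither restricted pool. Codons containing non-ACGT characters are
skipped and tallied, never silently dropped; RNA input is converted to the
DNA sense-strand convention (T for U) on read.

### Reference frequencies

Per taxon, each codon occurrence in the metagenome gene set contributes its
gene's mean read depth (or 1, unweighted) to a codon count table. Taxa
whose depth-adjusted total falls below 750,000 codons are removed (boundary
kept); genes shorter than 80 codons are excluded from trait calculation
(boundary kept). Within each synonymous family, frequencies *f_c* are
normalized counts; CAI weights are *w_c = f_c / max f*; the family argmax
set is the FOP optimal set (ties mark all tied codons optimal). The MILC
and ENC′ expectation *g_c* equals *f_c* — one reference serves every index.
Species-level tables can be aggregated to phylum level by summation before
reference building; the two orders commute.

**Pseudocount.** 0.5 per codon is added within a family only when at least
one member is unobserved. Fully observed families are therefore exact
(reproducing printed worked examples), while unobserved codons never get
weight 0, which would collapse the CAI geometric mean. With pseudocount 0,
a fully unobserved family has undefined (NaN) weights and index evaluation
raises with a pseudocount advisory.

### Gene traits

CAI is computed in log space, `exp(Σ O_c ln w_c / L)`; single-codon
families (Met/Trp, weight 1) are included in *L*. MILC follows the
per-amino-acid log-likelihood form with the short-sequence correction
summed over amino acids present in the transcript. ENC′ converts each
multi-codon family's chi-square deviation from *g* into a corrected
homozygosity `F′ = (χ² + L_a − r_a)/(r_a (L_a − 1))` (families need ≥ 2
codons observed), averages F′ within degeneracy classes, and combines
`ENC′ = 2 + 9/F̄′₂ + 1/F̄′₃ + 5/F̄′₄ + 3/F̄′₆`, clamped to [1, 61]; a missing
threefold class borrows the mean of the two- and fourfold classes, any
other missing class yields NaN. Amino-acid mean synthesis cost (~P bonds
per residue) and molar C:N come from editable TSV tables of per-residue
cost and elemental composition packaged with the library; no cost value is
hard-coded in logic. Undefined traits propagate as NaN so weighted
summaries renormalize over defined genes.

### Differential expression

A deliberately simplified negative-binomial two-arm comparison: size
factors by median-of-ratios over features expressed in all samples
(geometric-mean scaled to 1); per-feature dispersion by method of moments
`(var − µ)/µ²` pooled across arms, moderated toward the mean dispersion of
features of similar expression (tertiles of base mean) — full pooling below
4 replicates per arm, 70% weight otherwise, blended arithmetically. The
moderation strength was set so the null rejection rate of the Wald test is
near its nominal 5% at 4 replicates per arm; unmoderated moment estimates
at that sample size produce near-zero variances for some features and a
~10% false-positive rate. LFC is `log2` of the ratio of normalized arm
means (0.5-count offset when an arm mean is 0, flagged); `z = lfc/se` with
the delta-method standard error `var(log2 µ̂) ≈ (1/µ + disp)/(n ln²2)` is
referred to the standard normal, two-sided; q-values are
Benjamini–Hochberg; significance means FDR < 0.1. There is no dispersion
shrinkage toward a fitted trend curve, no LFC shrinkage, and no outlier
refitting — the calibration and recovery tests on synthetic truth, not
bit-agreement with any external tool, define correctness. Known
consequence: when effects are not balanced around zero, median-of-ratios
normalization absorbs part of the net shift into the size factors, biasing
all LFCs by a common constant; slopes of LFC on traits are unaffected.

### Trait summarization and association

Community trait means weight each gene by its normalized transcript count
in the sample (expression weighting, the default for metatranscriptome
figures) or by DNA depth (metagenome weighting). Group differences use
one-way ANOVA with Tukey-HSD pairwise comparisons (studentized range);
groups with a single replicate are flagged and excluded from pairwise
tests. Per-feature trait–LFC links use OLS with analytic standard errors;
rank-deficient designs are rejected naming the collinear predictors. The
pathway-level analysis averages a pathway's gene traits and LFCs within
each genome (one point per genome) and fits OLS across genomes — fits are
refused below 3 genomes (points still emitted) — reporting leave-one-out
slope influence so a single extreme genome dominating the relationship is
visible; exclusions are explicit configuration, never automatic outlier
deletion. A genome × 61-codon frequency matrix (family-block normalized)
is exported for ordination; ordination itself is out of scope.

## Synthetic community generator

The generator emulates the statistical structure the pipeline must detect,
not sequencing realism. Per taxon, each synonymous family's preference
vector is Dirichlet with per-codon concentration `1/bias_strength`
(`bias_strength = 0` is exactly uniform; the default 5 gives clearly
differentiated preferences). Per gene: a latent optimization level *t*
uniform on [0.05, 0.95]; residues uniform over the 20 amino acids; codons
drawn from `t·preference + (1−t)·uniform`, so no in-frame stops occur;
length uniform on 100–400 codons (above the 80-codon filter, which tests
exercise with explicit short-gene constructions); depth log-normal
(µ_log = 4.5, σ = 1, mean ≈ 90×), making default per-taxon codon totals
(~1–3 M) clear the 750,000 filter. Counts are negative-binomial
(variance `µ + 0.1 µ²`, control means log-normal around 50) with 4
replicates per arm; the treatment mean is the control mean times
`2^true_lfc`, where `true_lfc = α + β·t + N(0, 0.25)` for growth-pathway
genes (defaults α = 1, β = 2) and `α + N(0, 0.25)` for stress (α = 1,
β = 0) and background (α = 0) genes. Pathway classes are assigned
20/20/60%. A single integer seed drives hierarchical substreams
(profiles/genes/effects/counts), making all outputs byte-identical across
runs.

**What it does not emulate:** read-level noise, assembly and binning
artifacts, chimeras, taxon abundance skew beyond depth, uneven amino-acid
usage, within-genome trait structure (operons, HGT islands), or shifts in
the tRNA pool under stress. Passing recovery tests therefore demonstrates
that the estimators detect the planted trait–expression coupling under the
stated noise model — not that real soil communities behave this way.

## Problem sizes and numerical choices

Test and analysis runs use 30 taxa × 50 genes (1,500 genes, 8 samples) for
end-to-end recovery and 2,000 features for null calibration — sizes chosen
so the full suite runs in minutes on one core while leaving estimator
noise realistic. Oracle-equivalence tests compare against independent
brute-force implementations at 1e−12 (CAI, FOP, MILC, composition) and
1e−9 (ENC′). The generator's recovery behavior was characterized across a
21-seed sweep: the stress-pathway null is rejected at the 5% level in 1/21
seeds (nominal), and growth-pathway power is high but not unity. Default
seeds are 0 everywhere. Ties for the family-optimal codon mark all tied
codons optimal (so a uniform reference gives FOP = 1); the
lexicographically first tied codon is reported in summaries.

## Known limitations

- CAI measured against a taxon's own genomic background is self-referential:
  taxa with weak overall codon bias have flat references and score high CAI
  for every gene, so CAI comparisons are most meaningful within a taxon or
  among taxa of comparable bias.
- The Wald test's normal reference is approximate at very small replicate
  counts; moderation trades per-feature dispersion resolution for
  calibration.
- Pathway fits assume one point per genome with equal weight regardless of
  how many genes support it; the gene count per genome is reported but not
  used as a weight.
- The amino-acid cost table is organism-agnostic; costs differ across
  metabolic lifestyles and conditions. The table ships as data and is
  user-replaceable.
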