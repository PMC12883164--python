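# genetraits

Gene traits — codon optimization, synonymous-site nucleotide composition,
and amino-acid cost — linked to transcriptional responses in soil microbial
community metatranscriptomes.

Highly expressed genes tend to use the synonymous codons their host prefers
and energetically cheaper nucleotides and amino acids. This package builds
the machinery to test that prediction at community scale: per-taxon
"genomic background" codon-frequency references from metagenome coding
sequences, per-transcript optimization indices, differential expression
between treatments, and the association of pathway-averaged traits with
expression change. A synthetic community generator with known ground truth
stands in for sequencing data, so every stage is testable end to end.

## The statistics at the core

Against a taxon reference with within-family codon frequencies *f_c*:

- **CAI** (codon adaptation index): per-codon weights
  *w_c = f_c / max(f of synonymous codons)*, combined as the geometric mean
  over the transcript's *L* codons, `CAI = (Π w_c)^(1/L)`. A family with
  frequencies 0.2/0.8 gives weights 0.25/1.
- **FOP** (frequency of optimized codons): the fraction of codons that are
  the most frequent codon of their synonymous family in the reference.
- **MILC**: per amino acid, `M_a = Σ_c O_c ln(f_c,obs / g_c)` with *O_c*
  the codon counts and *g_c* the reference expectation;
  `MILC = Σ_a M_a / L − C` with the short-sequence correction
  `C = Σ_a (r_a − 1)/L − 0.5` over the amino acids present (*r_a* = family
  size). Values near 0 mean usage matching the reference.
- **ENC′**: background-corrected effective number of codons, from
  chi-square–corrected family homozygosities; ~20 at extreme bias, 61 at
  usage indistinguishable from background.
- **Nucleotide skews** at fourfold-degenerate (synonymous) sites:
  `GC skew = (G−C)/(G+C)`, `AT skew = (A−T)/(A+T)` on the sense strand.
- **Amino-acid cost**: mean high-energy phosphate bonds (~P) per encoded
  residue, plus the molar C:N of the residues.

References are depth-weighted codon counts per taxon; taxa under 750,000
depth-adjusted codons and genes under 80 codons are excluded. Differential
expression uses median-of-ratios normalization, moderated method-of-moments
negative-binomial dispersions, a Wald test, and Benjamini–Hochberg FDR
(significance at FDR < 0.1).

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic community (30 taxa × 50 genes, growth-pathway expression coupled
to optimization with slope β = 2, stress pathway uncoupled):

```sh
python analysis/01_simulate.py            # writes results/data/
python analysis/02_build_references.py
python analysis/03_gene_traits.py
python analysis/04_differential_expression.py
python analysis/05_trait_associations.py
```

The final step prints (seed 0):

```
transcript-pool fop: control vs treatment F=653.55, p=0.0000
...
per-gene LFC ~ fop + milc: R^2=0.009 over 1500 genes
growth: slope 4.101 +/- 0.607 (p=0.0000, n=30 genomes)
stress: slope -0.031 +/- 0.938 (p=0.9735, n=30 genomes)
```

Read: the transcript pool's count-weighted mean optimization rises under
treatment; single-gene traits barely predict single-gene expression change
(R² ≈ 0.01); but averaging over a pathway's genes within each genome
recovers a strong positive optimization–expression slope exactly where the
generator planted one (growth) and none where it did not (stress). The
genome-level slope (≈4.1 per unit FOP) exceeds the generative β = 2 per
unit *optimization* because FOP spans a narrower range than the latent
optimization level.

Equivalent single calls: `genetraits.run_all(PipelineConfig(...))` or the
stage functions in `genetraits.reference`, `.traits`, `.de`,
`.association`.

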