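"""Synthetic metagenome/metatranscriptome community with known ground truth.

The generator emulates the statistical structure the pipeline is built to
detect, without any sequencing data:

* taxa with distinct synonymous codon preference profiles (one Dirichlet
  draw per synonymous family, concentration 1/bias_strength so larger
  bias_strength gives spikier preferences; bias_strength 0 is exactly
  uniform);
* genes spanning a range of codon optimization: each gene draws its codons
  family-by-family from the mixture
  ``t · taxon preference + (1 − t) · uniform`` where ``t``, the gene's
  true optimization level, is uniform over the configured range;
* log-normal per-gene read depths;
* negative-binomial transcript counts whose treatment-arm mean is the
  control mean times ``2^true_lfc``, with
  ``true_lfc = alpha + beta · t + noise`` for genes of designated "growth"
  pathways and ``alpha + noise`` (no trait coupling) for "stress" and
  background genes.

A single integer seed drives hierarchical substreams (profiles / genes /
depths / counts), so every output is reproducible and partial regeneration
is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import GeneticCode, default_code
from .io import CodingSequence
from .de import CountMatrix

GROWTH = "growth"
STRESS = "stress"
BACKGROUND = "background"


@dataclass
class EffectModel:
    """Linear link from a gene's optimization level to its true LFC."""

    alpha: float = 0.0
    beta: float = 0.0


@dataclass
class GeneratorConfig:
    """Conditions of the synthetic community.

    Defaults describe a moderate soil-like community: 30 taxa of 50 genes,
    clearly differentiated codon preferences (bias_strength 5), gene
    lengths 100–400 codons (above the 80-codon analysis filter), log-normal
    depths, negative-binomial counts of mean ~50 and dispersion 0.1 with 4
    replicates per arm, and a growth-pathway effect of beta = 2 (LFC rises
    by 2 log2 units across the optimization range) against beta = 0 for the
    stress pathway.
    """

    n_taxa: int = 30
    genes_per_taxon: int = 50
    bias_strength: float = 5.0
    optimization_range: tuple[float, float] = (0.05, 0.95)
    length_range_codons: tuple[int, int] = (100, 400)
    depth_lognorm_mean: float = 4.5
    depth_lognorm_sigma: float = 1.0
    count_mean: float = 50.0
    count_dispersion: float = 0.1
    lfc_noise_sd: float = 0.25
    effect_models: dict[str, EffectModel] = field(default_factory=lambda: {
        GROWTH: EffectModel(alpha=1.0, beta=2.0),
        STRESS: EffectModel(alpha=1.0, beta=0.0),
        BACKGROUND: EffectModel(alpha=0.0, beta=0.0),
    })
    pathway_fractions: dict[str, float] = field(default_factory=lambda: {
        GROWTH: 0.2, STRESS: 0.2, BACKGROUND: 0.6,
    })
    treatments: tuple[str, str] = ("control", "treatment")
    replicates: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        lo, hi = self.optimization_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("optimization_range must lie within [0, 1]")
        if abs(sum(self.pathway_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("pathway_fractions must sum to 1")


def _streams(seed: int, *keys: int) -> np.random.Generator:
    """Independent substream keyed by (seed, *keys)."""
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated community."""

    genes: pd.DataFrame           # gene_id, taxon_id, pathway_class, true_optimization, true_lfc
    profiles: dict[str, dict[str, np.ndarray]]   # taxon -> {aa: probability vector}

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def generate_reference_profiles(
    config: GeneratorConfig,
    code: GeneticCode | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """One synonymous-preference probability vector per taxon and family.

    Dirichlet concentration per codon is ``1 / bias_strength``; the limit
    bias_strength -> 0 is handled exactly as the uniform profile.
    """
    config.validate()
    code = code or default_code()
    families = code.families()
    profiles: dict[str, dict[str, np.ndarray]] = {}
    for i in range(config.n_taxa):
        rng = _streams(config.seed, 1, i)
        prof: dict[str, np.ndarray] = {}
        for aa, fam in families.items():
            r = fam.r_a
            if config.bias_strength == 0 or r == 1:
                prof[aa] = np.full(r, 1.0 / r)
            else:
                prof[aa] = rng.dirichlet(np.full(r, 1.0 / config.bias_strength))
        profiles[f"taxon{i:03d}"] = prof
    return profiles


def generate_genes(
    config: GeneratorConfig,
    profiles: dict[str, dict[str, np.ndarray]],
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Draw gene sequences and their truth rows (optimization, pathway, depth).

    Residues are uniform over the 20 amino acids; codons come from the
    per-gene mixture of taxon preference and uniform usage, so no in-frame
    stops can occur.
    """
    config.validate()
    code = code or default_code()
    families = code.families()
    aas = sorted(families)
    fam_codons = {aa: sorted(families[aa].codons) for aa in aas}
    lo, hi = config.optimization_range
    classes = sorted(config.pathway_fractions)
    class_p = np.array([config.pathway_fractions[c] for c in classes])
    genes: list[CodingSequence] = []
    rows = []
    for ti, (taxon, prof) in enumerate(sorted(profiles.items())):
        rng = _streams(config.seed, 2, ti)
        for gi in range(config.genes_per_taxon):
            t = rng.uniform(lo, hi)
            pathway = rng.choice(classes, p=class_p)
            length = rng.integers(config.length_range_codons[0],
                                  config.length_range_codons[1] + 1)
            depth = rng.lognormal(config.depth_lognorm_mean,
                                  config.depth_lognorm_sigma)
            residues = rng.integers(0, len(aas), size=length)
            parts = []
            for ai in range(len(aas)):
                n_ai = int((residues == ai).sum())
                if n_ai == 0:
                    continue
                aa = aas[ai]
                p = t * prof[aa] + (1 - t) / len(fam_codons[aa])
                p = p / p.sum()
                draws = rng.choice(len(fam_codons[aa]), size=n_ai, p=p)
                parts.append((ai, draws))
            codon_picks = np.empty(length, dtype=object)
            for ai, draws in parts:
                idx = np.flatnonzero(residues == ai)
                codons = fam_codons[aas[ai]]
                codon_picks[idx] = [codons[d] for d in draws]
            seq = "".join(codon_picks.tolist())
            gene_id = f"{taxon}_g{gi:04d}"
            tag = frozenset() if pathway == BACKGROUND else frozenset({pathway})
            genes.append(CodingSequence(
                gene_id=gene_id, sequence=seq, taxon_id=taxon,
                ko_id=f"K{ {GROWTH: 10000, STRESS: 40000, BACKGROUND: 70000}[pathway] + gi:05d}",
                pathway_tags=tag, depth=float(depth),
            ))
            rows.append({"gene_id": gene_id, "taxon_id": taxon,
                         "pathway_class": pathway, "true_optimization": t,
                         "length_codons": int(length), "depth": float(depth)})
    truth = pd.DataFrame(rows)
    return genes, truth


def assign_true_lfc(config: GeneratorConfig, truth: pd.DataFrame) -> pd.DataFrame:
    """Add the true log2-fold change column from the per-pathway effect model."""
    rng = _streams(config.seed, 3)
    noise = rng.normal(0.0, config.lfc_noise_sd, size=len(truth))
    lfc = np.empty(len(truth))
    for i, row in enumerate(truth.itertuples()):
        em = config.effect_models.get(row.pathway_class, EffectModel())
        coupled = em.beta * row.true_optimization if row.pathway_class == GROWTH else 0.0
        lfc[i] = em.alpha + coupled + noise[i]
    out = truth.copy()
    out["true_lfc"] = lfc
    return out


def generate_counts(
    config: GeneratorConfig,
    truth: pd.DataFrame,
) -> CountMatrix:
    """Negative-binomial counts for both arms given the truth table.

    Per gene, a log-normal control mean around ``count_mean``; the
    treatment mean is the control mean times ``2^true_lfc``; counts are NB
    with variance ``µ + disp·µ²``.
    """
    config.validate()
    if "true_lfc" not in truth.columns:
        raise ValueError("truth table lacks true_lfc; run assign_true_lfc first")
    rng = _streams(config.seed, 4)
    n = len(truth)
    base = rng.lognormal(np.log(config.count_mean), 0.5, size=n)
    disp = config.count_dispersion
    control, treatment = config.treatments
    cols = {}
    design_rows = []
    for arm, mu_arm in ((control, base),
                        (treatment, base * 2.0 ** truth["true_lfc"].values)):
        for rep in range(1, config.replicates + 1):
            # NB via gamma-Poisson: shape 1/disp, scale mu*disp
            lam = rng.gamma(1.0 / disp, mu_arm * disp)
            cols[f"{arm}_{rep}"] = rng.poisson(lam)
            design_rows.append({"sample_id": f"{arm}_{rep}",
                                "treatment": arm, "replicate": rep})
    counts = pd.DataFrame(cols, index=truth["gene_id"].values)
    counts.index.name = "gene_id"
    design = pd.DataFrame(design_rows).set_index("sample_id")
    return CountMatrix(counts=counts, design=design)


def generate_community(
    config: GeneratorConfig | None = None,
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], SyntheticTruth, CountMatrix]:
    """Full community: sequences, truth (with true LFC), count matrix."""
    config = config or GeneratorConfig()
    profiles = generate_reference_profiles(config, code)
    genes, truth = generate_genes(config, profiles, code)
    truth = assign_true_lfc(config, truth)
    cm = generate_counts(config, truth)
    return genes, SyntheticTruth(genes=truth, profiles=profiles), cm


def write_community(
    outdir: str | Path,
    genes: list[CodingSequence],
    truth: SyntheticTruth,
    cm: CountMatrix,
) -> dict[str, Path]:
    """Emit the community as the pipeline's plain-text input files."""
    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds": outdir / "cds.fasta",
        "annotations": outdir / "annotations.tsv",
        "depths": outdir / "depths.tsv",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
    }
    gio.write_fasta({g.gene_id: g.sequence for g in genes}, paths["cds"])
    pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "taxon_id": [g.taxon_id for g in genes],
        "ko_id": [g.ko_id or "" for g in genes],
        "pathway_tags": [";".join(sorted(g.pathway_tags)) for g in genes],
    }).to_csv(paths["annotations"], sep="\t", index=False)
    pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "depth": [g.depth for g in genes],
    }).to_csv(paths["depths"], sep="\t", index=False)
    cm.counts.to_csv(paths["counts"], sep="\t")
    cm.design.to_csv(paths["design"], sep="\t")
    truth.to_tsv(paths["truth"])
    return paths
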