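"""Per-transcript gene traits.

Four codon-optimization indices are computed against a taxon's genomic
background reference:

* **CAI** — geometric mean over the transcript's codons of the reference
  weight ``w_c`` (codon frequency over the maximum frequency in its
  synonymous family). 1 means every codon is the taxon's preferred one.
* **FOP** — fraction of codons that are in the reference's optimal set.
* **MILC** — sum over amino acids of ``M_a = Σ O_c ln(f_obs/g_c)`` divided
  by transcript length, minus the short-sequence correction
  ``C = Σ(r_a − 1)/L − 0.5``. Values near 0 mean usage matching the
  reference.
* **ENC′** — background-corrected effective number of codons: per-family
  chi-square deviation of observed usage from the reference converts to a
  corrected homozygosity ``F′``, combined over degeneracy classes into a
  value from ~20 (one codon per family) to 61 (usage at background).

Nucleotide composition (GC content, GC skew ``(G−C)/(G+C)``, AT skew
``(A−T)/(A+T)``) is reported for all sites and restricted to the
fourfold-degenerate ("synonymous") and strictly nonsynonymous site pools.
Encoded amino-acid traits are the mean biosynthetic cost in high-energy
phosphate bonds per residue and the molar C:N ratio of the residues.

Traits that are undefined for a transcript (empty site pool, no estimable
family) are NaN, never 0, so weighted averages can renormalize over the
genes where the trait exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .genetic_code import (
    STOP,
    GeneticCode,
    SiteClass,
    default_code,
    iter_codons,
)
from .io import CodingSequence
from .reference import ReferenceFrequencies


@dataclass
class TranscriptCodonProfile:
    """Observed codon composition of one transcript.

    ``O_c`` counts sense codons only; stop and ambiguous codons are tallied
    separately and excluded from the length ``L``.
    """

    O_c: dict[str, int]
    n_stop: int = 0
    n_ambiguous: int = 0

    @property
    def L(self) -> int:
        return sum(self.O_c.values())


@dataclass
class AminoAcidTables:
    """Residue-level biosynthetic cost (~P bonds) and elemental composition."""

    cost: dict[str, float]
    composition: dict[str, dict[str, int]]

    @classmethod
    def default(cls) -> "AminoAcidTables":
        cost_ref = resources.files("genetraits.data") / "aa_cost.tsv"
        comp_ref = resources.files("genetraits.data") / "aa_composition.tsv"
        with resources.as_file(cost_ref) as p_cost, resources.as_file(comp_ref) as p_comp:
            return cls.from_files(p_cost, p_comp)

    @classmethod
    def from_files(cls, cost_path: str | Path, comp_path: str | Path) -> "AminoAcidTables":
        cost_df = pd.read_csv(cost_path, sep="\t").set_index("residue")
        comp_df = pd.read_csv(comp_path, sep="\t").set_index("residue")
        if len(cost_df) != 20 or len(comp_df) != 20:
            raise ValueError("amino-acid tables must have 20 residues")
        if (cost_df["cost"] <= 0).any():
            raise ValueError("amino-acid costs must be positive")
        return cls(
            cost=cost_df["cost"].to_dict(),
            composition={r: row.to_dict() for r, row in comp_df.iterrows()},
        )


def profile(sequence: str, code: GeneticCode | None = None) -> TranscriptCodonProfile:
    """Count each sense codon of a CDS; skip (and tally) stops and ambiguity."""
    code = code or default_code()
    if not sequence:
        raise ValueError("empty sequence")
    stops = code.stop_codons
    O_c: dict[str, int] = {}
    prof = TranscriptCodonProfile(O_c=O_c)
    for codon in iter_codons(sequence):
        if codon in stops:
            prof.n_stop += 1
        elif codon in code.codon_to_aa:
            O_c[codon] = O_c.get(codon, 0) + 1
        else:
            prof.n_ambiguous += 1
    return prof


def cai(prof: TranscriptCodonProfile, ref: ReferenceFrequencies) -> float:
    """Codon Adaptation Index: geometric mean of reference weights w_c."""
    if prof.L == 0:
        return float("nan")
    log_sum = 0.0
    for codon, n in prof.O_c.items():
        w = ref.w_c[codon]
        if not w > 0.0:  # catches 0 and NaN (undefined family)
            raise ValueError(
                f"codon {codon} has reference weight 0; rebuild the reference "
                "with a positive pseudocount"
            )
        log_sum += n * math.log(w)
    return math.exp(log_sum / prof.L)


def fop(prof: TranscriptCodonProfile, ref: ReferenceFrequencies) -> float:
    """Frequency of optimized codons: fraction of codons in the optimal set."""
    if prof.L == 0:
        return float("nan")
    n_opt = sum(n for codon, n in prof.O_c.items() if codon in ref.optimal)
    return n_opt / prof.L


def milc(prof: TranscriptCodonProfile, ref: ReferenceFrequencies) -> float:
    """MILC bias of the transcript against the reference expected frequencies.

    The correction sum Σ(r_a − 1) runs over the amino acids present in the
    transcript.
    """
    if prof.L == 0:
        return float("nan")
    code = ref.code
    by_aa: dict[str, dict[str, int]] = {}
    for codon, n in prof.O_c.items():
        by_aa.setdefault(code.codon_to_aa[codon], {})[codon] = n
    m_sum = 0.0
    corr_sum = 0.0
    for aa, obs in by_aa.items():
        fam = code.synonymous_family(aa)
        L_a = sum(obs.values())
        for codon, n in obs.items():
            g = ref.g_c[codon]
            if not g > 0.0:
                raise ValueError(
                    f"codon {codon} has expected frequency 0; rebuild the "
                    "reference with a positive pseudocount"
                )
            m_sum += n * math.log((n / L_a) / g)
        corr_sum += fam.r_a - 1
    c = corr_sum / prof.L - 0.5
    return m_sum / prof.L - c


def enc_prime(
    prof: TranscriptCodonProfile,
    ref: ReferenceFrequencies,
    min_family_count: int = 2,
) -> float:
    """Background-corrected effective number of codons (ENC′).

    For each multi-codon family with at least ``min_family_count`` codons in
    the transcript, the chi-square deviation of observed codon usage from
    the reference frequencies gives a corrected homozygosity
    ``F′ = (χ² + L_a − r_a) / (r_a (L_a − 1))``. Class averages of F′ over
    families of equal degeneracy combine as
    ``ENC′ = 2 + 9/F̄′₂ + 1/F̄′₃ + 5/F̄′₄ + 3/F̄′₆`` (bacterial code class
    sizes). A missing threefold class borrows the mean of the two- and
    fourfold averages; if any other class is missing the value is NaN
    (insufficient data). The result is clamped to [1, 61].
    """
    if prof.L == 0:
        return float("nan")
    code = ref.code
    by_aa: dict[str, dict[str, int]] = {}
    for codon, n in prof.O_c.items():
        by_aa.setdefault(code.codon_to_aa[codon], {})[codon] = n
    f_prime: dict[int, list[float]] = {}
    for aa, fam in code.families().items():
        r = fam.r_a
        if r == 1:
            continue
        obs = by_aa.get(aa)
        if obs is None:
            continue
        L_a = sum(obs.values())
        if L_a < max(min_family_count, 2):
            continue
        chi2 = 0.0
        for codon in fam.codons:
            g = ref.g_c[codon]
            if not g > 0.0:
                raise ValueError(
                    f"codon {codon} has expected frequency 0; rebuild the "
                    "reference with a positive pseudocount"
                )
            o = obs.get(codon, 0)
            chi2 += (o - L_a * g) ** 2 / (L_a * g)
        f_prime.setdefault(r, []).append((chi2 + L_a - r) / (r * (L_a - 1)))
    class_sizes = {2: 9, 3: 1, 4: 5, 6: 3}
    means = {r: float(np.mean(v)) for r, v in f_prime.items() if v}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2.0
    if not all(r in means and means[r] > 0 for r in class_sizes):
        return float("nan")
    enc = 2.0 + sum(n / means[r] for r, n in class_sizes.items())
    return float(min(max(enc, 1.0), 61.0))


def _site_pool(sequence: str, site_filter: SiteClass | None,
               code: GeneticCode) -> list[str]:
    """Nucleotides of a CDS at positions matching the site filter.

    ``None`` selects every position of every sense codon (total-gene pool);
    stop and ambiguous codons contribute to no pool.
    """
    pool: list[str] = []
    stops = code.stop_codons
    for codon in iter_codons(sequence):
        if codon in stops or codon not in code.codon_to_aa:
            continue
        if site_filter is None:
            pool.extend(codon)
        else:
            for pos in (1, 2, 3):
                if code.classify_site(codon, pos) is site_filter:
                    pool.append(codon[pos - 1])
    return pool


def gc_content(sequence: str, site_filter: SiteClass | None = None,
               code: GeneticCode | None = None) -> float:
    """(G+C)/(A+C+G+T) over the selected site pool; NaN on an empty pool."""
    pool = _site_pool(sequence, site_filter, code or default_code())
    if not pool:
        return float("nan")
    gc = sum(1 for nt in pool if nt in "GC")
    return gc / len(pool)


def gc_skew(sequence: str, site_filter: SiteClass | None = None,
            code: GeneticCode | None = None) -> float:
    """(G−C)/(G+C) on the sense strand over the selected site pool."""
    pool = _site_pool(sequence, site_filter, code or default_code())
    g = sum(1 for nt in pool if nt == "G")
    c = sum(1 for nt in pool if nt == "C")
    if g + c == 0:
        return float("nan")
    return (g - c) / (g + c)


def at_skew(sequence: str, site_filter: SiteClass | None = None,
            code: GeneticCode | None = None) -> float:
    """(A−T)/(A+T) on the sense strand over the selected site pool."""
    pool = _site_pool(sequence, site_filter, code or default_code())
    a = sum(1 for nt in pool if nt == "A")
    t = sum(1 for nt in pool if nt == "T")
    if a + t == 0:
        return float("nan")
    return (a - t) / (a + t)


def amino_acid_traits(
    residues: str,
    tables: AminoAcidTables | None = None,
    strict: bool = False,
) -> tuple[float, float]:
    """Mean synthesis cost (~P per residue) and molar C:N of a residue string.

    Unknown residues are skipped (tallied via the returned NaN path) unless
    ``strict``; stop markers are always ignored.
    """
    tables = tables or AminoAcidTables.default()
    total_cost = 0.0
    total_c = 0
    total_n = 0
    n_res = 0
    for r in residues:
        if r == STOP:
            continue
        if r not in tables.cost:
            if strict:
                raise ValueError(f"unknown residue: {r!r}")
            continue
        total_cost += tables.cost[r]
        total_c += tables.composition[r]["C"]
        total_n += tables.composition[r]["N"]
        n_res += 1
    if n_res == 0:
        return float("nan"), float("nan")
    cn = total_c / total_n if total_n else float("nan")
    return total_cost / n_res, cn


def translate_cds(sequence: str, code: GeneticCode | None = None) -> str:
    """Residue string of a CDS, skipping stop and ambiguous codons."""
    code = code or default_code()
    out = []
    for codon in iter_codons(sequence):
        if codon in code.codon_to_aa:
            aa = code.codon_to_aa[codon]
            if aa != STOP:
                out.append(aa)
    return "".join(out)


#: discard genes shorter than this many codons (low-frequency bias guard)
MIN_GENE_CODONS = 80


def length_filter(genes: list[CodingSequence],
                  min_codons: int = MIN_GENE_CODONS) -> list[CodingSequence]:
    """Keep genes with at least ``min_codons`` codons (boundary kept)."""
    return [g for g in genes if g.length_codons >= min_codons]


@dataclass
class GeneTraits:
    """All per-transcript traits for one gene (NaN marks undefined)."""

    gene_id: str
    taxon_id: str
    n_codons: int
    cai: float
    fop: float
    milc: float
    enc_prime: float
    gc_total: float
    gc_fourfold: float
    gc_nonsyn: float
    gc_skew_fourfold: float
    at_skew_fourfold: float
    aa_mean_cost: float
    aa_cn: float
    n_skipped_codons: int = 0


def compute_traits(
    gene: CodingSequence,
    ref: ReferenceFrequencies,
    aa_tables: AminoAcidTables | None = None,
    code: GeneticCode | None = None,
    with_enc: bool = True,
) -> GeneTraits:
    """Full trait record for one gene against its taxon reference."""
    code = code or default_code()
    aa_tables = aa_tables or AminoAcidTables.default()
    prof = profile(gene.sequence, code)
    cost, cn = amino_acid_traits(translate_cds(gene.sequence, code), aa_tables)
    return GeneTraits(
        gene_id=gene.gene_id,
        taxon_id=gene.taxon_id,
        n_codons=prof.L,
        cai=cai(prof, ref),
        fop=fop(prof, ref),
        milc=milc(prof, ref),
        enc_prime=enc_prime(prof, ref) if with_enc else float("nan"),
        gc_total=gc_content(gene.sequence, None, code),
        gc_fourfold=gc_content(gene.sequence, SiteClass.FOURFOLD_SYNONYMOUS, code),
        gc_nonsyn=gc_content(gene.sequence, SiteClass.NONSYNONYMOUS, code),
        gc_skew_fourfold=gc_skew(gene.sequence, SiteClass.FOURFOLD_SYNONYMOUS, code),
        at_skew_fourfold=at_skew(gene.sequence, SiteClass.FOURFOLD_SYNONYMOUS, code),
        aa_mean_cost=cost,
        aa_cn=cn,
        n_skipped_codons=prof.n_ambiguous,
    )


TRAIT_COLUMNS = [
    "cai", "fop", "milc", "enc_prime", "gc_total", "gc_fourfold", "gc_nonsyn",
    "gc_skew_fourfold", "at_skew_fourfold", "aa_mean_cost", "aa_cn",
]


def traits_table(
    genes: list[CodingSequence],
    references: dict[str, ReferenceFrequencies],
    taxon_of_gene: dict[str, str] | None = None,
    min_codons: int = MIN_GENE_CODONS,
    aa_tables: AminoAcidTables | None = None,
    code: GeneticCode | None = None,
    with_enc: bool = True,
) -> pd.DataFrame:
    """Trait rows for every gene whose taxon has a reference.

    ``taxon_of_gene`` overrides each gene's own taxon label when traits are
    computed against a coarser reference rank (e.g. phylum references for
    species-labelled genes). Genes below the length filter or without a
    reference are omitted.
    """
    code = code or default_code()
    aa_tables = aa_tables or AminoAcidTables.default()
    rows = []
    for gene in length_filter(genes, min_codons):
        taxon = (taxon_of_gene or {}).get(gene.gene_id, gene.taxon_id)
        ref = references.get(taxon)
        if ref is None:
            continue
        t = compute_traits(gene, ref, aa_tables, code, with_enc=with_enc)
        row = {"gene_id": t.gene_id, "taxon_id": taxon, "ko_id": gene.ko_id,
               "pathway_tags": ";".join(sorted(gene.pathway_tags)),
               "depth": gene.depth, "n_codons": t.n_codons}
        row.update({c: getattr(t, c) for c in TRAIT_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)
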