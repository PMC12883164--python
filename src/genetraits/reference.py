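"""Per-taxon "genomic background" codon-frequency references.

Codon optimization indices need a reference describing which synonymous
codons a taxon prefers. Lacking broad tRNA annotation, that reference is
the depth-weighted codon frequency of all coding sequence assigned to the
taxon in the metagenome. Within each synonymous family the frequencies are
normalized to sum to 1 (``f_c``); CAI weights are ``w_c = f_c / max f`` so
the preferred codon of every family has weight 1, and the per-family argmax
codons form the optimal set used by FOP.

Taxa with a total depth-adjusted codon count below 750,000 are removed
before references are built: below that depth the family frequencies are
too noisy to define a preference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .genetic_code import GeneticCode, default_code, iter_codons
from .io import CodingSequence

log = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"

#: total depth-adjusted codons required to keep a taxon's reference
MIN_TAXON_CODONS = 750_000.0


@dataclass
class CodonCountTable:
    """Depth-weighted codon occurrence counts for one taxon."""

    taxon_id: str
    counts: dict[str, float]
    n_stop: float = 0.0
    n_ambiguous: float = 0.0

    @property
    def total_codons(self) -> float:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = dict(self.counts)
        for c, v in other.counts.items():
            merged[c] = merged.get(c, 0.0) + v
        return CodonCountTable(
            taxon_id=self.taxon_id,
            counts=merged,
            n_stop=self.n_stop + other.n_stop,
            n_ambiguous=self.n_ambiguous + other.n_ambiguous,
        )


@dataclass
class ReferenceFrequencies:
    """Per-codon reference quantities for one taxon.

    ``f_c``: frequency of each codon within its synonymous family (sums to
    1 per family). ``w_c``: CAI weight, ``f_c`` over the family maximum.
    ``g_c``: expected frequency under the null used by MILC and ENC′ — equal
    to ``f_c`` under this package's single-reference design. ``optimal``:
    codons attaining the family maximum (all tied codons marked optimal).
    """

    taxon_id: str
    f_c: dict[str, float]
    w_c: dict[str, float]
    optimal: frozenset[str]
    code: GeneticCode = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def g_c(self) -> dict[str, float]:
        return self.f_c

    def optimal_of_family(self, residue: str) -> str:
        """Lexicographically first optimal codon of a family (for reports)."""
        fam = self.code.synonymous_family(residue)
        return min(c for c in fam.codons if c in self.optimal)


def accumulate_counts(
    genes: list[CodingSequence],
    depth_weighted: bool = True,
    code: GeneticCode | None = None,
) -> dict[str, CodonCountTable]:
    """Tally codon occurrences per taxon, each weighted by gene depth.

    Stop and ambiguous codons are tallied separately and never enter the
    sense-codon counts. Genes with no taxon label land in the
    ``"unclassified"`` bucket, which reference building skips.
    """
    code = code or default_code()
    stops = code.stop_codons
    tables: dict[str, CodonCountTable] = {}
    for gene in genes:
        taxon = gene.taxon_id or UNCLASSIFIED
        table = tables.get(taxon)
        if table is None:
            table = tables[taxon] = CodonCountTable(taxon_id=taxon, counts={})
        w = float(gene.depth) if depth_weighted else 1.0
        counts = table.counts
        for codon in iter_codons(gene.sequence):
            if codon in stops:
                table.n_stop += w
            elif codon in code.codon_to_aa:
                counts[codon] = counts.get(codon, 0.0) + w
            else:
                table.n_ambiguous += w
    return tables


def filter_taxa(
    tables: dict[str, CodonCountTable],
    min_total: float = MIN_TAXON_CODONS,
) -> dict[str, CodonCountTable]:
    """Drop taxa whose total depth-adjusted codon count is below ``min_total``.

    The boundary is kept: a taxon at exactly ``min_total`` is retained.
    """
    kept = {t: tab for t, tab in tables.items() if tab.total_codons >= min_total}
    if len(kept) < len(tables):
        log.info("filter_taxa: removed %d of %d taxa below %g codons",
                 len(tables) - len(kept), len(tables), min_total)
    return kept


def aggregate_rank(
    tables: dict[str, CodonCountTable],
    taxon_to_group: dict[str, str],
) -> dict[str, CodonCountTable]:
    """Sum taxon tables into higher-rank (e.g. phylum) tables.

    Taxa missing from the map are excluded with a logged count.
    """
    grouped: dict[str, CodonCountTable] = {}
    n_unmapped = 0
    for taxon, table in tables.items():
        group = taxon_to_group.get(taxon)
        if group is None:
            n_unmapped += 1
            continue
        if group in grouped:
            grouped[group] = grouped[group] + table
            grouped[group].taxon_id = group
        else:
            grouped[group] = CodonCountTable(
                taxon_id=group, counts=dict(table.counts),
                n_stop=table.n_stop, n_ambiguous=table.n_ambiguous,
            )
    if n_unmapped:
        log.warning("aggregate_rank: %d taxa had no group mapping", n_unmapped)
    return grouped


def build_reference(
    table: CodonCountTable,
    pseudocount: float = 0.5,
    code: GeneticCode | None = None,
) -> ReferenceFrequencies:
    """Turn a codon count table into family frequencies, weights and optima.

    The pseudocount is applied per codon within a family *only* when at
    least one family member is unobserved, so fully observed families —
    including printed worked examples — are reproduced exactly while
    unobserved codons never get weight 0 (which would zero out CAI).
    Ties for the family maximum mark every tied codon optimal.
    """
    code = code or default_code()
    if table.total_codons <= 0:
        raise ValueError(f"{table.taxon_id}: reference from empty count table")
    f_c: dict[str, float] = {}
    w_c: dict[str, float] = {}
    optimal: set[str] = set()
    for aa, fam in code.families().items():
        codons = sorted(fam.codons)
        raw = [table.counts.get(c, 0.0) for c in codons]
        pc = pseudocount if min(raw) == 0.0 else 0.0
        if pc == 0.0 and sum(raw) == 0.0:
            # Family never observed and no pseudocount: weights are
            # undefined. Stored as NaN; index calculations raise on use
            # with a pseudocount advisory.
            for c in codons:
                f_c[c] = float("nan")
                w_c[c] = float("nan")
            continue
        total = sum(raw) + fam.r_a * pc
        freqs = [(x + pc) / total for x in raw]
        fmax = max(freqs)
        for c, f in zip(codons, freqs):
            f_c[c] = f
            w_c[c] = f / fmax
            if f == fmax:
                optimal.add(c)
    return ReferenceFrequencies(
        taxon_id=table.taxon_id, f_c=f_c, w_c=w_c,
        optimal=frozenset(optimal), code=code,
    )


def build_references(
    tables: dict[str, CodonCountTable],
    pseudocount: float = 0.5,
    code: GeneticCode | None = None,
) -> dict[str, ReferenceFrequencies]:
    """References for every retained taxon (the unclassified bucket is skipped)."""
    return {
        t: build_reference(tab, pseudocount=pseudocount, code=code)
        for t, tab in tables.items()
        if t != UNCLASSIFIED
    }


def reference_table(refs: dict[str, ReferenceFrequencies],
                    tables: dict[str, CodonCountTable] | None = None) -> pd.DataFrame:
    """Long-format reference TSV payload: taxon, codon, count, f_c, w_c, is_optimal."""
    rows = []
    for taxon, ref in sorted(refs.items()):
        counts = tables[taxon].counts if tables and taxon in tables else {}
        for codon in sorted(ref.f_c):
            rows.append({
                "taxon_id": taxon,
                "codon": codon,
                "count": counts.get(codon, float("nan")),
                "f_c": ref.f_c[codon],
                "w_c": ref.w_c[codon],
                "is_optimal": codon in ref.optimal,
            })
    return pd.DataFrame(rows)
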