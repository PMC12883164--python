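"""Genetic code tables, synonymous-codon families, and site degeneracy classes.

Every codon-usage statistic in this package is defined relative to a genetic
code: which codons are synonymous (encode the same amino acid) and which codon
positions are degenerate. This module owns that mapping. The default code is
NCBI translation table 11 (bacteria/archaea/plant plastids), whose sense and
stop assignments coincide with the standard code — appropriate for soil
bacterial and archaeal communities.

Site degeneracy drives the synonymous/nonsynonymous nucleotide pools:

* a *fourfold-degenerate* (synonymous) site is a codon position where every
  single-nucleotide substitution preserves the encoded amino acid;
* a *nonsynonymous* site is one where every substitution changes it;
* everything else is *mixed* and belongs to neither pool.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

NUCLEOTIDES = ("A", "C", "G", "T")
STOP = "*"

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

_RNA_TO_DNA = str.maketrans("Uu", "Tt")


class AmbiguousCodonError(ValueError):
    """Raised when a codon contains characters outside A/C/G/T."""


class SiteClass(enum.Enum):
    """Degeneracy class of one codon position under a genetic code."""

    FOURFOLD_SYNONYMOUS = "fourfold_synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    MIXED = "mixed"


@dataclass(frozen=True)
class SynonymousFamily:
    """The set of codons encoding one amino acid.

    ``r_a`` is the family size (1 for Met/Trp up to 6 for Leu/Ser/Arg under
    the standard bacterial code); it enters the short-sequence correction of
    the MILC statistic.
    """

    amino_acid: str
    codons: frozenset[str]

    @property
    def r_a(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid mapping over the 64 DNA codons.

    Stop codons map to ``"*"`` and belong to no synonymous family.
    """

    table_id: int
    codon_to_aa: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must define all 64 codons, got {len(self.codon_to_aa)}"
            )
        aas = set(self.codon_to_aa.values()) - {STOP}
        if not aas <= set(AMINO_ACIDS):
            raise ValueError(f"unexpected residue symbols: {aas - set(AMINO_ACIDS)}")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.codon_to_aa.items()) if aa != STOP)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == STOP)

    def translate(self, codon: str) -> str:
        """Return the residue (or ``"*"``) for one codon.

        RNA input (U) is accepted and read in the DNA sense-strand
        convention. Raises :class:`AmbiguousCodonError` on non-ACGT
        characters so callers can decide to skip or fail.
        """
        codon = codon.upper().translate(_RNA_TO_DNA)
        aa = self.codon_to_aa.get(codon)
        if aa is None:
            raise AmbiguousCodonError(f"ambiguous or malformed codon: {codon!r}")
        return aa

    def synonymous_family(self, residue: str) -> SynonymousFamily:
        """All codons translating to ``residue`` and their count r_a."""
        if residue == STOP:
            raise ValueError("stop codons form no synonymous family")
        codons = frozenset(
            c for c, aa in self.codon_to_aa.items() if aa == residue
        )
        if not codons:
            raise ValueError(f"unknown residue: {residue!r}")
        return SynonymousFamily(residue, codons)

    def families(self) -> dict[str, SynonymousFamily]:
        """Synonymous families for all residues present in the code."""
        return {aa: self.synonymous_family(aa) for aa in sorted(set(self.codon_to_aa.values()) - {STOP})}

    def classify_site(self, codon: str, position: int) -> SiteClass:
        """Degeneracy class of ``position`` (1-based) in a sense codon.

        FOURFOLD_SYNONYMOUS if all three substitutions at the position keep
        the residue, NONSYNONYMOUS if all three change it, MIXED otherwise.
        """
        if position not in (1, 2, 3):
            raise ValueError("codon position must be 1, 2 or 3")
        codon = codon.upper().translate(_RNA_TO_DNA)
        aa = self.translate(codon)
        if aa == STOP:
            raise ValueError(f"cannot classify sites of stop codon {codon}")
        i = position - 1
        same = 0
        for nt in NUCLEOTIDES:
            if nt == codon[i]:
                continue
            mutant = codon[:i] + nt + codon[i + 1:]
            if self.codon_to_aa[mutant] == aa:
                same += 1
        if same == 3:
            return SiteClass.FOURFOLD_SYNONYMOUS
        if same == 0:
            return SiteClass.NONSYNONYMOUS
        return SiteClass.MIXED


def load_code(path: str | Path) -> GeneticCode:
    """Load a genetic code from a 64-line ``codon<TAB>residue`` file."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        codon, aa = line.split("\t")
        codon = codon.upper().translate(_RNA_TO_DNA)
        if codon in mapping:
            raise ValueError(f"duplicate codon {codon} in {path}")
        mapping[codon] = aa
    return GeneticCode(table_id=0, codon_to_aa=mapping)


@lru_cache(maxsize=None)
def default_code(table_id: int = 11) -> GeneticCode:
    """The packaged bacterial code (NCBI table 11)."""
    if table_id != 11:
        raise ValueError(
            "only translation table 11 is packaged; load others with load_code()"
        )
    ref = resources.files("genetraits.data") / "translation_table_11.tsv"
    with resources.as_file(ref) as path:
        code = load_code(path)
    return GeneticCode(table_id=11, codon_to_aa=code.codon_to_aa)


def clean_sequence(seq: str) -> str:
    """Canonicalize a nucleotide string: uppercase, RNA U -> DNA T."""
    return seq.upper().translate(_RNA_TO_DNA)


def iter_codons(seq: str):
    """Yield successive 3-mers of a canonicalized sequence."""
    seq = clean_sequence(seq)
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i:i + 3]
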