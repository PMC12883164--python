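"""Readers and writers for the formats the pipeline touches.

FASTA via Biopython, GFF3 via gffutils, tabular inputs via pandas. All
readers validate rather than coerce: malformed records raise, and records
excluded by a rule (e.g. CDS length not divisible by 3) are counted and
reported, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, clean_sequence, default_code

log = logging.getLogger(__name__)


@dataclass
class CodingSequence:
    """One protein-coding gene with its community-context labels.

    ``depth`` is the mean per-base read coverage of the gene in the
    metagenome; it weights the gene's contribution to taxon codon-frequency
    references and to community trait averages.
    """

    gene_id: str
    sequence: str
    taxon_id: str = ""
    ko_id: str | None = None
    pathway_tags: frozenset[str] = frozenset()
    depth: float = 1.0

    def __post_init__(self) -> None:
        self.sequence = clean_sequence(self.sequence)
        if len(self.sequence) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(self.sequence)} not divisible by 3"
            )
        if self.depth < 0:
            raise ValueError(f"{self.gene_id}: negative depth {self.depth}")

    @property
    def length_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass
class ExtractionReport:
    """Counts of records excluded during CDS extraction."""

    n_extracted: int = 0
    n_length_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence mapping.

    Duplicate ids are an error; an empty file yields an empty dict.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        records[rec.id] = clean_sequence(str(rec.seq))
    return records


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def extract_cds(
    contigs_path: str | Path,
    gff_path: str | Path,
    code: GeneticCode | None = None,
) -> tuple[list[CodingSequence], ExtractionReport]:
    """Cut CDS features out of contigs using GFF3 coordinates.

    Coordinates are 1-based inclusive per the GFF3 standard; minus-strand
    features are reverse-complemented; the ``phase`` column trims partial
    leading codons. Sequences whose (phase-adjusted) length is not divisible
    by 3 are excluded and tallied in the report.
    """
    code = code or default_code()
    contigs = read_fasta(contigs_path)
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: list[CodingSequence] = []
    report = ExtractionReport()
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.seqid not in contigs:
            raise ValueError(f"feature {feat.id}: unknown contig {feat.seqid}")
        contig = contigs[feat.seqid]
        if feat.start < 1 or feat.end > len(contig):
            raise ValueError(
                f"feature {feat.id}: {feat.start}..{feat.end} outside contig "
                f"{feat.seqid} (length {len(contig)})"
            )
        seq = contig[feat.start - 1: feat.end]
        if feat.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        elif feat.strand != "+":
            raise ValueError(f"feature {feat.id}: strand must be + or -")
        phase = feat.frame if feat.frame in ("0", "1", "2") else "0"
        seq = seq[int(phase):]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if len(seq) % 3 != 0:
            report.n_length_excluded += 1
            report.excluded_ids.append(gene_id)
            continue
        out.append(CodingSequence(gene_id=gene_id, sequence=seq))
        report.n_extracted += 1
    if report.n_length_excluded:
        log.info("extract_cds: excluded %d feature(s) with length %% 3 != 0",
                 report.n_length_excluded)
    return out, report


def default_pathway_tags() -> pd.Series:
    """Packaged KO -> pathway tag map.

    Covers the curated nitrogen-assimilation KO list plus the carbon
    metabolism (ko01200) and ribosomal protein (ko03010) pathway ids, for
    tagging annotation tables when no project-specific map is supplied.
    """
    from importlib import resources

    ref = resources.files("genetraits.data") / "pathway_kos.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index("ko_id")["pathway"]


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, taxon_id, ko_id, pathway_tags.

    ``pathway_tags`` is a semicolon-separated list (may be empty); the
    returned frame is indexed by gene_id with tags parsed into frozensets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"gene_id", "taxon_id", "ko_id", "pathway_tags"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation table missing columns: {required - set(df.columns)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in annotations: {dupes[:5]}")
    df = df.set_index("gene_id")
    df["pathway_tags"] = [
        frozenset(t for t in tags.split(";") if t) for tags in df["pathway_tags"]
    ]
    return df


def read_depths(path: str | Path) -> pd.Series:
    """Per-gene mean read depth TSV: gene_id, depth."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "depth": float})
    if not {"gene_id", "depth"} <= set(df.columns):
        raise ValueError("depth table must have columns gene_id, depth")
    if (df["depth"] < 0).any():
        bad = df.loc[df["depth"] < 0, "gene_id"].tolist()
        raise ValueError(f"negative depths for genes: {bad[:5]}")
    return df.set_index("gene_id")["depth"]


def read_design(path: str | Path) -> pd.DataFrame:
    """Sample design TSV: sample_id, treatment, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str,
                                            "replicate": int})
    if not {"sample_id", "treatment", "replicate"} <= set(df.columns):
        raise ValueError("design table must have columns sample_id, treatment, replicate")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design table")
    return df.set_index("sample_id")


def read_counts(path: str | Path, design_path: str | Path) -> "CountMatrix":
    """Transcript count TSV (gene_id x sample columns) plus its design."""
    from .de import CountMatrix  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    design = read_design(design_path)
    missing = set(df.columns) - set(design.index)
    if missing:
        raise ValueError(f"count columns with no design row: {sorted(missing)}")
    if (df.values < 0).any():
        raise ValueError("negative transcript counts")
    if not (df.dtypes == int).all():
        as_int = df.round().astype(int)
        if not (as_int.values == df.values).all():
            raise ValueError("non-integer transcript counts")
        df = as_int
    return CountMatrix(counts=df, design=design.loc[list(df.columns)])


def assemble_genes(
    cds: dict[str, str] | list[CodingSequence],
    annotations: pd.DataFrame,
    depths: pd.Series | None = None,
) -> list[CodingSequence]:
    """Join sequences with annotation and depth tables into CodingSequences.

    Genes absent from the annotation table fall into the "unclassified"
    taxon bucket; genes without a depth row get depth 1.
    """
    if isinstance(cds, list):
        cds = {g.gene_id: g.sequence for g in cds}
    genes = []
    for gene_id, seq in cds.items():
        if gene_id in annotations.index:
            row = annotations.loc[gene_id]
            taxon, ko, tags = row["taxon_id"], row["ko_id"] or None, row["pathway_tags"]
        else:
            taxon, ko, tags = "unclassified", None, frozenset()
        depth = float(depths.get(gene_id, 1.0)) if depths is not None else 1.0
        genes.append(CodingSequence(gene_id=gene_id, sequence=seq, taxon_id=taxon,
                                    ko_id=ko, pathway_tags=tags, depth=depth))
    return genes
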