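#!/usr/bin/env python
"""Build per-taxon genomic-background codon-frequency references.

Reads the community inputs written by 01_simulate.py, accumulates
depth-weighted codon counts per taxon, drops taxa below 750,000
depth-adjusted codons, and derives family frequencies, CAI weights and
optimal-codon sets. Writes results/references.tsv and the genome x codon
frequency matrix (ordination input) to results/codon_matrix.tsv.
"""

import argparse
from pathlib import Path

from genetraits import io, reference
from genetraits.association import export_codon_matrix


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--min-taxon-codons", type=float,
                    default=reference.MIN_TAXON_CODONS)
    args = ap.parse_args()
    data = Path(args.datadir)
    out = Path(args.outdir)

    seqs = io.read_fasta(data / "cds.fasta")
    ann = io.read_annotations(data / "annotations.tsv")
    depths = io.read_depths(data / "depths.tsv")
    genes = io.assemble_genes(seqs, ann, depths)

    tables = reference.accumulate_counts(genes, depth_weighted=True)
    kept = reference.filter_taxa(tables, args.min_taxon_codons)
    refs = reference.build_references(kept)
    reference.reference_table(refs, kept).to_csv(
        out / "references.tsv", sep="\t", index=False)

    ann_flat = ann.reset_index().assign(
        pathway_tags=lambda d: d["pathway_tags"].apply(
            lambda t: ";".join(sorted(t))))
    mat = export_codon_matrix(ann_flat, seqs)
    mat.to_csv(out / "codon_matrix.tsv", sep="\t")

    print(f"accumulated codon tables for {len(tables)} taxa; "
          f"{len(kept)} retained at >= {args.min_taxon_codons:g} codons")
    totals = sorted(t.total_codons for t in tables.values())
    print(f"depth-adjusted codon totals: min {totals[0]:.3g}, "
          f"median {totals[len(totals)//2]:.3g}, max {totals[-1]:.3g}")
    print(f"wrote {out/'references.tsv'} and {out/'codon_matrix.tsv'}")


if __name__ == "__main__":
    main()
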