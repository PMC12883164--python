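#!/usr/bin/env python
"""Compute per-transcript gene traits against each taxon's reference.

CAI, FOP, MILC, ENC', GC content (total / fourfold-degenerate /
nonsynonymous sites), GC and AT skew at fourfold sites, and encoded
amino-acid mean cost and C:N. Genes shorter than 80 codons are discarded.
Writes results/gene_traits.tsv.
"""

import argparse
from pathlib import Path

from genetraits import io, reference, traits


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--min-codons", type=int, default=traits.MIN_GENE_CODONS)
    args = ap.parse_args()
    data = Path(args.datadir)

    seqs = io.read_fasta(data / "cds.fasta")
    ann = io.read_annotations(data / "annotations.tsv")
    depths = io.read_depths(data / "depths.tsv")
    genes = io.assemble_genes(seqs, ann, depths)

    refs = reference.build_references(reference.filter_taxa(
        reference.accumulate_counts(genes)))
    tt = traits.traits_table(genes, refs, min_codons=args.min_codons)
    out = Path(args.outdir) / "gene_traits.tsv"
    tt.to_csv(out, sep="\t", index=False)

    n_short = len(genes) - len(traits.length_filter(genes, args.min_codons))
    print(f"{len(genes)} genes read; {n_short} below {args.min_codons} codons; "
          f"{len(tt)} trait rows written to {out}")
    for c in ("cai", "fop", "milc", "enc_prime", "gc_fourfold"):
        print(f"  {c}: mean {tt[c].mean():.4f} (sd {tt[c].std():.4f})")


if __name__ == "__main__":
    main()
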