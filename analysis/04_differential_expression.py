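#!/usr/bin/env python
"""Estimate per-gene log2-fold changes, treatment vs control.

Median-of-ratios normalization, moderated method-of-moments dispersions, a
Wald test, and Benjamini-Hochberg FDR at the 0.1 significance threshold.
Writes results/differential_expression.tsv.
"""

import argparse
from pathlib import Path

from genetraits import de, io


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--control", default="control")
    ap.add_argument("--treatment", default="treatment")
    ap.add_argument("--fdr", type=float, default=de.FDR_THRESHOLD)
    args = ap.parse_args()
    data = Path(args.datadir)

    cm = io.read_counts(data / "counts.tsv", data / "design.tsv")
    res = de.estimate_de(cm, args.control, args.treatment, fdr_threshold=args.fdr)
    out = Path(args.outdir) / "differential_expression.tsv"
    res.table.to_csv(out, sep="\t")

    sig = res.table[res.table["significant"]]
    print(f"{len(res.table)} features tested; {len(sig)} significant at "
          f"FDR < {args.fdr} ({(sig['lfc'] > 0).sum()} up, "
          f"{(sig['lfc'] < 0).sum()} down)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
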