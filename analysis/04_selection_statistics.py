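#!/usr/bin/env python
"""Per-gene selection statistics: MK tables, NI, DoS, NG86 dN/dS, GC, length.

Polarizes SNPs into within-species polymorphisms vs fixed interspecies
differences, classifies coding changes against the reference codons, and
writes one row per gene.
"""

import argparse
from pathlib import Path

import pandas as pd

from castepop import coding_selection as cs
from castepop import io_formats as iof


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/selection"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sheet = iof.read_sample_sheet(args.indir / "samples.tsv")
    vt = iof.read_vcf(args.indir / "variants.vcf", sheet)
    seqs = iof.read_fasta(args.indir / "ref.fa")
    genes = iof.read_gff3(args.indir / "genes.gff3")

    mk = cs.mk_tables_for_genes(vt, seqs, genes, "carbonaria", "hockingsi")
    feats = pd.DataFrame([cs.gene_features(seqs, g) for g in genes])
    table = mk.merge(feats, on="gene_id")
    table.to_csv(args.outdir / "gene_selection_stats.tsv", sep="\t", index=False)

    defined_ni = int(table.NI.notna().sum())
    print(f"{len(table)} genes; NI defined for {defined_ni} "
          f"({100 * defined_ni / len(table):.0f}%)")
    print("median NI   :", round(table.NI.median(), 3))
    print("median DoS  :", round(table.DoS.median(), 3))
    print("median dN/dS:", round(table.dNdS.median(), 3))
    print("mean gene GC%:", round(table.gc_percent.mean(), 1))


if __name__ == "__main__":
    main()
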