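#!/usr/bin/env python
"""Generate the synthetic two-species dataset and write it in standard formats.

Emits a reference FASTA, GFF3 gene models, a biallelic-SNP VCF, a sample
sheet, a caste x tissue count matrix and the generator's ground truth under
results/sim/. Downstream scripts re-read these files, so the whole pipeline
is exercised through its on-disk interfaces.
"""

import argparse
from pathlib import Path

from castepop import io_formats as iof
from castepop import synthetic_data as syn


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/sim"))
    ap.add_argument("--genes-per-class", type=int, default=100)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = syn.relaxed_worker_scenario(n_per_class=args.genes_per_class, seed=args.seed)
    seqs, genes, vt, truth = syn.simulate_genomes(cfg)
    em = syn.simulate_counts(cfg, truth)

    iof.write_fasta(seqs, args.outdir / "ref.fa")
    iof.write_gff3(genes, {c: len(s) for c, s in seqs.items()}, args.outdir / "genes.gff3")
    iof.write_vcf(vt, args.outdir / "variants.vcf")
    em.counts.rename_axis("gene").to_csv(args.outdir / "counts.tsv", sep="\t")
    em.meta.rename_axis("sample").to_csv(args.outdir / "sample_meta.tsv", sep="\t")
    sheet = (
        "sample\tspecies\tpopulation\n"
        + "\n".join(f"{s}\t{sp}\t{p}" for s, sp, p in zip(vt.samples, vt.species, vt.population))
        + "\n"
    )
    (args.outdir / "samples.tsv").write_text(sheet)
    truth.sites.to_csv(args.outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.genes.to_csv(args.outdir / "truth_genes.tsv", sep="\t", index=False)
    print(f"wrote {vt.n_sites} SNPs, {len(genes)} genes, "
          f"{em.counts.shape[1]} expression samples -> {args.outdir}")


if __name__ == "__main__":
    main()
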