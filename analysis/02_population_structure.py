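#!/usr/bin/env python
"""SNP filtering, LD pruning, PCA and pairwise FST on the simulated dataset.

Reads results/sim/ back from disk, applies the completeness and MAF filters,
LD-prunes for the PCA, and writes sample coordinates plus per-pair
Weir-Cockerham FST summaries.
"""

import argparse
from pathlib import Path

import pandas as pd

from castepop import io_formats as iof
from castepop import popgen_stats as pg


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/sim"))
    ap.add_argument("--outdir", type=Path, default=Path("results/popstructure"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    sheet = iof.read_sample_sheet(args.indir / "samples.tsv")
    vt = iof.read_vcf(args.indir / "variants.vcf", sheet)
    genes = iof.read_gff3(args.indir / "genes.gff3")

    filtered = pg.filter_snps(vt, maf_min=0.05, min_called_alleles=50)
    print("filter report:", filtered.filter_report)
    pruned = pg.ld_prune(filtered, r2_max=0.8, window_bp=500_000)
    print(f"LD pruning kept {pruned.n_sites} of {filtered.n_sites} SNPs")

    coords, evals = pg.pca_genotypes(pruned)
    coords["species"] = pruned.species
    coords["population"] = pruned.population
    coords.rename_axis("sample").to_csv(args.outdir / "pca_coords.tsv", sep="\t")
    pct = 100 * evals[:5] / evals.sum()
    print("PC1-5 explained variance (%):", [round(x, 1) for x in pct])

    pairs = [
        ("carbonaria_vs_hockingsi", {"species": "carbonaria"}, {"species": "hockingsi"}),
        ("carb_north_vs_south", {"population": "carb_north"}, {"population": "carb_south"}),
        ("hock_north_vs_south", {"population": "hock_north"}, {"population": "hock_south"}),
    ]
    rows, high_bed = [], []
    for name, a, b in pairs:
        site_fst, unw, w = pg.weir_cockerham_fst(vt, a, b)
        rows.append({"pair": name, "fst_unweighted": unw, "fst_weighted": w,
                     "n_snps": int(site_fst.theta.notna().sum())})
        if name == "carbonaria_vs_hockingsi":
            site_fst.to_csv(args.outdir / "site_fst_species.tsv", sep="\t", index=False)
            bins, r, p = pg.fst_bins_cds_fraction(site_fst, genes)
            bins.to_csv(args.outdir / "fst_bins_cds.tsv", sep="\t", index=False)
            print(f"FST-bin vs CDS-fraction correlation r={r:.3f} (p={p:.3g})")
            flagged = pg.flag_divergent_genes(site_fst, genes)
            flagged.to_csv(args.outdir / "divergent_genes.tsv", sep="\t", index=False)
            hi = pg.fixed_snp_cds_intersect(site_fst, genes, threshold=0.95)
            bed = pd.DataFrame({"chrom": hi.contig, "start": hi.pos - 1,
                                "end": hi.pos, "name": hi.gene_id})
            bed.to_csv(args.outdir / "high_fst_snps.bed", sep="\t",
                       index=False, header=False)
            print(f"{len(hi)} SNPs with theta > 0.95; "
                  f"{len(flagged)} genes with >=3 high-FST CDS SNPs")
    fst = pd.DataFrame(rows)
    fst.to_csv(args.outdir / "pairwise_fst.tsv", sep="\t", index=False)
    print(fst.to_string(index=False))


if __name__ == "__main__":
    main()
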