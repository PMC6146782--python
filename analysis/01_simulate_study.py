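#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the contrast design the downstream analyses consume: Balding-Nichols
breed allele frequencies for 5 minipig + 5 large-pig breeds over 18 autosomes
and X (540 Mb), six injected 1 Mb sweeps of intensity 0.9 in the minipig
group, minipig site allele counts for the CLR scan, a null gene/GO
annotation, and the F2 cross with a 3 cm X-haplotype effect. Writes
everything under results/sim/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sweepcontrast import regions as rg
from sweepcontrast.synthdata import (SimConfig, simulate_contrast_genome,
                                     simulate_f2_cross, simulate_gene_annotation,
                                     simulate_sample_metadata, simulate_site_counts)
from sweepcontrast.xqtl import write_chip


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cfg = SimConfig(seed=args.seed)
    rng = np.random.default_rng(args.seed)
    table = simulate_contrast_genome(cfg, rng)
    table.write_cache(args.out / "breed_freqs.npz")
    simulate_sample_metadata(cfg).to_csv(args.out / "samples.tsv", sep="\t", index=False)
    pd.DataFrame({"chrom": list(cfg.chrom_lengths),
                  "length": list(cfg.chrom_lengths.values())}
                 ).to_csv(args.out / "genome.tsv", sep="\t", header=False, index=False)
    rg.write_bed(cfg.truth_regions(), args.out / "truth_sweeps.bed")

    alt, n = simulate_site_counts(table, cfg.breeds["minipig"],
                                  cfg.n_individuals_per_breed, rng)
    pd.DataFrame({"chrom": table.loci["chrom"], "pos": table.loci["pos"],
                  "alt_count": alt, "n_alleles": n}
                 ).to_csv(args.out / "minipig_site_counts.tsv", sep="\t", index=False)

    genes, go_map = simulate_gene_annotation(cfg)
    genes[["chrom", "start", "end", "gene_id"]].to_csv(
        args.out / "genes.bed", sep="\t", header=False, index=False)
    go_map.to_csv(args.out / "go_map.tsv", sep="\t", index=False)

    chip, records = simulate_f2_cross(cfg)
    records.to_csv(args.out / "phenotypes.tsv", sep="\t", index=False)
    write_chip(chip, args.out / "chip_genotypes.tsv", args.out / "chip_map.tsv")

    print(f"simulated {table.n_loci} loci across {len(cfg.chrom_lengths)} chromosomes "
          f"({sum(cfg.chrom_lengths.values()) / 1e6:.0f} Mb), "
          f"{len(cfg.sweeps)} injected sweeps, {len(records)} F2 animals -> {args.out}")


if __name__ == "__main__":
    main()
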