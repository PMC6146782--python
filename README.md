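# sweepcontrast

Contrast-based selective-sweep analysis for minipig vs. large-pig genomes,
with an X-linked haplotype-QTL validation of the major sweep on chromosome X.

Miniature pig breeds differ from commercial breeds by roughly an order of
magnitude in body size, and the genomic regions targeted by that selection
leave a characteristic footprint: locally depleted diversity in the minipigs
together with strong differentiation against large pigs. This package
implements the full analysis chain that detects such regions from biallelic
SNP data and validates their phenotypic effect in an F2 cross, exercised
end-to-end on synthetic data with the same statistical structure, so every
stage is testable without the original re-sequencing data.

## The statistics at the core

For each locus with reference-allele frequency *p* in the minipig in-silico
pool (MPP — the unweighted mean of the member-breed frequencies), expected
heterozygosity is

> H<sub>exp</sub> = 2p(1 − p),

averaged in 100 kb sliding windows with 80% overlap and Z-normalised
(autosomes and X separately). Windows below the 1% quantile (classically
Z = −2.34) seed a sweep candidate, extended over contiguous windows below the
5% quantile (−1.64). Differentiation between the large-pig pool (LPP) and the
MPP is the fixation index

> F<sub>ST</sub> = [ Σ n<sub>i</sub>(p<sub>i</sub> − p̄)² / (2n̄) ] / [ p̄(1 − p̄) ],

windowed and screened for *high* outliers by the same seed/extend rule. A
SweepFinder-style composite likelihood ratio (CLR) test compares, at each
20 kb grid point, a star-approximation sweep model (per-lineage escape
probability 1 − e<sup>−αd</sup> at distance *d*) against the genome-wide
background site-frequency spectrum. The final sweep call is

> (H<sub>exp</sub> ∪ CLR) ∩ F<sub>ST</sub>,

with a 200 kb minimum width and 0.5 Mb padding per side. Genes in the
combined regions are tested for GO over-representation (one-sided Fisher's
exact test, fold enrichment a / [(a+b)(a+c)/N]) against per-term empirical
thresholds from 5000 random circular shifts of the region set. The
X-chromosome sweep is validated in a large-dam × minipig-sire F2 cross: three
haplotype classes (homozygous/hemizygous large, heterozygous female,
hemizygous-minipig male) enter a fixed-effects model

> y = B + S + b₁A + b₂A² + H(S) + B×S + b₃(B×A) + b₄(B×A²) + B×H(S) + b₅(A×H(S)) + e

reduced by backward elimination, followed by LS-means and LSD contrasts.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(outputs under `results/`):

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_sweep_scan.py
python analysis/03_enrichment.py
python analysis/04_phylogeny.py
python analysis/05_xqtl.py
```

which prints, stage by stage:

```
simulated 108000 loci across 19 chromosomes (540 Mb), 6 injected sweeps, 454 F2 animals -> results/sim
combined regions: 6; recovered 6/6 truth sweeps; detected 2.37% of the genome, false-positive fraction 0.00%
368 GO terms tested against 5000 shifts; 20 significant (5.4%; null annotation, so ~5% expected)
NJ tree over 60 individuals (8000 chr1 loci); mean 1-IBS within minipig group 0.281 vs across groups 0.306; genome-wide group FST 0.0321 ± 0.0011
3 diagnostic markers; Mendelian chi-square p = 0.227; retained terms: B, S, A, A2, HS; male large-vs-minipig haplotype contrast 3.28 cm (SE 0.19, 5.1% of mean height)
```

Reading these numbers: the scan recovered all six injected 1 Mb sweeps while
flagging ~2.4% of the genome (sweeps plus their 0.5 Mb padding) and calling
nothing outside them; the permutation-calibrated enrichment flags ~5% of GO
terms on a *null* annotation, i.e. the empirical thresholds are honest; the
neighbor-joining tree separates the two breed groups; and the F2 model
recovers the simulated 3 cm male haplotype effect (estimate 3.28 ± 0.19 cm)
while backward elimination keeps exactly the terms that carry signal.

The same stages are scriptable via the `sweepcontrast` CLI
(`simulate`, `freqs`, `pool`, `scan`, `clr`, `combine`, `phylo`, `enrich`,
`xqtl`, `run`) for VCF/TSV/BED inputs.

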