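"""Synthetic inputs with the statistical structure the sweep contrast assumes.

Allele frequencies follow the Balding-Nichols hierarchical model: per locus an
ancestral frequency pi ~ Uniform(0.05, 0.95), and per breed

    p ~ Beta(pi (1-F)/F, (1-pi) (1-F)/F)

so that across-breed variance at a locus is F * pi * (1 - pi), with F the
background differentiation. Sweeps are injected by deterministically shrinking
the target group's frequencies towards a fixation boundary inside a region,
which lowers expected heterozygosity and raises FST there — the
summary-statistic signature the scan detects, without simulating genealogies.

Individual genotypes are drawn under Hardy-Weinberg from the breed
frequencies and can be written as a small VCF (with GQ/AD/DP fields) plus a
sample metadata TSV, so the full VCF ingest path is exercised. A companion
generator produces the F2 cross: X haplotypes transmitted by the Mendelian
rules of the large-dam x minipig-sire design, diagnostic chip markers, and
size phenotypes built from breed, sex, age, age squared and the X-haplotype
effect in hemizygous-minipig males.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .freqio import BreedFrequencyTable
from .xqtl import ChipGenotypes

# 18 autosomes totalling 500 Mb, plus a 40 Mb X chromosome.
DEFAULT_CHROM_LENGTHS_MB = {
    **{str(i + 1): L for i, L in enumerate(
        [40, 37, 35, 33, 32, 31, 30, 29, 28, 27, 26, 25, 24, 23, 22, 21, 20, 17])},
    "X": 40,
}

DEFAULT_SWEEPS = (
    ("2", 15_000_000, 16_000_000),
    ("5", 10_000_000, 11_000_000),
    ("8", 12_000_000, 13_000_000),
    ("11", 8_000_000, 9_000_000),
    ("14", 11_000_000, 12_000_000),
    ("17", 9_000_000, 10_000_000),
)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic genome and cross.

    Defaults emulate the contrast design: two groups of five breeds each with
    background differentiation F_bg = 0.10 (the scale of between-breed-group
    pig FST), 200 loci/Mb, six injected 1 Mb sweeps of intensity 0.9 in the
    minipig group, and an F2 cross with a 3 cm X-haplotype effect on traits of
    the 65-84 cm slaughter-size scale.
    """

    seed: int = 0
    n_breeds_per_group: int = 5
    n_individuals_per_breed: int = 6
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {
        c: mb * 1_000_000 for c, mb in DEFAULT_CHROM_LENGTHS_MB.items()})
    loci_per_mb: float = 200.0
    f_background: float = 0.10
    group_divergence: float = 0.5   # share of F_bg attributable to the group split
    sweeps: tuple = tuple((c, s, e, "minipig", 0.9) for c, s, e in DEFAULT_SWEEPS)
    # F2 cross
    n_f2: int = 454
    haplotype_effect_cm: float = 3.0
    sex_effect_cm: float = 1.5
    breed_effect_cm: float = 1.0
    age_range_days: tuple[int, int] = (166, 439)
    age_slope: float = 0.12          # cm per day (centred)
    age_quad: float = -2e-4          # cm per day^2 (centred)
    trait_mean_cm: float = 65.0      # slaughter-height scale
    residual_sd_cm: float = 1.5

    def __post_init__(self):
        if not (0.0 < self.f_background < 1.0):
            raise ValueError("f_background must be in (0, 1)")
        if not (0.0 <= self.group_divergence < 1.0):
            raise ValueError("group_divergence must be in [0, 1)")
        for chrom, start, end, group, intensity in self.sweeps:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(f"sweep {chrom}:{start}-{end} outside chromosome bounds")
            if not (0.0 < intensity <= 1.0):
                raise ValueError("sweep intensity must be in (0, 1]")

    @property
    def breeds(self) -> dict[str, list[str]]:
        return {
            "minipig": [f"mini_{i + 1}" for i in range(self.n_breeds_per_group)],
            "large": [f"large_{i + 1}" for i in range(self.n_breeds_per_group)],
        }

    def truth_regions(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, s, e) for c, s, e, _, _ in self.sweeps],
            columns=["chrom", "start", "end"])


def _bn_draw(rng, anc: np.ndarray, f: float, size) -> np.ndarray:
    """One Balding-Nichols layer: Beta draws around ancestral frequencies."""
    if f <= 0:
        return np.broadcast_to(anc, size).copy()
    anc = np.clip(anc, 1e-9, 1 - 1e-9)
    return rng.beta(anc * (1 - f) / f, (1 - anc) * (1 - f) / f, size=size)


def simulate_breed_frequencies(cfg: SimConfig,
                               rng: np.random.Generator | None = None) -> BreedFrequencyTable:
    """Hierarchical Balding-Nichols breed frequencies (no sweeps yet).

    Two layers: an ancestral frequency per locus diverges into the two group
    frequencies, which diverge into the member breeds. The between- and
    within-group Beta concentrations are chosen so total across-breed variance
    equals ``f_background * pi * (1 - pi)``, with ``group_divergence`` setting
    the share of that variance carried by the group split.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    breeds = cfg.breeds["minipig"] + cfg.breeds["large"]
    chroms, poss = [], []
    for chrom, length in cfg.chrom_lengths.items():
        n_loci = int(round(cfg.loci_per_mb * length / 1e6))
        # draw-with-margin then de-duplicate: collisions are negligible at
        # these densities and this avoids materialising a length-sized arange
        draw = rng.integers(1, length + 1, size=int(n_loci * 1.1) + 16)
        pos = np.unique(draw)
        if len(pos) > n_loci:
            pos = np.sort(rng.choice(pos, size=n_loci, replace=False))
        n_loci = len(pos)
        chroms.extend([chrom] * n_loci)
        poss.extend(pos.tolist())
    loci = pd.DataFrame({"chrom": chroms, "pos": np.array(poss, dtype=np.int64)})
    pi = rng.uniform(0.05, 0.95, size=len(loci))
    f_between = cfg.f_background * cfg.group_divergence
    # within-group divergence such that total variance stays F_bg * pi(1-pi)
    f_within = (cfg.f_background - f_between) / (1.0 - f_between)
    n_mini = len(cfg.breeds["minipig"])
    freq = np.empty((len(loci), len(breeds)))
    for gi, group in enumerate(("minipig", "large")):
        p_group = _bn_draw(rng, pi, f_between, len(loci))
        members = cfg.breeds[group]
        cols = slice(0, n_mini) if group == "minipig" else slice(n_mini, len(breeds))
        freq[:, cols] = _bn_draw(rng, p_group[:, None], f_within,
                                 (len(loci), len(members)))
    n_alleles = np.full(freq.shape, 2.0 * cfg.n_individuals_per_breed)
    table = BreedFrequencyTable(loci=loci, breeds=tuple(breeds), freq=freq, n_alleles=n_alleles)
    table.loci.attrs["ancestral"] = pi
    return table


def inject_sweep(table: BreedFrequencyTable, region: tuple[str, int, int],
                 group_breeds: list[str], intensity: float,
                 toward: str = "low") -> BreedFrequencyTable:
    """Shrink the target breeds' frequencies towards fixation inside a region.

    ``toward='low'`` maps p -> p * (1 - intensity); ``'high'`` is the
    symmetric move towards 1. Returns a new table; the input is unchanged.
    """
    if not (0.0 <= intensity <= 1.0):
        raise ValueError("intensity must be in [0, 1]")
    chrom, start, end = region
    freq = table.freq.copy()
    cols = [table.breed_index(b) for b in group_breeds]
    in_region = ((table.loci["chrom"] == chrom)
                 & (table.loci["pos"] - 1 >= start)
                 & (table.loci["pos"] - 1 < end)).to_numpy()
    sub = freq[np.ix_(in_region, cols)]
    if toward == "low":
        sub = sub * (1.0 - intensity)
    elif toward == "high":
        sub = 1.0 - (1.0 - sub) * (1.0 - intensity)
    else:
        raise ValueError("toward must be 'low' or 'high'")
    freq[np.ix_(in_region, cols)] = sub
    return BreedFrequencyTable(loci=table.loci, breeds=table.breeds,
                               freq=freq, n_alleles=table.n_alleles)


def simulate_contrast_genome(cfg: SimConfig,
                             rng: np.random.Generator | None = None) -> BreedFrequencyTable:
    """Breed frequencies with all configured sweeps injected."""
    rng = rng or np.random.default_rng(cfg.seed)
    table = simulate_breed_frequencies(cfg, rng)
    group_map = cfg.breeds
    for chrom, start, end, group, intensity in cfg.sweeps:
        table = inject_sweep(table, (chrom, start, end), group_map[group], intensity)
    return table


def simulate_site_counts(table: BreedFrequencyTable, breeds: list[str],
                         n_per_breed: int, rng: np.random.Generator):
    """Binomially sampled alt-allele counts per locus over the given breeds.

    Returns (alt_count, n_alleles) arrays: the genotype-level data the CLR
    scan consumes, without materialising a VCF.
    """
    cols = [table.breed_index(b) for b in breeds]
    p_ref = table.freq[:, cols]
    n = 2 * n_per_breed
    alt = rng.binomial(n, 1.0 - np.nan_to_num(p_ref, nan=0.5))
    alt = np.where(np.isnan(p_ref), 0, alt)
    return alt.sum(axis=1), np.full(len(table.loci), n * len(cols), dtype=np.int64)


def simulate_sample_metadata(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for group, breeds in cfg.breeds.items():
        for b in breeds:
            for i in range(cfg.n_individuals_per_breed):
                sex = "female" if i % 2 == 0 else "male"
                rows.append((f"{b}_ind{i + 1}", b, group, "individual", sex))
    return pd.DataFrame(rows, columns=["sample_id", "breed", "group", "data_mode", "sex"])


def simulate_genotypes(table: BreedFrequencyTable, meta: pd.DataFrame, vcf_path,
                       rng: np.random.Generator, gq_range: tuple[int, int] = (30, 60),
                       dp_range: tuple[int, int] = (8, 20),
                       x_chroms=("X", "chrX")) -> None:
    """Write a VCF of Hardy-Weinberg genotypes drawn from the breed frequencies.

    Individuals get diploid GT (haploid for males on X) with GQ above the
    default filter threshold; pool samples get AD/DP fields. REF/ALT bases are
    arbitrary (A/G).
    """
    samples = meta["sample_id"].tolist()
    breed_of = dict(zip(meta["sample_id"], meta["breed"]))
    mode_of = dict(zip(meta["sample_id"], meta["data_mode"]))
    sex_of = dict(zip(meta["sample_id"], meta["sex"]))
    bidx = {b: table.breed_index(b) for b in set(breed_of.values())}

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(table.loci["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        chroms = table.loci["chrom"].to_numpy()
        poss = table.loci["pos"].to_numpy()
        for i in range(table.n_loci):
            on_x = chroms[i] in x_chroms
            fields = []
            for s in samples:
                p = table.freq[i, bidx[breed_of[s]]]
                if mode_of[s] == "pool":
                    dp = int(rng.integers(dp_range[0], dp_range[1] + 1))
                    ref_d = int(rng.binomial(dp, 0.5 if np.isnan(p) else p))
                    fields.append(f"./.:.:{ref_d},{dp - ref_d}:{dp}")
                    continue
                gq = int(rng.integers(gq_range[0], gq_range[1] + 1))
                if np.isnan(p):
                    gt = "./."
                elif on_x and sex_of[s] == "male":
                    gt = "0" if rng.random() < p else "1"
                else:
                    ref_dose = rng.binomial(2, p)
                    gt = {2: "0/0", 1: "0/1", 0: "1/1"}[ref_dose]
                fields.append(f"{gt}:{gq}:.:.")
            fh.write(f"{chroms[i]}\t{poss[i]}\t.\tA\tG\t.\tPASS\t.\tGT:GQ:AD:DP\t"
                     + "\t".join(fields) + "\n")


# --- F2 cross ---------------------------------------------------------------

INFORMATIVE_SNPS = ("INRA_c1", "H3GA_c2", "MARC_c3")  # centre-of-region diagnostics


def simulate_f2_cross(cfg: SimConfig, rng: np.random.Generator | None = None,
                      traits: tuple[str, ...] = ("height_slaughter",)
                      ) -> tuple[ChipGenotypes, pd.DataFrame]:
    """F2 cross with an X-linked haplotype effect.

    Founder dams (Duroc/Yorkshire) carry the large-pig X haplotype, founder
    sires the minipig one; transmission follows the Mendelian rules of the
    design with no recombination. Chip data contain the diagnostic markers
    (alt allele = minipig haplotype) plus background markers. Phenotypes:

        y = mean + breed + sex + b1*(A - Ā) + b2*(A - Ā)^2
            - effect * 1{male hemizygous minipig} + N(0, sd^2)
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if cfg.n_f2 < 20:
        raise ValueError("n_f2 must be >= 20")
    n_dams, n_sires, n_f1 = 13, 21, 40
    samples, sexes, gens, groups, ploidy = [], [], [], [], []
    # haplotype per X copy: 'L' large, 'm' minipig
    haps: list[tuple[str, ...]] = []
    dam_breeds = {}
    for i in range(n_dams):
        sid = f"P0_dam_{i + 1}"
        samples.append(sid)
        sexes.append("female")
        gens.append("P0")
        groups.append("large")
        ploidy.append(2)
        haps.append(("L", "L"))
        dam_breeds[sid] = "Duroc" if i < 6 else "Yorkshire"
    for i in range(n_sires):
        samples.append(f"P0_sire_{i + 1}")
        sexes.append("male")
        gens.append("P0")
        groups.append("minipig")
        ploidy.append(1)
        haps.append(("m",))
    f1_breed = {}
    for i in range(n_f1):
        sid = f"F1_{i + 1}"
        sex = "female" if i < n_f1 // 2 else "male"
        samples.append(sid)
        sexes.append(sex)
        gens.append("F1")
        groups.append("")
        ploidy.append(2 if sex == "female" else 1)
        haps.append(("L", "m") if sex == "female" else ("L",))
        f1_breed[sid] = "Duroc" if rng.random() < 6 / 13 else "Yorkshire"
    f2_rows = []
    a_lo, a_hi = cfg.age_range_days
    for i in range(cfg.n_f2):
        sid = f"F2_{i + 1}"
        sex = "female" if rng.random() < 0.5 else "male"
        dam_hap = "L" if rng.random() < 0.5 else "m"  # from heterozygous F1 dam
        samples.append(sid)
        sexes.append(sex)
        gens.append("F2")
        groups.append("")
        if sex == "female":
            ploidy.append(2)
            haps.append((dam_hap, "L"))  # sire contributes his single X (large)
        else:
            ploidy.append(1)
            haps.append((dam_hap,))
        breed = "Duroc" if rng.random() < 0.5 else "Yorkshire"
        age = float(rng.uniform(a_lo, a_hi))
        f2_rows.append((sid, breed, sex, age, haps[-1]))

    # chip: diagnostic markers (alt = minipig allele) + background markers
    snp_ids = list(INFORMATIVE_SNPS) + [f"BG_{j + 1}" for j in range(12)]
    n_snp = len(snp_ids)
    pos = np.sort(rng.choice(np.arange(52_000_000, 61_000_000), size=n_snp, replace=False))
    geno = np.full((len(samples), n_snp), np.nan)
    for si, h in enumerate(haps):
        mini_dose = sum(1 for x in h if x == "m")
        for j, snp in enumerate(snp_ids):
            if snp in INFORMATIVE_SNPS:
                geno[si, j] = mini_dose
            else:
                p_alt = 0.3
                geno[si, j] = rng.binomial(ploidy[si], p_alt)
    chip = ChipGenotypes(samples=tuple(samples), snp_ids=tuple(snp_ids),
                         chrom=np.array(["X"] * n_snp), pos=pos.astype(np.int64),
                         geno=geno, ploidy=np.array(ploidy, dtype=np.int64),
                         sex=tuple(sexes), generation=tuple(gens), group=tuple(groups))

    amid = (a_lo + a_hi) / 2.0
    rows = []
    for sid, breed, sex, age, h in f2_rows:
        mini_hemi = (sex == "male" and h[0] == "m")
        if sex == "female":
            hap_class = 1 if h == ("L", "L") else 2
        else:
            hap_class = 3 if mini_hemi else 1
        base = (cfg.trait_mean_cm
                + (cfg.breed_effect_cm if breed == "Duroc" else 0.0)
                + (cfg.sex_effect_cm if sex == "male" else 0.0)
                + cfg.age_slope * (age - amid)
                + cfg.age_quad * (age - amid) ** 2
                - (cfg.haplotype_effect_cm if mini_hemi else 0.0))
        rec = {"animal_id": sid, "founder_dam_breed": breed, "sex": sex,
               "age_days": age, "hap_class": hap_class}
        for trait in traits:
            rec[trait] = base + rng.normal(0.0, cfg.residual_sd_cm)
        rows.append(rec)
    records = pd.DataFrame(rows)
    return chip, records


# --- gene annotation for the enrichment stage --------------------------------

def simulate_gene_annotation(cfg: SimConfig, rng: np.random.Generator | None = None,
                             n_genes: int = 2000, n_terms: int = 400,
                             genes_per_term: int = 100,
                             gene_length: int = 20_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random gene intervals plus a random gene -> GO-term mapping.

    Gene starts are uniform over the genome; each term draws
    ``genes_per_term`` member genes uniformly without replacement, so term
    membership is independent of genomic position (a null annotation).
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    chrom_names = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chrom_names], dtype=float)
    probs = lengths / lengths.sum()
    rows = []
    for i in range(n_genes):
        c = chrom_names[rng.choice(len(chrom_names), p=probs)]
        start = int(rng.integers(0, cfg.chrom_lengths[c] - gene_length))
        rows.append((f"gene_{i + 1}", c, start, start + gene_length))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    pairs = []
    ids = genes["gene_id"].to_numpy()
    for t in range(n_terms):
        members = rng.choice(ids, size=genes_per_term, replace=False)
        pairs.extend((g, f"GO:{t + 1:07d}") for g in members)
    go_map = pd.DataFrame(pairs, columns=["gene_id", "term"])
    return genes, go_map
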