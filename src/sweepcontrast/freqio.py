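"""VCF ingest, genotype-quality filtering, and per-breed reference-allele frequencies.

The sweep contrast works on reference-allele frequencies per breed. Two data
modes are supported, mirroring mixed re-sequencing designs:

* *individual* samples carry genotypes with a GQ value; calls below the GQ
  threshold are treated as missing,
* *pool* samples carry ref/alt allele depths and a total depth (DP); sites
  below the DP threshold are treated as missing. A pool contributes one
  diploid pseudo-observation to its breed, with fractional reference count
  ``2 * ref_depth / DP``.

Males are hemizygous on the X chromosome and contribute a single allele there,
whether the call is written as haploid or (redundantly) diploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

X_CHROM_NAMES = frozenset({"X", "chrX", "x"})

GROUPS = ("minipig", "large", "other")
DATA_MODES = ("individual", "pool")
SEXES = ("female", "male", "unknown")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


class ConfigError(ValueError):
    """Raised on inconsistent sample metadata / input configuration."""


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, breed, group, data_mode, sex)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "breed", "group", "data_mode", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise ConfigError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ConfigError(f"duplicate sample_id in metadata: {dup}")
    for col, allowed in (("group", GROUPS), ("data_mode", DATA_MODES), ("sex", SEXES)):
        bad = set(meta[col]) - set(allowed)
        if bad:
            raise ConfigError(f"invalid {col} value(s): {sorted(bad)}")
    return meta


@dataclass
class VariantSite:
    """One biallelic SNP with per-sample payloads.

    ``alleles`` is (n_samples, 2) int8; 0 = reference, 1 = alternative,
    -1 = missing, -2 = absent second allele of a haploid call.
    Depth fields are -1 where not applicable (individual samples).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    samples: tuple[str, ...]
    alleles: np.ndarray
    gq: np.ndarray         # float, NaN where absent
    ref_depth: np.ndarray  # int, -1 where absent
    alt_depth: np.ndarray
    dp: np.ndarray
    is_pool: np.ndarray = field(default=None)  # bool per sample

    def __post_init__(self):
        if self.pos < 1:
            raise VcfParseError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if self.ref == self.alt:
            raise VcfParseError(f"{self.chrom}:{self.pos}: REF equals ALT")
        if self.is_pool is None:
            self.is_pool = np.zeros(len(self.samples), dtype=bool)


def _is_biallelic_snp(ref: str, alts: Sequence[str]) -> bool:
    return len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1 and alts[0] in "ACGT" and ref in "ACGT"


def load_biallelic_snps(vcf_source, meta: pd.DataFrame | None = None,
                        site_filter: Callable[[VariantSite], bool] | None = None) -> Iterator[VariantSite]:
    """Stream biallelic SNPs from a VCF file, dropping indels and multi-allelic records.

    ``site_filter`` is a generic site-level hook (return False to drop a site);
    the default passes everything. Sample order follows the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source), gts012=False)
    samples = tuple(vcf.samples)
    is_pool = np.zeros(len(samples), dtype=bool)
    if meta is not None:
        meta_idx = meta.set_index("sample_id")
        unknown = [s for s in samples if s not in meta_idx.index]
        if unknown:
            raise ConfigError(f"VCF samples absent from metadata: {unknown}")
        is_pool = np.array([meta_idx.loc[s, "data_mode"] == "pool" for s in samples])
    for var in vcf:
        if not _is_biallelic_snp(var.REF, var.ALT):
            continue
        gts = var.genotypes  # list of [a0, (a1,) phased]
        alleles = np.full((len(samples), 2), -1, dtype=np.int8)
        for i, g in enumerate(gts):
            calls = g[:-1]
            for j, a in enumerate(calls[:2]):
                alleles[i, j] = a if a in (0, 1) else -1
            if len(calls) == 1:
                alleles[i, 1] = -2
        gq = var.gt_quals.astype(float) if var.gt_quals is not None else np.full(len(samples), np.nan)
        gq = np.where(gq < 0, np.nan, gq)
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            ad = ad.astype(np.int64)
            ref_d = np.where(ad[:, 0] < 0, -1, ad[:, 0])
            alt_d = np.where(ad[:, 1] < 0, -1, ad[:, 1]) if ad.shape[1] > 1 else np.full(len(samples), -1)
        else:
            ref_d = np.full(len(samples), -1, dtype=np.int64)
            alt_d = np.full(len(samples), -1, dtype=np.int64)
        dp = var.gt_depths.astype(np.int64) if var.gt_depths is not None else np.full(len(samples), -1)
        dp = np.where(dp < 0, -1, dp)
        site = VariantSite(chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0],
                           samples=samples, alleles=alleles, gq=gq,
                           ref_depth=ref_d, alt_depth=alt_d, dp=dp, is_pool=is_pool.copy())
        if site_filter is not None and not site_filter(site):
            continue
        yield site


def apply_genotype_filters(site: VariantSite, min_gq: int = 20, min_pool_dp: int = 4) -> VariantSite:
    """Mask sub-threshold payloads: GQ < ``min_gq`` (individuals), DP < ``min_pool_dp`` (pools).

    Thresholds are inclusive minima ("minimum of X" means >= X passes).
    Filtering never fails and is idempotent.
    """
    if min_gq < 0 or min_pool_dp < 0:
        raise ValueError("filter thresholds must be >= 0")
    alleles = site.alleles.copy()
    dp = site.dp.copy()
    ref_d = site.ref_depth.copy()
    alt_d = site.alt_depth.copy()
    ind = ~site.is_pool
    fail_gq = ind & ((site.gq < min_gq) | (np.isnan(site.gq) & (min_gq > 0)))
    sub = alleles[fail_gq]
    sub[sub != -2] = -1  # keep the haploid sentinel, mask called alleles
    alleles[fail_gq] = sub
    fail_dp = site.is_pool & (dp < min_pool_dp)
    dp[fail_dp] = -1
    ref_d[fail_dp] = -1
    alt_d[fail_dp] = -1
    return replace(site, alleles=alleles, dp=dp, ref_depth=ref_d, alt_depth=alt_d)


@dataclass
class BreedFrequencyTable:
    """Per-locus reference-allele frequency per breed.

    ``freq`` and ``n_alleles`` are (n_loci, n_breeds); missing cells are NaN in
    ``freq`` and 0 in ``n_alleles``. ``loci`` has columns chrom, pos (1-based).
    """

    loci: pd.DataFrame
    breeds: tuple[str, ...]
    freq: np.ndarray
    n_alleles: np.ndarray

    def __post_init__(self):
        ok = ~np.isnan(self.freq)
        if ok.any():
            vals = self.freq[ok]
            if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
                raise ValueError("frequencies outside [0, 1]")
            if (self.n_alleles[ok] < 1).any():
                raise ValueError("present frequency cell with n_alleles < 1")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def breed_index(self, breed: str) -> int:
        return self.breeds.index(breed)

    def to_frame(self) -> pd.DataFrame:
        df = self.loci[["chrom", "pos"]].copy()
        for j, b in enumerate(self.breeds):
            df[b] = self.freq[:, j]
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_cache(self, path) -> None:
        np.savez_compressed(path, chrom=self.loci["chrom"].to_numpy(dtype="U"),
                            pos=self.loci["pos"].to_numpy(),
                            breeds=np.array(self.breeds, dtype="U"),
                            freq=self.freq, n_alleles=self.n_alleles)

    @classmethod
    def read_cache(cls, path) -> "BreedFrequencyTable":
        z = np.load(path, allow_pickle=False)
        loci = pd.DataFrame({"chrom": z["chrom"].astype(str), "pos": z["pos"].astype(np.int64)})
        return cls(loci=loci, breeds=tuple(z["breeds"].astype(str)),
                   freq=z["freq"], n_alleles=z["n_alleles"])


def breed_allele_frequencies(sites: Iterable[VariantSite], meta: pd.DataFrame,
                             x_chroms: frozenset = X_CHROM_NAMES) -> BreedFrequencyTable:
    """Aggregate filtered sites into per-breed reference-allele frequencies.

    Individuals contribute their called alleles (one allele for males on X);
    pools contribute a diploid pseudo-observation of 2 * ref_depth / DP
    reference alleles. Breeds with no called data at a locus get a missing cell.
    """
    meta_idx = meta.set_index("sample_id")
    breeds = tuple(dict.fromkeys(meta["breed"]))
    b_of = {s: breeds.index(meta_idx.loc[s, "breed"]) for s in meta_idx.index}
    male = {s: meta_idx.loc[s, "sex"] == "male" for s in meta_idx.index}

    chroms, poss, freq_rows, n_rows = [], [], [], []
    for site in sites:
        unknown = [s for s in site.samples if s not in b_of]
        if unknown:
            raise ConfigError(f"VCF samples absent from metadata: {unknown}")
        on_x = site.chrom in x_chroms
        ref_count = np.zeros(len(breeds))
        n_called = np.zeros(len(breeds))
        for i, s in enumerate(site.samples):
            j = b_of[s]
            if site.is_pool[i]:
                if site.dp[i] >= 1 and site.ref_depth[i] >= 0:
                    ref_count[j] += 2.0 * site.ref_depth[i] / site.dp[i]
                    n_called[j] += 2.0
                continue
            calls = site.alleles[i]
            calls = calls[calls >= 0]
            if on_x and male[s]:
                calls = calls[:1]  # hemizygous: one allele
            if len(calls):
                ref_count[j] += float((calls == 0).sum())
                n_called[j] += float(len(calls))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, ref_count / np.maximum(n_called, 1), np.nan)
        chroms.append(site.chrom)
        poss.append(site.pos)
        freq_rows.append(p)
        n_rows.append(n_called)

    loci = pd.DataFrame({"chrom": chroms, "pos": np.array(poss, dtype=np.int64)})
    freq = np.array(freq_rows) if freq_rows else np.empty((0, len(breeds)))
    n = np.array(n_rows) if n_rows else np.empty((0, len(breeds)))
    return BreedFrequencyTable(loci=loci, breeds=breeds, freq=freq, n_alleles=n)
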