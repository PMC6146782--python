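import numpy as np
import pandas as pd
import pytest

from sweepcontrast.freqio import VariantSite


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_site(chrom="1", pos=100, ref="A", alt="G", genotypes=(), gq=None,
              pools=(), sexes=None):
    """Construct a VariantSite from compact genotype strings.

    ``genotypes``: e.g. ("0/0", "0/1", "1", "./.") — "1" is a haploid call.
    ``pools``: list of (ref_depth, alt_depth, dp) appended as pool samples.
    """
    n_ind = len(genotypes)
    n = n_ind + len(pools)
    samples = tuple(f"s{i}" for i in range(n))
    alleles = np.full((n, 2), -1, dtype=np.int8)
    for i, g in enumerate(genotypes):
        parts = g.replace("|", "/").split("/")
        if len(parts) == 1:
            alleles[i, 0] = -1 if parts[0] == "." else int(parts[0])
            alleles[i, 1] = -2
        else:
            for j, a in enumerate(parts[:2]):
                alleles[i, j] = -1 if a == "." else int(a)
    gq_arr = np.full(n, np.nan)
    if gq is not None:
        gq_arr[:n_ind] = gq
    else:
        gq_arr[:n_ind] = 99.0
    ref_d = np.full(n, -1, dtype=np.int64)
    alt_d = np.full(n, -1, dtype=np.int64)
    dp = np.full(n, -1, dtype=np.int64)
    for j, (r, a, d) in enumerate(pools):
        ref_d[n_ind + j] = r
        alt_d[n_ind + j] = a
        dp[n_ind + j] = d
    is_pool = np.array([False] * n_ind + [True] * len(pools))
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt, samples=samples,
                       alleles=alleles, gq=gq_arr, ref_depth=ref_d, alt_depth=alt_d,
                       dp=dp, is_pool=is_pool)


def meta_for_site(site, breeds=None, sexes=None, group="other"):
    """Metadata frame matching a site's samples (one breed unless specified)."""
    n = len(site.samples)
    breeds = breeds or ["b1"] * n
    sexes = sexes or ["female"] * n
    return pd.DataFrame({
        "sample_id": list(site.samples),
        "breed": breeds,
        "group": [group] * n,
        "data_mode": ["pool" if p else "individual" for p in site.is_pool],
        "sex": sexes,
    })
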