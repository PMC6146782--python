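"""In-silico pooling: group-level allele frequencies from per-breed frequencies.

The two contrasting virtual pools (large-pig pool, LPP; minipig pool, MPP) are
built as the *unweighted* average of the member breeds' reference-allele
frequencies. A locus is excluded from both pools when fewer than 50% of the
breeds in either group have a record there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .freqio import BreedFrequencyTable, ConfigError


@dataclass
class GroupPool:
    """Pooled frequencies for one breed group on the retained locus set."""

    group: str
    member_breeds: tuple[str, ...]
    loci: pd.DataFrame            # chrom, pos of retained loci
    pooled_freq: np.ndarray       # p̄ per retained locus
    n_breeds_with_record: np.ndarray


def insilico_pool(table: BreedFrequencyTable, membership: dict[str, list[str]],
                  min_record_fraction: float = 0.5) -> tuple[GroupPool, GroupPool]:
    """Build the two in-silico pools from a breed frequency table.

    ``membership`` maps the two group names to their member breeds. The pooled
    frequency is the arithmetic mean over member breeds with a record. Loci
    where the breeds-with-record fraction is strictly below
    ``min_record_fraction`` in *either* group are dropped from both pools.
    """
    if len(membership) != 2:
        raise ConfigError("membership must define exactly two groups")
    names = list(membership)
    cols = {}
    for g in names:
        breeds = membership[g]
        if not breeds:
            raise ConfigError(f"group {g!r} is empty")
        missing = set(breeds) - set(table.breeds)
        if missing:
            raise ConfigError(f"group {g!r} lists unknown breeds: {sorted(missing)}")
        cols[g] = [table.breed_index(b) for b in breeds]
    overlap = set(membership[names[0]]) & set(membership[names[1]])
    if overlap:
        raise ConfigError(f"breeds in both groups: {sorted(overlap)}")

    keep = np.ones(table.n_loci, dtype=bool)
    means, counts = {}, {}
    for g in names:
        sub = table.freq[:, cols[g]]
        n_rec = (~np.isnan(sub)).sum(axis=1)
        sums = np.nansum(sub, axis=1)
        means[g] = np.where(n_rec > 0, sums / np.maximum(n_rec, 1), np.nan)
        counts[g] = n_rec
        keep &= n_rec / len(cols[g]) >= min_record_fraction

    loci = table.loci.loc[keep, ["chrom", "pos"]].reset_index(drop=True)
    pools = tuple(
        GroupPool(group=g, member_breeds=tuple(membership[g]), loci=loci,
                  pooled_freq=means[g][keep], n_breeds_with_record=counts[g][keep])
        for g in names
    )
    return pools


def membership_from_metadata(meta: pd.DataFrame,
                             groups: tuple[str, str] = ("large", "minipig")) -> dict[str, list[str]]:
    """Derive pool membership from the metadata group column."""
    out = {}
    for g in groups:
        breeds = list(dict.fromkeys(meta.loc[meta["group"] == g, "breed"]))
        if not breeds:
            raise ConfigError(f"no breeds with group={g!r} in metadata")
        out[g] = breeds
    return out


def pooled_frequency_frame(pool_a: GroupPool, pool_b: GroupPool) -> pd.DataFrame:
    """TSV-ready frame: chrom, pos, p_<groupA>, p_<groupB>."""
    df = pool_a.loci.copy()
    df[f"p_{pool_a.group}"] = pool_a.pooled_freq
    df[f"p_{pool_b.group}"] = pool_b.pooled_freq
    return df
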