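"""Genomic interval utilities on 0-based half-open coordinates.

Regions are plain :class:`pandas.DataFrame` objects with at least the columns
``chrom`` (str), ``start`` and ``end`` (int, half-open). Sweep-region frames
additionally carry ``source`` (comma-joined provenance labels) and ``padded``
(bool). All functions return new frames and never mutate their inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REGION_COLUMNS = ["chrom", "start", "end"]


def empty_regions(extra: tuple[str, ...] = ()) -> pd.DataFrame:
    cols = REGION_COLUMNS + list(extra)
    return pd.DataFrame({c: pd.Series(dtype="int64" if c in ("start", "end") else "object") for c in cols})


def _check(regions: pd.DataFrame) -> None:
    if len(regions) and not (regions["end"] > regions["start"]).all():
        raise ValueError("regions must satisfy end > start")


def merge_regions(regions: pd.DataFrame, join_source: bool = False) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals per chromosome.

    With ``join_source`` the ``source`` labels of merged members are unioned.
    """
    _check(regions)
    if not len(regions):
        return regions.copy()
    has_source = join_source and "source" in regions.columns
    out = []
    for chrom, grp in regions.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"])
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        srcs = grp["source"].tolist() if has_source else None
        cur_s, cur_e = starts[0], ends[0]
        cur_src = set(srcs[0].split(",")) if has_source else None
        for i in range(1, len(grp)):
            if starts[i] <= cur_e:  # overlap or abut
                cur_e = max(cur_e, ends[i])
                if has_source:
                    cur_src |= set(srcs[i].split(","))
            else:
                out.append((chrom, cur_s, cur_e, ",".join(sorted(cur_src)) if has_source else None))
                cur_s, cur_e = starts[i], ends[i]
                cur_src = set(srcs[i].split(",")) if has_source else None
        out.append((chrom, cur_s, cur_e, ",".join(sorted(cur_src)) if has_source else None))
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "source"])
    if not has_source:
        df = df.drop(columns="source")
    return df.reset_index(drop=True)


def total_length(regions: pd.DataFrame) -> int:
    """Total base pairs covered after merging overlaps."""
    merged = merge_regions(regions[REGION_COLUMNS]) if len(regions) else regions
    if not len(merged):
        return 0
    return int((merged["end"] - merged["start"]).sum())


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap >= 1 bp of any subject interval?"""
    _check(query)
    _check(subject)
    result = np.zeros(len(query), dtype=bool)
    if not len(query) or not len(subject):
        return result
    merged = merge_regions(subject[REGION_COLUMNS])
    for chrom, grp in merged.groupby("chrom"):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy()
        qe = query.loc[mask, "end"].to_numpy()
        ss = grp["start"].to_numpy()
        se = grp["end"].to_numpy()
        # half-open overlap: exists j with ss[j] < qe and se[j] > qs
        idx = np.searchsorted(se, qs, side="right")
        hit = (idx < len(ss)) & (ss[np.minimum(idx, len(ss) - 1)] < qe)
        result[np.flatnonzero(mask)] = hit
    return result


def overlap_length(query: pd.DataFrame, subject: pd.DataFrame) -> int:
    """Base pairs in the intersection of the two (merged) region sets."""
    a = merge_regions(query[REGION_COLUMNS]) if len(query) else query
    b = merge_regions(subject[REGION_COLUMNS]) if len(subject) else subject
    total = 0
    if not len(a) or not len(b):
        return 0
    for chrom, ga in a.groupby("chrom"):
        gb = b[b["chrom"] == chrom]
        if not len(gb):
            continue
        for s, e in zip(ga["start"], ga["end"]):
            ov = np.minimum(gb["end"].to_numpy(), e) - np.maximum(gb["start"].to_numpy(), s)
            total += int(ov[ov > 0].sum())
    return total


def pad_regions(regions: pd.DataFrame, pad: int, genome_lengths: dict[str, int]) -> pd.DataFrame:
    """Extend each interval by ``pad`` bp on both sides, clipped to [0, chrom length]."""
    _check(regions)
    out = regions.copy()
    if not len(out):
        return out
    missing = set(out["chrom"]) - set(genome_lengths)
    if missing:
        raise ValueError(f"regions on chromosomes without a declared length: {sorted(missing)}")
    lens = out["chrom"].map(genome_lengths).to_numpy()
    out["start"] = np.maximum(out["start"].to_numpy() - pad, 0)
    out["end"] = np.minimum(out["end"].to_numpy() + pad, lens)
    return out


def genome_fraction(regions: pd.DataFrame, genome_lengths: dict[str, int]) -> float:
    """Fraction of the genome covered by the merged regions."""
    _check(regions)
    if len(regions):
        chrom_len = regions["chrom"].map(genome_lengths)
        if chrom_len.isna().any():
            raise ValueError("region on chromosome absent from genome_lengths")
        if ((regions["start"] < 0) | (regions["end"] > chrom_len)).any():
            raise ValueError("region outside chromosome bounds")
    genome = sum(genome_lengths.values())
    if genome <= 0:
        raise ValueError("genome has zero length")
    return total_length(regions) / genome


def write_bed(regions: pd.DataFrame, path) -> None:
    """Write regions as BED; the 4th column carries the source labels if present."""
    cols = REGION_COLUMNS + (["source"] if "source" in regions.columns else [])
    regions[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; extra columns beyond the 4th are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name"})
    keep = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    out = df[keep].copy()
    out["chrom"] = out["chrom"].astype(str)
    return out
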