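"""Windowed sweep statistics and outlier-region calling.

The scan works on overlapping sliding windows (default 100 kb, 80% overlap,
i.e. a 20 kb step). Per-locus statistics — expected heterozygosity of the
minipig pool, and the two-population fixation index — are averaged per window,
heterozygosity is Z-normalised (autosomes and X separately), and outlier
regions are called with a seed-and-extend rule: a window beyond the seed
quantile starts a region, which grows over contiguous windows beyond the
extension quantile. Heterozygosity and CLR regions are unioned, intersected
with high-FST regions, length-filtered and padded to give the final sweeps.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import regions as rg

WINDOW_SIZE = 100_000
WINDOW_OVERLAP = 0.8
MIN_LOCI_PER_WINDOW = 10

TRACK_COLUMNS = ["chrom", "start", "end", "value", "n_loci"]


def expected_heterozygosity(p):
    """Hexp = 2p(1-p) for reference-allele frequency p (scalar or array)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def fst_locus(p1, n1, p2, n2):
    """Two-population fixation index at a locus.

    With group frequencies p_i and sizes n_i: p̄ is the weighted mean
    frequency, n̄ the average group size, and

        FST = [Σ n_i (p_i - p̄)² / (2 n̄)] / [p̄ (1 - p̄)]

    Returns NaN where p̄ is 0 or 1 (undefined denominator). Vectorised.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 < 1) or np.any(n2 < 1):
        raise ValueError("group sizes must be >= 1")
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    nbar = (n1 + n2) / 2.0
    num = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / (2.0 * nbar)
    den = pbar * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def make_windows(chrom_length: int, size: int = WINDOW_SIZE,
                 overlap: float = WINDOW_OVERLAP) -> np.ndarray:
    """Window start positions on one chromosome (0-based half-open windows).

    Step = size * (1 - overlap). Trailing partial windows are dropped so every
    window has equal size (keeps Z-scores comparable across windows).
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    step = int(round(size * (1.0 - overlap)))
    if step < 1:
        raise ValueError("window step rounds to zero")
    if chrom_length < size:
        return np.empty(0, dtype=np.int64)
    last_start = chrom_length - size
    return np.arange(0, last_start + 1, step, dtype=np.int64)


def window_mean(loci: pd.DataFrame, value: np.ndarray, genome_lengths: dict[str, int],
                size: int = WINDOW_SIZE, overlap: float = WINDOW_OVERLAP,
                min_loci: int = MIN_LOCI_PER_WINDOW, statistic_name: str = "stat") -> pd.DataFrame:
    """Average a per-locus statistic in sliding windows.

    ``loci`` has chrom and pos (1-based) columns sorted by position within each
    chromosome; NaN locus values are ignored. Windows with fewer than
    ``min_loci`` contributing loci get a missing (NaN) value. Returns a window
    track frame (chrom, start, end, value, n_loci) whose ``attrs['statistic']``
    records the statistic name.

    Uses the fact that with step = size*(1-overlap) each window is a run of
    ``size/step`` consecutive step-bins, so per-bin sums give all window sums.
    """
    value = np.asarray(value, dtype=float)
    step = int(round(size * (1.0 - overlap)))
    bins_per_window = size // step if size % step == 0 else None
    frames = []
    for chrom, length in genome_lengths.items():
        starts = make_windows(length, size, overlap)
        if not len(starts):
            continue
        mask = (loci["chrom"] == chrom).to_numpy()
        pos0 = loci.loc[mask, "pos"].to_numpy(dtype=np.int64) - 1  # to 0-based
        vals = value[mask]
        ok = ~np.isnan(vals) & (pos0 >= 0) & (pos0 < length)
        pos0, vals = pos0[ok], vals[ok]
        if bins_per_window is not None:
            nbins = (length // step) + 1
            b = pos0 // step
            sums = np.bincount(b, weights=vals, minlength=nbins)
            cnts = np.bincount(b, minlength=nbins)
            csum = np.concatenate([[0.0], np.cumsum(sums)])
            ccnt = np.concatenate([[0], np.cumsum(cnts)])
            i0 = starts // step
            wsum = csum[i0 + bins_per_window] - csum[i0]
            wcnt = (ccnt[i0 + bins_per_window] - ccnt[i0]).astype(np.int64)
        else:  # irregular step: direct per-window scan
            order = np.argsort(pos0, kind="stable")
            pos0, vals = pos0[order], vals[order]
            csum = np.concatenate([[0.0], np.cumsum(vals)])
            lo = np.searchsorted(pos0, starts, side="left")
            hi = np.searchsorted(pos0, starts + size, side="left")
            wsum = csum[hi] - csum[lo]
            wcnt = (hi - lo).astype(np.int64)
        with np.errstate(invalid="ignore"):
            wval = np.where(wcnt >= max(min_loci, 1), wsum / np.maximum(wcnt, 1), np.nan)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                    "end": starts + size, "value": wval, "n_loci": wcnt}))
    track = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACK_COLUMNS)
    track.attrs["statistic"] = statistic_name
    return track


def znormalize(track: pd.DataFrame, x_chroms=("X", "chrX")) -> pd.DataFrame:
    """Z-score window values, normalising autosomes and the X chromosome separately.

    Uses the population (n-denominator) standard deviation over non-missing
    windows of each partition. Raises on a degenerate (constant) partition.
    """
    out = track.copy()
    on_x = out["chrom"].isin(x_chroms).to_numpy()
    for mask, label in ((~on_x, "autosomes"), (on_x, "chrX")):
        vals = out.loc[mask, "value"].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if not mask.any():
            continue
        if len(obs) < 2:
            raise ValueError(f"{label}: need >= 2 non-missing windows to Z-normalise")
        sd = float(np.std(obs))  # population sd
        if sd == 0:
            raise ValueError(f"{label}: zero standard deviation (constant track)")
        out.loc[mask, "value"] = (vals - float(np.mean(obs))) / sd
    out.attrs["statistic"] = track.attrs.get("statistic", "stat") + "_z"
    return out


def call_outlier_regions(track: pd.DataFrame, tail: str = "lower",
                         q_seed: float = 0.01, q_ext: float = 0.05,
                         seed_threshold: float | None = None,
                         ext_threshold: float | None = None,
                         source: str = "hexp") -> pd.DataFrame:
    """Seed-and-extend outlier-region caller.

    Thresholds default to empirical quantiles of the non-missing window values
    (q_seed / q_ext on the chosen tail); fixed thresholds (e.g. the classical
    -2.34 / -1.64 Z cut-offs) can be passed to override them. A window beyond
    the seed threshold starts a region; the region extends over contiguous
    windows beyond the extension threshold; overlapping window spans merge.
    """
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    if q_seed > q_ext:
        raise ValueError("q_seed must be <= q_ext")
    vals_all = track["value"].to_numpy(dtype=float)
    obs = vals_all[~np.isnan(vals_all)]
    if not len(obs):
        return rg.empty_regions(("source",))
    if tail == "lower":
        t_seed = float(np.quantile(obs, q_seed)) if seed_threshold is None else seed_threshold
        t_ext = float(np.quantile(obs, q_ext)) if ext_threshold is None else ext_threshold
    else:
        t_seed = float(np.quantile(obs, 1 - q_seed)) if seed_threshold is None else seed_threshold
        t_ext = float(np.quantile(obs, 1 - q_ext)) if ext_threshold is None else ext_threshold

    pieces = []
    for chrom, grp in track.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        v = grp["value"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if tail == "lower":
            is_seed = v <= t_seed
            is_ext = v <= t_ext
        else:
            is_seed = v >= t_seed
            is_ext = v >= t_ext
        is_seed &= ~np.isnan(v)
        is_ext &= ~np.isnan(v)
        # runs of contiguous extension windows containing >= 1 seed
        i = 0
        n = len(v)
        while i < n:
            if not is_ext[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and is_ext[j + 1]:
                j += 1
            if is_seed[i:j + 1].any():
                pieces.append((chrom, int(starts[i]), int(ends[j])))
            i = j + 1
    if not pieces:
        return rg.empty_regions(("source",))
    out = pd.DataFrame(pieces, columns=["chrom", "start", "end"])
    out = rg.merge_regions(out)
    out["source"] = source
    return out


def combine_signals(hexp_regions: pd.DataFrame, clr_regions: pd.DataFrame,
                    fst_regions: pd.DataFrame, genome_lengths: dict[str, int],
                    min_width: int = 200_000, pad: int = 500_000) -> pd.DataFrame:
    """Final sweep call: (Hexp ∪ CLR) ∩ FST, length filter, then padding.

    Candidates are the union of heterozygosity and CLR regions; only those
    overlapping at least 1 bp of an FST region survive. Candidates narrower
    than ``min_width`` are dropped *before* padding by ``pad`` on each side
    (clipped to chromosome bounds). Overlapping padded regions are merged and
    keep the union of their provenance labels.
    """
    parts = []
    for df, label in ((hexp_regions, "hexp"), (clr_regions, "clr")):
        if len(df):
            d = df[rg.REGION_COLUMNS].copy()
            d["source"] = df["source"] if "source" in df.columns else label
            parts.append(d)
    if not parts:
        return rg.empty_regions(("source", "padded"))
    cand = pd.concat(parts, ignore_index=True)
    cand = rg.merge_regions(cand, join_source=True)
    keep = rg.overlaps_any(cand, fst_regions) if len(fst_regions) else np.zeros(len(cand), bool)
    cand = cand.loc[keep]
    cand = cand.loc[(cand["end"] - cand["start"]) >= min_width]
    if not len(cand):
        return rg.empty_regions(("source", "padded"))
    cand = cand.copy()
    cand["source"] = cand["source"].map(lambda s: ",".join(sorted(set(s.split(",")) | {"fst"})))
    padded = rg.pad_regions(cand, pad, genome_lengths)
    out = rg.merge_regions(padded, join_source=True).sort_values(["chrom", "start"]).reset_index(drop=True)
    out["padded"] = True
    return out


genome_fraction = rg.genome_fraction
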