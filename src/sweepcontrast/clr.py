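"""Composite likelihood ratio (CLR) scan for selective sweeps.

The test contrasts, at each position of a genomic grid, a sweep model against
the genome-wide background site-frequency spectrum (SFS), in the classical
star-phylogeny approximation: during the sweep each of the n sampled lineages
escapes independently with probability

    p_e = 1 - exp(-alpha * d)

where d is the physical distance from the site to the putative sweep centre
and alpha measures sweep strength per base pair (physical distance proxies
recombination distance in the absence of a genetic map). Lineages that fail
to escape coalesce into a single ancestral lineage; escaped lineages draw
their allelic state from the background spectrum. The composite likelihood of
the observed allele counts is maximised over a grid of alpha values and
compared with the background likelihood:

    LR = 2 * (ln CL_sweep - ln CL_background), clipped at 0.

Invariant sites are excluded, so all spectra are conditioned on polymorphism.
A folded spectrum (minor-allele counts) is used by default since ancestral
states are unknown. A parser for grid files produced by the original
SweepFinder implementation is provided for interoperability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import regions as rg


DEFAULT_GRID_STEP = 20_000
DEFAULT_MAX_DIST = 3_000_000
N_PE_BINS = 257


def default_alpha_grid(n_alpha: int = 40, min_footprint: float = 1e4,
                       max_footprint: float = 1e7) -> np.ndarray:
    """Log-spaced alpha values spanning sweep footprints of 10 kb to 10 Mb.

    The footprint is the distance at which the escape probability reaches 1/2,
    i.e. alpha = ln(2) / footprint.
    """
    footprints = np.geomspace(min_footprint, max_footprint, n_alpha)
    return np.log(2.0) / footprints


@dataclass
class SiteSpectrumData:
    """Observed allele counts per polymorphic site.

    ``k`` is the non-reference (or minor, if folded) allele count, ``n`` the
    number of sampled alleles. Invariant sites (k == 0 or k == n) must be
    excluded before construction.
    """

    chrom: np.ndarray
    pos: np.ndarray   # 1-based positions
    k: np.ndarray
    n: np.ndarray
    folded: bool = True

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.k = np.asarray(self.k, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if np.any((self.k < 0) | (self.k > self.n)):
            raise ValueError("allele counts must satisfy 0 <= k <= n")
        if np.any((self.k == 0) | (self.k == self.n)):
            raise ValueError("invariant sites must be excluded")
        if self.folded and np.any(self.k > self.n // 2):
            raise ValueError("folded counts must be minor-allele counts (k <= n/2)")

    def __len__(self) -> int:
        return len(self.pos)


def sites_from_counts(chrom, pos, alt_count, n, folded: bool = True) -> SiteSpectrumData:
    """Build spectrum data from alt-allele counts, dropping invariant sites."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    k = np.asarray(alt_count, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    keep = (k > 0) & (k < n)
    if not keep.any():
        raise ValueError("no variable sites")
    k, n, chrom, pos = k[keep], n[keep], chrom[keep], pos[keep]
    if folded:
        k = np.minimum(k, n - k)
    return SiteSpectrumData(chrom=chrom, pos=pos, k=k, n=n, folded=folded)


def sites_from_frequency_table(table, breeds: list[str], folded: bool = True) -> SiteSpectrumData:
    """Spectrum data from the genotype-backed cells of a breed frequency table.

    Reconstructs per-site alt-allele counts as sum over the given breeds of
    (1 - p) * n_alleles — exact when the table was built from individual
    genotypes (e.g. the minipig breeds of the contrast). Requires every breed
    cell present at a site; sites with missing cells are dropped.
    """
    cols = [table.breed_index(b) for b in breeds]
    f = table.freq[:, cols]
    n = table.n_alleles[:, cols]
    complete = (~np.isnan(f)).all(axis=1)
    alt = np.rint(((1.0 - f) * n)[complete].sum(axis=1)).astype(np.int64)
    tot = np.rint(n[complete].sum(axis=1)).astype(np.int64)
    return sites_from_counts(table.loci.loc[complete, "chrom"].to_numpy(),
                             table.loci.loc[complete, "pos"].to_numpy(),
                             alt, tot, folded=folded)


def background_sfs(data: SiteSpectrumData) -> np.ndarray:
    """Empirical background spectrum: P(count class) over the observed classes.

    Returns a vector over k = 0..n (folded: only k <= n/2 populated); entries
    sum to 1 and invariant classes are zero by construction.
    """
    if len(data) == 0:
        raise ValueError("no variable sites")
    n = int(data.n[0])
    if not np.all(data.n == n):
        raise ValueError("background spectrum requires a constant sample size n")
    counts = np.bincount(data.k, minlength=n + 1).astype(float)
    return counts / counts.sum()


class _SweepModel:
    """Precomputed sweep-model site probabilities on a grid of escape probabilities.

    For constant sample size n, tabulates P(observed class k | p_e) for
    N_PE_BINS values of p_e in [0, 1]; the scan then looks probabilities up by
    binned p_e = exp(-alpha d). All spectra are conditioned on polymorphism.
    """

    def __init__(self, bg: np.ndarray, n: int, folded: bool):
        self.n = n
        self.folded = folded
        # Unfolded working spectrum: split folded mass symmetrically.
        b = np.zeros(n + 1)
        if folded:
            for k in range(1, n // 2 + 1):
                if k == n - k:
                    b[k] = bg[k]
                else:
                    b[k] = b[k] + bg[k] / 2.0
                    b[n - k] = b[n - k] + bg[k] / 2.0
        else:
            b = bg.copy()
        b[0] = b[n] = 0.0
        b = b / b.sum()
        self._b = b
        # Downsampled spectra B[m][i]: P(i derived among m lineages), m = 1..n.
        ks = np.arange(n + 1)
        self._bm = []
        for m in range(0, n + 1):
            if m == 0:
                self._bm.append(np.zeros(1))
                continue
            ii = np.arange(m + 1)
            # hypergeom.pmf(i; N=n, K=k, m) for all i, k
            pm = stats.hypergeom.pmf(ii[:, None], n, ks[None, :], m)
            self._bm.append(pm @ b)
        self._table = self._build_table()
        with np.errstate(divide="ignore"):
            self._log_table = np.log(self._table)
        self.pe_grid = np.linspace(0.0, 1.0, N_PE_BINS)

    def _build_table(self) -> np.ndarray:
        n = self.n
        pe_grid = np.linspace(0.0, 1.0, N_PE_BINS)
        # pe = 0 exactly makes polymorphism impossible; evaluate the bin at a
        # tiny escape probability so conditioning yields the pe -> 0+ limit.
        pe_grid = pe_grid.copy()
        pe_grid[0] = 1e-8
        js = np.arange(n + 1)
        table = np.zeros((N_PE_BINS, n + 1))
        for bi, pe in enumerate(pe_grid):
            pj = stats.binom.pmf(js, n, pe)
            dist = np.zeros(n + 1)
            # j = n: all escape, plain background
            dist += pj[n] * self._b
            for j in range(0, n):
                m = j + 1
                bm = self._bm[m]
                ii = np.arange(m + 1)
                w = pj[j] * bm
                # collapsed lineage derived (prob i/m): k = n - j + i - 1
                kd = n - j + ii - 1
                np.add.at(dist, kd, w * (ii / m))
                # collapsed lineage ancestral: k = i
                np.add.at(dist, ii, w * (1.0 - ii / m))
            dist[0] = dist[n] = 0.0  # condition on polymorphism
            s = dist.sum()
            if s > 0:
                dist = dist / s
            if self.folded:
                fold = np.zeros(n + 1)
                for k in range(1, n // 2 + 1):
                    fold[k] = dist[k] + (dist[n - k] if k != n - k else 0.0)
                dist = fold
            table[bi] = dist
        return table

    def log_prob(self, k: np.ndarray, pe: np.ndarray) -> np.ndarray:
        """log P(k | p_e) with p_e binned to the precomputed grid; broadcastable."""
        bi = np.rint(pe * (N_PE_BINS - 1)).astype(np.int64)
        return self._log_table[bi, k]


def clr_scan(data: SiteSpectrumData, genome_lengths: dict[str, int],
             grid_step: int = DEFAULT_GRID_STEP, alpha_grid: np.ndarray | None = None,
             max_dist: int = DEFAULT_MAX_DIST) -> pd.DataFrame:
    """Composite likelihood ratio scan on a regular grid.

    Returns a frame chrom/pos/lr/alpha, one row per grid point. Sites further
    than ``max_dist`` from a grid point are treated as fully escaped (they
    contribute identically to both models and cancel). Grid points with no
    site in range have LR = 0.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if len(alpha_grid) == 0:
        return pd.DataFrame(columns=["chrom", "pos", "lr", "alpha"])
    if np.any(alpha_grid <= 0):
        raise ValueError("alpha grid must be positive")
    n = int(data.n[0])
    if not np.all(data.n == n):
        raise ValueError("clr_scan requires a constant sample size n")
    bg = background_sfs(data)
    model = _SweepModel(bg, n, data.folded)
    with np.errstate(divide="ignore"):
        log_bg = np.log(np.where(bg > 0, bg, 1.0))
    frames = []
    block_size = 256
    for chrom, length in genome_lengths.items():
        sel = data.chrom == chrom
        pos = data.pos[sel].astype(np.int64)
        k = data.k[sel]
        order = np.argsort(pos, kind="stable")
        pos, k = pos[order], k[order]
        site_log_bg = log_bg[k]
        grid = np.arange(grid_step // 2, length, grid_step, dtype=np.int64)
        lr_out = np.zeros(len(grid))
        alpha_out = np.full(len(grid), float(alpha_grid[0]))
        for b0 in range(0, len(grid), block_size):
            block = grid[b0:b0 + block_size]
            lo = int(np.searchsorted(pos, block[0] - max_dist, side="left"))
            hi = int(np.searchsorted(pos, block[-1] + max_dist, side="right"))
            if hi <= lo:
                continue
            d = np.abs(pos[lo:hi][None, :] - block[:, None]).astype(float)  # (B, S)
            in_range = d <= max_dist
            kk = np.broadcast_to(k[lo:hi], d.shape)
            # ll0 over the in-range sites of each grid point
            ll0 = np.where(in_range, site_log_bg[lo:hi][None, :], 0.0).sum(axis=1)
            best_ll = np.full(len(block), -np.inf)
            best_a = np.zeros(len(block), dtype=np.int64)
            for ai, alpha in enumerate(alpha_grid):
                pe = -np.expm1(-alpha * d)  # escape probability
                lp = model.log_prob(kk, pe)
                ll = np.where(in_range, lp, 0.0).sum(axis=1)
                better = ll > best_ll
                best_ll[better] = ll[better]
                best_a[better] = ai
            lr_out[b0:b0 + len(block)] = np.maximum(0.0, 2.0 * (best_ll - ll0))
            alpha_out[b0:b0 + len(block)] = alpha_grid[best_a]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": grid,
                                    "lr": lr_out, "alpha": alpha_out}))
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "lr", "alpha"])
    return out


def parse_sweepfinder_grid(source, chrom: str = "1") -> pd.DataFrame:
    """Parse a SweepFinder-style grid file (columns location, LR, alpha).

    Positions are returned ascending; out-of-order input is re-sorted with a
    warning. The single-chromosome grid is labelled with ``chrom``.
    """
    try:
        df = pd.read_csv(source, sep=r"\s+", header=0)
    except pd.errors.EmptyDataError as exc:
        raise ValueError("empty SweepFinder grid file") from exc
    if df.shape[1] < 3:
        raise ValueError("expected >= 3 whitespace-delimited columns (location, LR, alpha)")
    df = df.iloc[:, :3].copy()
    df.columns = ["pos", "lr", "alpha"]
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(f"non-numeric value in column {col!r} at data line {bad + 1}") from exc
    if len(df) == 0:
        raise ValueError("SweepFinder grid file contains no data rows")
    if not df["pos"].is_monotonic_increasing:
        warnings.warn("SweepFinder grid positions out of order; re-sorting", stacklevel=2)
        df = df.sort_values("pos").reset_index(drop=True)
    df.insert(0, "chrom", chrom)
    df["pos"] = df["pos"].astype(np.int64)
    return df


def clr_regions(results: pd.DataFrame, q: float = 0.01,
                grid_step: int = DEFAULT_GRID_STEP) -> pd.DataFrame:
    """Top-q CLR regions: grid points with LR >= the (1-q) empirical quantile.

    Ties at the threshold are kept. Adjacent selected grid points merge; each
    selected point spans half a grid step to each side.
    """
    if not len(results):
        raise ValueError("empty CLR results")
    lr = results["lr"].to_numpy(dtype=float)
    thr = float(np.quantile(lr, 1.0 - q))
    sel = results.loc[lr >= thr]
    pieces = pd.DataFrame({
        "chrom": sel["chrom"],
        "start": np.maximum(sel["pos"].to_numpy() - grid_step // 2, 0),
        "end": sel["pos"].to_numpy() + grid_step // 2,
    })
    out = rg.merge_regions(pieces)
    out["source"] = "clr"
    return out
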