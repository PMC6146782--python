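"""End-to-end orchestration of the sweep-contrast workflow.

Ties the stages together: breed frequencies -> in-silico pools -> windowed
Hexp / FST tracks -> outlier regions -> (optional) CLR scan -> combined sweep
regions. Each stage returns plain frames so intermediate results can be
cached, written and restarted independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clr as clr_mod
from . import regions as rg
from . import sweepscan as sw
from .freqio import BreedFrequencyTable
from .pooling import insilico_pool


@dataclass
class ScanParams:
    """All tunables of the windowed scan, at the classical defaults."""

    window: int = sw.WINDOW_SIZE
    overlap: float = sw.WINDOW_OVERLAP
    min_loci: int = sw.MIN_LOCI_PER_WINDOW
    q_seed: float = 0.01
    q_ext: float = 0.05
    z_seed: float | None = None  # e.g. -2.34 fixed-threshold override
    z_ext: float | None = None   # e.g. -1.64
    min_width: int = 200_000
    pad: int = 500_000
    clr_q: float = 0.01
    clr_grid_step: int = clr_mod.DEFAULT_GRID_STEP

    def __post_init__(self):
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must be in [0, 1)")
        if not (0 < self.q_seed <= self.q_ext < 1):
            raise ValueError("need 0 < q_seed <= q_ext < 1")


@dataclass
class ScanResult:
    pools: tuple
    hexp_z: pd.DataFrame
    fst_track: pd.DataFrame
    hexp_regions: pd.DataFrame
    fst_regions: pd.DataFrame
    clr_grid: pd.DataFrame | None
    clr_regions: pd.DataFrame
    combined: pd.DataFrame


def sweep_scan(table: BreedFrequencyTable, membership: dict[str, list[str]],
               genome_lengths: dict[str, int], params: ScanParams | None = None,
               mpp_group: str = "minipig",
               clr_data: clr_mod.SiteSpectrumData | None = None,
               clr_grid: pd.DataFrame | None = None) -> ScanResult:
    """Run the full contrast scan and combine the signals.

    Expected heterozygosity is computed from the minipig pool frequency,
    Z-normalised (autosomes vs X separately) and screened for low outliers;
    FST between the two pools is screened for high outliers; CLR evidence may
    come from an internal scan (``clr_data``) or an external grid
    (``clr_grid``). The final call is (Hexp ∪ CLR) ∩ FST with the minimum
    width and padding rules applied.
    """
    params = params or ScanParams()
    pool_a, pool_b = insilico_pool(table, membership)
    mpp = pool_a if pool_a.group == mpp_group else pool_b
    lpp = pool_b if mpp is pool_a else pool_a

    hexp = sw.expected_heterozygosity(np.clip(mpp.pooled_freq, 0.0, 1.0))
    hexp_track = sw.window_mean(mpp.loci, hexp, genome_lengths, params.window,
                                params.overlap, params.min_loci, "hexp")
    hexp_z = sw.znormalize(hexp_track)
    hexp_regions = sw.call_outlier_regions(
        hexp_z, tail="lower", q_seed=params.q_seed, q_ext=params.q_ext,
        seed_threshold=params.z_seed, ext_threshold=params.z_ext, source="hexp")

    fst = sw.fst_locus(np.clip(lpp.pooled_freq, 0, 1), np.maximum(lpp.n_breeds_with_record, 1),
                       np.clip(mpp.pooled_freq, 0, 1), np.maximum(mpp.n_breeds_with_record, 1))
    fst_track = sw.window_mean(mpp.loci, fst, genome_lengths, params.window,
                               params.overlap, params.min_loci, "fst")
    fst_regions = sw.call_outlier_regions(
        fst_track, tail="upper", q_seed=params.q_seed, q_ext=params.q_ext, source="fst")

    grid = clr_grid
    if grid is None and clr_data is not None:
        grid = clr_mod.clr_scan(clr_data, genome_lengths, grid_step=params.clr_grid_step)
    if grid is not None and len(grid):
        clr_reg = clr_mod.clr_regions(grid, q=params.clr_q, grid_step=params.clr_grid_step)
    else:
        clr_reg = rg.empty_regions(("source",))

    combined = sw.combine_signals(hexp_regions, clr_reg, fst_regions, genome_lengths,
                                  min_width=params.min_width, pad=params.pad)
    return ScanResult(pools=(lpp, mpp), hexp_z=hexp_z, fst_track=fst_track,
                      hexp_regions=hexp_regions, fst_regions=fst_regions,
                      clr_grid=grid, clr_regions=clr_reg, combined=combined)


def recovery_stats(combined: pd.DataFrame, truth: pd.DataFrame,
                   genome_lengths: dict[str, int]) -> dict[str, float]:
    """Truth comparison: recovered truth intervals and false-positive fraction.

    A truth interval counts as recovered when any combined region overlaps it
    by >= 1 bp. The false-positive genome fraction is the genome share covered
    by combined regions that overlap *no* truth interval (padding around a
    recovered sweep is method behaviour, not a false call).
    """
    if not len(truth):
        raise ValueError("empty truth set")
    recovered = rg.overlaps_any(truth, combined) if len(combined) else np.zeros(len(truth), bool)
    if len(combined):
        is_fp = ~rg.overlaps_any(combined, truth)
        fp_fraction = rg.genome_fraction(combined.loc[is_fp], genome_lengths)
    else:
        fp_fraction = 0.0
    return {
        "n_truth": int(len(truth)),
        "n_recovered": int(recovered.sum()),
        "recovered_fraction": float(recovered.mean()),
        "false_positive_genome_fraction": float(fp_fraction),
        "detected_genome_fraction": rg.genome_fraction(combined, genome_lengths) if len(combined) else 0.0,
    }
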