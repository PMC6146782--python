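"""Window machinery, per-locus statistics, outlier calling, signal combination."""

import numpy as np
import pandas as pd
import pytest

from sweepcontrast import regions as rg
from sweepcontrast.sweepscan import (call_outlier_regions, combine_signals,
                                     expected_heterozygosity, fst_locus,
                                     genome_fraction, make_windows, window_mean,
                                     znormalize)


class TestFormulas:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.5, 0.5), (0.2, 0.32), (1.0, 0.0)])
    def test_hexp(self, p, expected):
        assert expected_heterozygosity(p) == pytest.approx(expected)

    def test_hexp_domain(self):
        with pytest.raises(ValueError):
            expected_heterozygosity(1.2)

    @pytest.mark.parametrize("p1,n1,p2,n2,expected", [
        (0.3, 10, 0.3, 10, 0.0),
        (1.0, 10, 0.0, 10, 1.0),
        (0.8, 10, 0.2, 10, 0.36),  # p̄=0.5, numerator 0.09, denominator 0.25
    ])
    def test_fst(self, p1, n1, p2, n2, expected):
        assert fst_locus(p1, n1, p2, n2) == pytest.approx(expected)

    def test_fst_undefined_at_joint_fixation(self):
        assert np.isnan(fst_locus(1.0, 10, 1.0, 10))
        assert np.isnan(fst_locus(0.0, 5, 0.0, 7))

    def test_fst_requires_positive_sizes(self):
        with pytest.raises(ValueError):
            fst_locus(0.5, 0, 0.5, 10)


class TestWindows:
    def test_single_window(self):
        np.testing.assert_array_equal(make_windows(100_000), [0])

    def test_enumeration(self):
        # 200 kb chromosome: starts 0, 20k, ..., 100k (windows fully inside)
        starts = make_windows(200_000)
        np.testing.assert_array_equal(starts, np.arange(0, 100_001, 20_000))

    def test_short_chromosome_empty(self):
        assert len(make_windows(50_000)) == 0

    def test_window_mean_simple(self):
        loci = pd.DataFrame({"chrom": ["1", "1"], "pos": [50_001, 90_001]})
        track = window_mean(loci, np.array([0.1, 0.3]), {"1": 100_000}, min_loci=1)
        assert track["value"].iloc[0] == pytest.approx(0.2)

    def test_empty_window_missing(self):
        loci = pd.DataFrame({"chrom": ["1"], "pos": [10]})
        track = window_mean(loci, np.array([0.5]), {"1": 300_000}, min_loci=1)
        # later windows have no loci -> NaN
        assert np.isnan(track["value"].iloc[-1])

    def test_min_loci_masks(self):
        loci = pd.DataFrame({"chrom": ["1"] * 5, "pos": [1, 2, 3, 4, 5]})
        track = window_mean(loci, np.ones(5), {"1": 100_000}, min_loci=6)
        assert np.isnan(track["value"]).all()
        assert (track["n_loci"] == 5).all()

    def test_against_bruteforce_oracle(self, rng):
        """Window means equal an O(L*W) double-loop oracle on 1000 random loci."""
        length = 1_000_000
        pos = np.sort(rng.choice(np.arange(1, length + 1), 1000, replace=False))
        vals = rng.normal(size=1000)
        loci = pd.DataFrame({"chrom": ["1"] * 1000, "pos": pos})
        track = window_mean(loci, vals, {"1": length}, min_loci=1)
        for _, row in track.iterrows():
            inside = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
            if inside.sum() == 0:
                assert np.isnan(row["value"])
            else:
                assert row["value"] == pytest.approx(vals[inside].mean())
            assert row["n_loci"] == inside.sum()


class TestZNormalize:
    def test_three_values(self):
        track = pd.DataFrame({"chrom": ["1"] * 3, "start": [0, 1, 2], "end": [1, 2, 3],
                              "value": [1.0, 2.0, 3.0], "n_loci": [10] * 3})
        z = znormalize(track)
        np.testing.assert_allclose(z["value"], [-1.224745, 0.0, 1.224745], atol=1e-6)

    def test_constant_track_errors(self):
        track = pd.DataFrame({"chrom": ["1"] * 3, "start": [0, 1, 2], "end": [1, 2, 3],
                              "value": [1.0, 1.0, 1.0], "n_loci": [10] * 3})
        with pytest.raises(ValueError, match="zero standard deviation"):
            znormalize(track)

    def test_partitions_normalised_separately(self, rng):
        auto = rng.normal(0, 1, 50)
        xvals = rng.normal(5, 2, 50)  # shifted X distribution
        track = pd.DataFrame({
            "chrom": ["1"] * 50 + ["X"] * 50,
            "start": list(range(50)) * 2, "end": list(range(1, 51)) * 2,
            "value": np.concatenate([auto, xvals]), "n_loci": [10] * 100,
        })
        z = znormalize(track)
        for sel in (z["chrom"] == "1", z["chrom"] == "X"):
            assert z.loc[sel, "value"].mean() == pytest.approx(0.0, abs=1e-9)
            assert np.std(z.loc[sel, "value"]) == pytest.approx(1.0, abs=1e-9)


def _track(values, chrom="1", step=20_000, size=100_000):
    starts = np.arange(len(values)) * step
    return pd.DataFrame({"chrom": [chrom] * len(values), "start": starts,
                         "end": starts + size, "value": values,
                         "n_loci": [10] * len(values)})


def outlier_oracle(values, starts, ends, t_seed, t_ext, lower=True):
    """Brute-force seed/extend scan used as the independent oracle."""
    v = np.asarray(values, dtype=float)
    beyond_seed = (v <= t_seed) if lower else (v >= t_seed)
    beyond_ext = (v <= t_ext) if lower else (v >= t_ext)
    beyond_seed &= ~np.isnan(v)
    beyond_ext &= ~np.isnan(v)
    spans = []
    for i in np.flatnonzero(beyond_seed):
        lo = i
        while lo - 1 >= 0 and beyond_ext[lo - 1]:
            lo -= 1
        hi = i
        while hi + 1 < len(v) and beyond_ext[hi + 1]:
            hi += 1
        spans.append((starts[lo], ends[hi]))
    merged = []
    for s, e in sorted(spans):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class TestOutlierRegions:
    def test_no_seed_empty(self):
        track = _track([0.0, 0.1, -0.1])
        out = call_outlier_regions(track, seed_threshold=-5, ext_threshold=-4)
        assert len(out) == 0

    def test_all_seed_single_region(self):
        track = _track([-3.0, -3.2, -4.0])
        out = call_outlier_regions(track, seed_threshold=-2.34, ext_threshold=-1.64)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (0, 140_000)

    def test_toy_track_hand_scan(self):
        # fixed thresholds -2.34 / -1.64: seed at window 2 extends over window 3
        track = _track([-1.0, -2.5, -1.8, -0.2])
        out = call_outlier_regions(track, seed_threshold=-2.34, ext_threshold=-1.64)
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (20_000, 140_000)

    def test_upper_tail(self):
        track = _track([0.1, 0.9, 0.5, 0.1])
        out = call_outlier_regions(track, tail="upper", seed_threshold=0.8,
                                   ext_threshold=0.4, source="fst")
        assert len(out) == 1
        assert (out["start"].iloc[0], out["end"].iloc[0]) == (20_000, 140_000)

    def test_matches_oracle_on_random_tracks(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            vals = rng.normal(size=n)
            vals[rng.random(n) < 0.1] = np.nan
            track = _track(vals)
            obs = vals[~np.isnan(vals)]
            if len(obs) < 2:
                continue
            t_seed = float(np.quantile(obs, 0.01))
            t_ext = float(np.quantile(obs, 0.05))
            out = call_outlier_regions(track, q_seed=0.01, q_ext=0.05)
            expect = outlier_oracle(vals, track["start"].to_numpy(),
                                    track["end"].to_numpy(), t_seed, t_ext)
            assert list(zip(out["start"], out["end"])) == expect

    def test_widening_extension_never_shrinks(self, rng):
        for _ in range(20):
            vals = rng.normal(size=40)
            track = _track(vals)
            narrow = call_outlier_regions(track, q_seed=0.02, q_ext=0.05)
            wide = call_outlier_regions(track, q_seed=0.02, q_ext=0.30)
            for _, r in narrow.iterrows():
                cover = wide[(wide["chrom"] == r["chrom"]) & (wide["start"] <= r["start"])
                             & (wide["end"] >= r["end"])]
                assert len(cover) == 1


def _regions(rows, source="hexp"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["source"] = source
    return df


GL = {"1": 10_000_000}


class TestCombine:
    def test_no_fst_overlap_dropped(self):
        out = combine_signals(_regions([("1", 0, 300_000)]), _regions([], "clr"),
                              _regions([("1", 5_000_000, 5_300_000)], "fst"), GL)
        assert len(out) == 0

    def test_min_width_before_padding(self):
        out = combine_signals(_regions([], "hexp"), _regions([("1", 0, 150_000)], "clr"),
                              _regions([("1", 0, 150_000)], "fst"), GL)
        assert len(out) == 0

    def test_padding(self):
        out = combine_signals(_regions([("1", 1_000_000, 1_300_000)]), _regions([], "clr"),
                              _regions([("1", 1_200_000, 1_250_000)], "fst"), GL)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"]) == (500_000, 1_800_000)  # 300 kb + 2*500 kb
        assert row["padded"]
        assert set(row["source"].split(",")) == {"hexp", "fst"}

    def test_clipped_at_chromosome_bounds(self):
        out = combine_signals(_regions([("1", 0, 300_000)]), _regions([], "clr"),
                              _regions([("1", 0, 100_000)], "fst"), GL)
        assert out["start"].iloc[0] == 0

    def test_order_invariance_and_disjoint_output(self, rng):
        rows = [("1", int(s), int(s) + int(w)) for s, w in
                zip(rng.integers(0, 8_000_000, 12), rng.integers(200_000, 600_000, 12))]
        fst = _regions([("1", 0, 10_000_000)], "fst")
        a = combine_signals(_regions(rows), _regions([], "clr"), fst, GL)
        b = combine_signals(_regions(rows[::-1]), _regions([], "clr"), fst, GL)
        pd.testing.assert_frame_equal(a, b)
        starts, ends = a["start"].to_numpy(), a["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()  # padded regions never overlap


class TestGenomeFraction:
    def test_empty(self):
        assert genome_fraction(rg.empty_regions(), {"1": 100}) == 0.0

    def test_full_genome(self):
        df = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [1000]})
        assert genome_fraction(df, {"1": 1000}) == 1.0

    def test_overlapping_merged(self):
        df = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 5000], "end": [10_000, 15_000]})
        assert genome_fraction(df, {"1": 100_000}) == pytest.approx(0.15)

    def test_out_of_bounds_rejected(self):
        df = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [2000]})
        with pytest.raises(ValueError):
            genome_fraction(df, {"1": 1000})
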