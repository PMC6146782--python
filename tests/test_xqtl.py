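"""Chip filtering, haplotype classes, Mendelian expectations, and the size model."""

import numpy as np
import pandas as pd
import pytest

from sweepcontrast.xqtl import (UNASSIGNED, ChipGenotypes, classify_haplotype,
                                expected_cross_distribution, filter_chip,
                                fit_size_model, informative_snps, ls_means,
                                _build_design)


def make_chip(geno, ploidy=None, sex=None, generation=None, group=None):
    geno = np.asarray(geno, dtype=float)
    n, m = geno.shape
    return ChipGenotypes(
        samples=tuple(f"s{i}" for i in range(n)),
        snp_ids=tuple(f"snp{j}" for j in range(m)),
        chrom=np.array(["X"] * m), pos=np.arange(m, dtype=np.int64) * 1000 + 52_000_000,
        geno=geno, ploidy=np.asarray(ploidy if ploidy is not None else [2] * n),
        sex=tuple(sex or ["female"] * n),
        generation=tuple(generation or ["F2"] * n),
        group=tuple(group or [""] * n),
    )


class TestFilterChip:
    def test_high_missing_individual_removed(self):
        geno = np.zeros((3, 20))
        geno[0, :19] = np.nan  # 95% missing
        geno[:, 0] = [np.nan, 1, 0]  # keep SNPs polymorphic
        geno[1:, 1:] = 1.0
        geno[2, 1:] = 0.0
        chip = make_chip(geno)
        out = filter_chip(chip)
        assert "s0" not in out.samples

    def test_snp_callrate_boundary_kept(self):
        # 10 samples, one SNP with exactly 90% call rate: strict "less than" fails
        geno = np.tile([[0.0, 1.0]], (10, 1))
        geno[0, 0] = np.nan
        geno[::2, 1] = 0.0
        geno[5, 0] = 1.0  # keep SNP 0 polymorphic
        out = filter_chip(make_chip(geno))
        assert "snp0" in out.snp_ids

    def test_monomorphic_snp_removed(self):
        geno = np.column_stack([np.zeros(10), np.tile([0.0, 1.0], 5)])
        out = filter_chip(make_chip(geno))
        assert "snp0" not in out.snp_ids
        assert "snp1" in out.snp_ids


class TestInformativeSnps:
    def _founders(self, mini_col, large_col):
        geno = np.column_stack([np.concatenate([large_col, mini_col])])
        n_large, n_mini = len(large_col), len(mini_col)
        return make_chip(
            geno,
            ploidy=[2] * n_large + [1] * n_mini,
            sex=["female"] * n_large + ["male"] * n_mini,
            generation=["P0"] * (n_large + n_mini),
            group=["large"] * n_large + ["minipig"] * n_mini,
        )

    def test_fixed_difference_informative(self):
        chip = self._founders(mini_col=np.ones(4), large_col=np.zeros(4))
        assert informative_snps(chip) == ["snp0"]

    def test_het_founder_disqualifies(self):
        # one large-group female heterozygous: marker not informative
        chip = self._founders(mini_col=np.ones(4), large_col=np.array([0, 0, 0, 1.0]))
        assert informative_snps(chip) == []

    def test_segregating_in_minipigs_not_informative(self):
        chip = self._founders(mini_col=np.array([1, 1, 0, 1.0]), large_col=np.zeros(4))
        assert informative_snps(chip) == []


class TestClassifyHaplotype:
    def _chip_with_founders(self, f2_geno, f2_sex, f2_ploidy):
        n_f2 = len(f2_geno)
        geno = np.vstack([np.zeros((2, 2)), np.ones((2, 2)), np.asarray(f2_geno, float)])
        return make_chip(
            geno,
            ploidy=[2, 2, 1, 1] + list(f2_ploidy),
            sex=["female", "female", "male", "male"] + list(f2_sex),
            generation=["P0"] * 4 + ["F2"] * n_f2,
            group=["large", "large", "minipig", "minipig"] + [""] * n_f2,
        )

    def test_classes(self):
        chip = self._chip_with_founders(
            f2_geno=[[0, 0], [1, 1], [1, 1], [0, 0], [2, 2]],
            f2_sex=["female", "female", "male", "male", "female"],
            f2_ploidy=[2, 2, 1, 1, 2],
        )
        classes = classify_haplotype(chip, ["snp0", "snp1"])
        assert classes["s4"] == 1  # homozygous large female
        assert classes["s5"] == 2  # heterozygous female
        assert classes["s6"] == 3  # hemizygous minipig male
        assert classes["s7"] == 1  # hemizygous large male
        assert classes["s8"] == UNASSIGNED  # homozygous minipig female: not a design class

    def test_discordant_unassigned(self):
        chip = self._chip_with_founders(
            f2_geno=[[1, 0]], f2_sex=["female"], f2_ploidy=[2])
        classes = classify_haplotype(chip, ["snp0", "snp1"])
        assert classes["s4"] == UNASSIGNED

    def test_all_missing_unassigned(self):
        chip = self._chip_with_founders(
            f2_geno=[[np.nan, np.nan]], f2_sex=["female"], f2_ploidy=[2])
        classes = classify_haplotype(chip, ["snp0", "snp1"])
        assert classes["s4"] == UNASSIGNED


def test_chip_tsv_roundtrip(tmp_path):
    from sweepcontrast.synthdata import SimConfig, simulate_f2_cross
    from sweepcontrast.xqtl import read_chip, write_chip

    chip, _ = simulate_f2_cross(SimConfig(seed=12, n_f2=40))
    write_chip(chip, tmp_path / "g.tsv", tmp_path / "m.tsv")
    back = read_chip(tmp_path / "g.tsv", tmp_path / "m.tsv")
    assert back.samples == chip.samples
    assert back.snp_ids == chip.snp_ids
    np.testing.assert_array_equal(back.ploidy, chip.ploidy)
    np.testing.assert_allclose(back.geno, chip.geno, equal_nan=True)
    np.testing.assert_array_equal(back.pos, chip.pos)
    assert back.generation == chip.generation


class TestExpectedCross:
    def test_printed_expectations(self):
        dist = expected_cross_distribution()
        assert dist["F1"]["female"] == {"Lm": 1.0}
        assert dist["F1"]["male"] == {"L": 1.0}
        assert dist["F2"]["female"] == {"LL": 0.5, "Lm": 0.5}
        assert dist["F2"]["male"] == {"L": 0.5, "m": 0.5}

    def test_proportions_sum_to_one(self):
        for gen in expected_cross_distribution().values():
            for props in gen.values():
                assert sum(props.values()) == pytest.approx(1.0)


def simulate_records(rng, n=200, effect=3.0, sd=1.0):
    sex = rng.choice(["female", "male"], n)
    breed = rng.choice(["Duroc", "Yorkshire"], n)
    age = rng.uniform(166, 439, n)
    hap = np.where(sex == "female",
                   rng.choice([1, 2], n), rng.choice([1, 3], n))
    y = (65 + 1.0 * (breed == "Duroc") + 1.5 * (sex == "male")
         + 0.1 * (age - 300) - effect * ((sex == "male") & (hap == 3))
         + rng.normal(0, sd, n))
    return pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                         "founder_dam_breed": breed, "sex": sex,
                         "age_days": age, "hap_class": hap, "y": y})


class TestSizeModel:
    def test_full_model_matches_normal_equations(self, rng):
        """OLS coefficients reproduce the normal-equations solution to 1e-8."""
        df = simulate_records(rng, n=40)
        fit = fit_size_model(df, "y", alpha=1.1)  # alpha > 1: nothing removed
        X = _build_design(df, fit.retained, fit.design_info["means"]).to_numpy()
        y = df["y"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.results.params, beta, atol=1e-8)

    def test_effect_recovery_single_replicate(self, rng):
        df = simulate_records(rng, n=400, effect=3.0, sd=1.0)
        fit = fit_size_model(df, "y")
        assert "HS" in fit.retained
        means, comps = ls_means(fit)
        row = comps[(comps["level1"] == ("male", 1)) & (comps["level2"] == ("male", 3))]
        assert row["diff"].iloc[0] == pytest.approx(3.0, abs=0.5)

    def test_marginality_protected(self, rng):
        df = simulate_records(rng, n=300)
        fit = fit_size_model(df, "y")
        for term in fit.retained:
            if ":" in term:
                from sweepcontrast.xqtl import _CONTAINS
                assert _CONTAINS[term] <= set(fit.retained)
        # A2 may never outlive A
        if "A2" in fit.retained:
            assert "A" in fit.retained

    def test_backward_selection_deterministic(self, rng):
        df = simulate_records(rng, n=150)
        f1 = fit_size_model(df, "y")
        f2 = fit_size_model(df, "y")
        assert f1.retained == f2.retained

    def test_always_keep_focal_term(self, rng):
        df = simulate_records(rng, n=150, effect=0.0)
        fit = fit_size_model(df, "y", always_keep=("HS",))
        assert "HS" in fit.retained

    def test_single_level_factor_rejected(self, rng):
        df = simulate_records(rng, n=50)
        df["sex"] = "female"
        with pytest.raises(ValueError):
            fit_size_model(df, "y")


class TestLsMeans:
    def test_balanced_one_factor_equals_raw_means(self, rng):
        # balanced design, no covariate effects: LS-means = raw group means
        n = 120
        sex = np.repeat(["female", "male"], n // 2)
        hap = np.concatenate([np.tile([1, 1, 2, 2], n // 8), np.tile([1, 1, 3, 3], n // 8)])
        breed = np.tile(["Duroc", "Yorkshire"], n // 2)
        age = np.tile([280.0, 290, 300, 310, 320, 330], n // 6)
        y = 60 + 2.0 * (hap == 3) + rng.normal(0, 0.02, n)
        df = pd.DataFrame({"founder_dam_breed": breed, "sex": sex, "age_days": age,
                           "hap_class": hap, "y": y})
        fit = fit_size_model(df, "y", always_keep=("HS",))
        means, _ = ls_means(fit)
        for _, row in means.iterrows():
            sel = (sex == row["sex"]) & (hap == row["hap_class"])
            assert row["lsmean"] == pytest.approx(y[sel].mean(), abs=0.02)

    def test_covariate_adjustment_closed_form(self):
        # 12 rows, age confounded with haplotype class; hand-computed adjustment
        df = pd.DataFrame({
            "founder_dam_breed": ["Duroc", "Yorkshire"] * 12,
            "sex": ["male"] * 12 + ["female"] * 12,
            "age_days": [200, 210, 220, 230, 240, 250, 300, 310, 320, 330, 340, 350] * 2,
            "hap_class": [1] * 6 + [3] * 6 + [1] * 6 + [2] * 6,
        })
        df["y"] = 50 + 0.1 * df["age_days"] - 3.0 * (df["hap_class"] == 3)
        fit = fit_size_model(df, "y", always_keep=("HS",))
        means, comps = ls_means(fit)
        # noise-free data: adjusted difference is exactly the injected effect
        row = comps[(comps["level1"] == ("male", 1)) & (comps["level2"] == ("male", 3))]
        assert row["diff"].iloc[0] == pytest.approx(3.0, abs=1e-6)

    def test_identical_groups_nonsignificant(self, rng):
        df = simulate_records(rng, n=200, effect=0.0, sd=1.0)
        fit = fit_size_model(df, "y", always_keep=("HS",))
        _, comps = ls_means(fit)
        same_sex = comps[[l1[0] == l2[0] for l1, l2 in zip(comps["level1"], comps["level2"])]]
        assert (same_sex["p"] > 0.01).all()

    def test_term_absent_raises(self, rng):
        df = simulate_records(rng, n=200, effect=0.0)
        fit = fit_size_model(df, "y")
        if "HS" not in fit.retained:
            with pytest.raises(ValueError):
                ls_means(fit)
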