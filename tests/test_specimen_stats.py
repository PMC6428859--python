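"""Repeatability (ICC), shape~species+size models, variance-ratio F test."""

import numpy as np
import pytest
from scipy import stats

from morphorates import (
    DataError,
    f_two_sided_pvalue,
    repeatability,
    shape_effects_model,
    variance_ratio_test,
)


def icc_oracle(values, groups):
    """Independent sums-of-squares oracle for the one-way ANOVA ICC."""
    values = np.asarray(values, float)
    labels = sorted(set(groups))
    groups = list(groups)
    n_i = np.array([groups.count(g) for g in labels], float)
    n = len(values)
    k = len(labels)
    means = np.array([np.mean([v for v, g in zip(values, groups) if g == lab])
                      for lab in labels])
    grand = values.mean()
    ms_a = np.sum(n_i * (means - grand) ** 2) / (k - 1)
    ms_w = sum((v - means[labels.index(g)]) ** 2 for v, g in zip(values, groups)) / (n - k)
    n0 = (n - np.sum(n_i**2) / n) / (k - 1)
    return (ms_a - ms_w) / (ms_a + (n0 - 1) * ms_w)


class TestRepeatability:
    def test_zero_within_group_variance_gives_one(self):
        res = repeatability([1, 1, 2, 2, 5, 5], ["a", "a", "b", "b", "c", "c"],
                            n_boot=50, n_perm=50, seed=0)
        assert res.icc == pytest.approx(1.0)

    def test_equal_group_means_clamped_to_zero(self):
        res = repeatability([1, 3, 1, 3, 1, 3], ["a", "a", "b", "b", "c", "c"],
                            n_boot=50, n_perm=50, seed=0)
        assert res.icc == 0.0

    def test_balanced_toy_matches_anova_oracle(self):
        values = [1.0, 1.0, 2.0, 2.0, 3.0, 3.5]
        groups = ["a", "a", "b", "b", "c", "c"]
        res = repeatability(values, groups, n_boot=50, n_perm=50, seed=0)
        assert res.icc == pytest.approx(icc_oracle(values, groups), abs=1e-10)

    def test_unbalanced_matches_anova_oracle(self):
        values = [1.0, 1.2, 0.9, 4.0, 4.2, 7.7, 8.1, 8.0, 7.9]
        groups = ["a", "a", "a", "b", "b", "c", "c", "c", "c"]
        res = repeatability(values, groups, n_boot=50, n_perm=50, seed=0)
        assert res.icc == pytest.approx(icc_oracle(values, groups), abs=1e-10)

    def test_affine_invariance(self, rng):
        values = rng.normal(size=20)
        groups = list("abcd") * 5
        a = repeatability(values, groups, n_boot=50, n_perm=50, seed=1)
        b = repeatability(3.0 * values - 7.0, groups, n_boot=50, n_perm=50, seed=1)
        assert a.icc == pytest.approx(b.icc, abs=1e-12)

    def test_uncertainty_and_significance_behave(self):
        rng = np.random.default_rng(2)
        effects = rng.normal(0, 2.0, size=10)
        values = np.concatenate([e + rng.normal(0, 0.5, size=5) for e in effects])
        groups = np.repeat([f"g{i}" for i in range(10)], 5)
        res = repeatability(values, groups, n_boot=300, n_perm=300, seed=3)
        assert res.ci_lower <= res.icc <= res.ci_upper
        assert res.p_value <= 0.05
        assert res.se > 0

    def test_all_singletons_rejected(self):
        with pytest.raises(DataError):
            repeatability([1.0, 2.0, 3.0], ["a", "b", "c"], seed=0)


class TestShapeEffectsModel:
    def _study(self, n_species=33, per_species=5, n_total=None, seed=0):
        rng = np.random.default_rng(seed)
        species = np.repeat([f"s{i:02d}" for i in range(n_species)], per_species)
        if n_total is not None:
            species = species[:n_total]
        effects = dict(zip(sorted(set(species)), rng.normal(0, 2, n_species)))
        score = np.array([effects[s] for s in species]) + rng.normal(
            0, 1, len(species)
        )
        size = rng.lognormal(0, 0.3, len(species))
        return score, species, size

    def test_degrees_of_freedom_for_157_specimens(self):
        # 33 species x ~5 specimens, 157 rows, one covariate:
        # df = (33 - 1, 157 - 33 - 1) = (32, 123) with complete data
        rng = np.random.default_rng(1)
        species = np.concatenate([
            np.repeat([f"s{i:02d}" for i in range(31)], 5),  # 155... adjust below
        ])
        species = np.concatenate([
            np.repeat([f"s{i:02d}" for i in range(33)], 4),  # 132
            [f"s{i:02d}" for i in range(25)],  # +25 -> 157
        ])
        score = rng.normal(size=157)
        size = rng.lognormal(0, 0.3, 157)
        table = shape_effects_model(score, species, size).frame
        species_row = table[table["effect"] == "species"].iloc[0]
        assert (species_row["df_num"], species_row["df_den"]) == (32, 123)

    def test_incomplete_case_dropped_matches_printed_df(self):
        # one specimen without a size measurement -> df_den 122
        rng = np.random.default_rng(2)
        species = np.concatenate([
            np.repeat([f"s{i:02d}" for i in range(33)], 4),
            [f"s{i:02d}" for i in range(25)],
        ])
        score = rng.normal(size=157)
        size = rng.lognormal(0, 0.3, 157)
        size[10] = np.nan
        table = shape_effects_model(score, species, size).frame
        assert table[table["effect"] == "species"].iloc[0]["df_den"] == 122

    def test_null_size_effect_p_uniform(self):
        # size independent of score: its p-values should look uniform
        pvals = []
        for seed in range(40):
            score, species, size = self._study(n_species=10, per_species=4,
                                               seed=seed)
            table = shape_effects_model(score, species, size).frame
            pvals.append(table[table["effect"] == "size"].iloc[0]["p_value"])
        assert 0.2 < np.mean(pvals) < 0.8
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_sex_term_included_when_supplied(self):
        score, species, size = self._study(n_species=6, per_species=6, seed=3)
        sex = np.tile(["female", "male", "female", "male", "female", "male"],
                      len(score) // 6)
        table = shape_effects_model(score, species, size, sex=sex).frame
        assert list(table["effect"]) == ["species", "sex", "size"]

    def test_single_species_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(DataError):
            shape_effects_model(rng.normal(size=6), ["s1"] * 6,
                                rng.lognormal(0, 0.3, 6))


class TestVarianceRatio:
    def test_df_for_two_33_species_samples(self, rng):
        res = variance_ratio_test(rng.normal(size=33), rng.normal(size=33))
        assert (res.df1, res.df2) == (32, 32)

    def test_identical_samples_give_f_one_p_one(self, rng):
        x = rng.normal(size=20)
        res = variance_ratio_test(x, x.copy())
        assert res.f_stat == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_reported_statistic_two_sided_p(self):
        # F = 2.28 at df (32, 32): two-sided p from an independent CDF oracle
        oracle = 2 * min(stats.f.cdf(2.28, 32, 32), stats.f.sf(2.28, 32, 32))
        assert f_two_sided_pvalue(2.28, 32, 32) == pytest.approx(oracle, abs=1e-12)
        assert round(f_two_sided_pvalue(2.28, 32, 32), 2) == 0.02

    def test_reciprocal_symmetry(self, rng):
        x, y = rng.normal(size=15), 2.0 * rng.normal(size=18)
        a = variance_ratio_test(x, y)
        b = variance_ratio_test(y, x)
        assert a.f_stat * b.f_stat == pytest.approx(1.0, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_zero_denominator_variance_rejected(self, rng):
        with pytest.raises(DataError):
            variance_ratio_test(rng.normal(size=5), np.ones(5))
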