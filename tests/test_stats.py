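"""Statistical battery: brute-force rank oracles, calibration runs and
threshold arithmetic."""

import numpy as np
import pytest
from scipy import stats as sps

from thetagamma.stats import (bonferroni, friedman_relationship,
                              gated_between, kw_within, normality_gate,
                              rank_between)


# ---------------------------------------------------------------- oracles

def brute_force_rank_sum_w(a, b):
    """Rank-sum U of the first sample computed from first principles."""
    ranks = sps.rankdata(np.concatenate([a, b]))
    return ranks[:len(a)].sum() - len(a) * (len(a) + 1) / 2.0


def brute_force_kw(groups):
    """Kruskal-Wallis H with tie correction, from the defining formula."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    h = 0.0
    for r, g in zip(np.split(ranks, splits), groups):
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


def brute_force_friedman(mat):
    """Friedman chi-square (no ties) for a blocks x treatments matrix."""
    n, k = mat.shape
    ranks = np.vstack([sps.rankdata(row) for row in mat])
    rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(rj ** 2) - 3.0 * n * (k + 1)


# ---------------------------------------------------------------- gate

class TestNormalityGate:
    def test_gaussian_samples_route_parametric(self):
        rng = np.random.default_rng(1)
        routes = [normality_gate(rng.standard_normal(200))
                  for _ in range(100)]
        assert routes.count("parametric") >= 90

    def test_exponential_samples_route_nonparametric(self):
        rng = np.random.default_rng(2)
        routes = [normality_gate(rng.exponential(size=200))
                  for _ in range(100)]
        assert routes.count("nonparametric") >= 99

    def test_small_sample_defaults_nonparametric_with_warning(self):
        with pytest.warns(UserWarning, match="small"):
            assert normality_gate(np.arange(5.0)) == "nonparametric"

    def test_constant_sample_defaults_nonparametric_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert normality_gate(np.ones(20)) == "nonparametric"


# ---------------------------------------------------------------- rank sum

class TestRankBetween:
    def test_identical_groups_null_result(self):
        x = np.arange(10.0)
        res = rank_between(x, x)
        assert res.p > 0.9
        assert abs(res.effect_r) < 0.05

    def test_large_shift_detected_with_large_effect(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(30)
        res = rank_between(a, a + 5.0)
        assert res.p < 0.001
        assert abs(res.effect_r) > 0.5

    def test_statistic_matches_brute_force_on_small_fixtures(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.integers(0, 20, size=5).astype(float)
            b = rng.integers(0, 20, size=6).astype(float)
            assert rank_between(a, b).statistic == \
                pytest.approx(brute_force_rank_sum_w(a, b))

    def test_effect_size_is_z_over_sqrt_n(self):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal(40), rng.standard_normal(40) + 0.4
        res = rank_between(a, b)
        assert res.effect_r == pytest.approx(res.z / np.sqrt(80))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_between(np.array([]), np.arange(3.0))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            rank_between(rng.standard_normal(30),
                         rng.standard_normal(30)).p < 0.05
            for _ in range(1000))
        assert 0.035 <= rejections / 1000 <= 0.065


class TestGatedBattery:
    @pytest.mark.parametrize("dist,seed", [("gaussian", 101),
                                           ("exponential", 202)])
    def test_type_one_error_within_band_under_null(self, dist, seed):
        rng = np.random.default_rng(seed)
        reps = 2000
        rej = 0
        for _ in range(reps):
            if dist == "gaussian":
                a, b = rng.standard_normal(25), rng.standard_normal(25)
            else:
                a, b = rng.exponential(size=25), rng.exponential(size=25)
            rej += gated_between(a, b).p < 0.05
        assert 0.035 <= rej / reps <= 0.065


# ---------------------------------------------------------------- KW

class TestKruskalWallis:
    def test_df_is_k_minus_1_and_null_p_large(self):
        rng = np.random.default_rng(7)
        groups = [rng.standard_normal(10) for _ in range(10)]
        res = kw_within(groups)
        assert res.df == 9.0
        assert res.p > 0.001

    def test_statistic_matches_brute_force_3x5_fixture(self):
        rng = np.random.default_rng(8)
        groups = [rng.integers(0, 30, 5).astype(float) for _ in range(3)]
        res = kw_within(groups)
        assert res.statistic == pytest.approx(brute_force_kw(groups))

    def test_shifted_group_flagged_against_baseline(self):
        rng = np.random.default_rng(9)
        hits, reps = 0, 30
        for _ in range(reps):
            groups = [rng.standard_normal(20) for _ in range(5)]
            groups[3] = groups[3] + 4.0
            res = kw_within(groups, baseline_index=0)
            tab = res.posthoc
            shifted = tab[((tab.group_a == "0") & (tab.group_b == "3"))
                          | ((tab.group_a == "3") & (tab.group_b == "0"))]
            others = tab[tab["vs_baseline"]
                         & ~tab.index.isin(shifted.index)]
            if shifted["significant"].all() \
                    and not others["significant"].any():
                hits += 1
        assert hits >= 0.9 * reps

    def test_small_groups_excluded_with_warning(self):
        groups = [np.arange(5.0), np.array([1.0]), np.arange(5.0) + 1,
                  np.arange(5.0) + 2]
        with pytest.warns(UserWarning, match="excluded"):
            res = kw_within(groups)
        assert res.df == 2.0

    def test_conover_variant_runs_and_flags_monotonically(self):
        rng = np.random.default_rng(10)
        groups = [rng.standard_normal(8), rng.standard_normal(8) + 3,
                  rng.standard_normal(8)]
        res = kw_within(groups, posthoc="conover")
        assert res.posthoc is not None and len(res.posthoc) == 3


# ---------------------------------------------------------------- Friedman

class TestFriedman:
    def test_identical_constant_series_give_zero_chi2(self):
        s = [np.ones(10)] * 3
        res = friedman_relationship(s)
        assert res.statistic == 0.0

    def test_paper_orientation_df_is_epochs_minus_1(self):
        rng = np.random.default_rng(11)
        series = [rng.standard_normal(10) for _ in range(3)]
        res = friedman_relationship(series)
        assert res.df == 9.0
        res2 = friedman_relationship(series,
                                     orientation="series_as_treatments")
        assert res2.df == 2.0

    def test_matches_brute_force_on_3x10_fixture(self):
        rng = np.random.default_rng(12)
        series = [rng.permutation(10).astype(float) + rng.uniform(0, .1, 10)
                  for _ in range(3)]
        res = friedman_relationship(series)
        mat = np.vstack(series)          # blocks = series (paper orientation)
        assert res.statistic == pytest.approx(brute_force_friedman(mat))

    def test_comonotone_series_score_higher_than_independent(self):
        rng = np.random.default_rng(13)
        wins = 0
        for _ in range(100):
            base = rng.standard_normal(10)
            co = [base + 0.2 * rng.standard_normal(10) for _ in range(3)]
            ind = [rng.standard_normal(10) for _ in range(3)]
            wins += (friedman_relationship(co).statistic
                     > friedman_relationship(ind).statistic)
        assert wins > 70

    def test_misaligned_series_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            friedman_relationship([np.arange(5.0), np.arange(6.0)])


# ---------------------------------------------------------------- Bonferroni

class TestBonferroni:
    def test_70_comparisons_reproduce_printed_threshold(self):
        assert bonferroni(0.05, 70) == pytest.approx(0.000714285714)
        assert round(bonferroni(0.05, 70), 5) == 0.00071

    @pytest.mark.parametrize("m,expected", [(1, 0.05), (5, 0.01)])
    def test_simple_cases(self, m, expected):
        assert bonferroni(0.05, m) == pytest.approx(expected)

    def test_flags_monotone_in_alpha(self):
        rng = np.random.default_rng(14)
        groups = [rng.standard_normal(8) for _ in range(4)]
        groups[1] += 2.0
        flags_strict = kw_within(groups, alpha=0.01).posthoc["significant"]
        flags_loose = kw_within(groups, alpha=0.05).posthoc["significant"]
        assert not (flags_strict & ~flags_loose).any()

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni(0.05, 0)
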