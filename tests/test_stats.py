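"""Statistical procedures: calibration, exact oracles, power analysis."""

import numpy as np
import pytest

from digdive import ValidationError
from digdive.stats import (
    PowerSpec,
    cohens_d,
    compact_letter_display,
    ks_two_sample,
    kruskal_posthoc,
    lilliefors_test,
    mhc_rate,
    one_sample_t,
    preference_index,
    rank_sum_test,
    sample_size_t,
    select_test,
    survival_ratio,
    t_power,
    two_sample_t,
)


class TestLilliefors:
    def test_type_one_error_calibrated(self):
        """Gaussian data rejected at about the nominal 5% rate."""
        rng = np.random.default_rng(0)
        rej = 0
        runs = 400
        for i in range(runs):
            x = rng.standard_normal(50)
            rej += lilliefors_test(x, n_mc=400, seed=i) < 0.05
        assert abs(rej / runs - 0.05) < 0.025

    def test_uniform_data_rejected(self):
        """Power check: uniform data is reliably flagged as non-normal.

        At n = 100 the test's true power against Uniform(0, 1) is about
        0.58 (verified against statsmodels), so the near-certain
        rejection regime needs the larger sample.
        """
        rng = np.random.default_rng(1)
        rej_100 = sum(
            lilliefors_test(rng.random(100), n_mc=400, seed=i) < 0.05 for i in range(40)
        )
        assert rej_100 >= 0.35 * 40  # well above the 5% null rate
        rej_300 = sum(
            lilliefors_test(rng.random(300), n_mc=400, seed=i) < 0.05 for i in range(40)
        )
        assert rej_300 >= 38

    def test_agrees_with_statsmodels_statistic(self):
        """Independent cross-check of the KS distance against statsmodels."""
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        from digdive.stats import lilliefors_statistic

        rng = np.random.default_rng(2)
        x = rng.gamma(2.0, size=60)
        d_sm, _ = sm_lilliefors(x, dist="norm")
        assert lilliefors_statistic(x) == pytest.approx(d_sm, abs=1e-10)

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValidationError):
            lilliefors_test(np.ones(10))
        with pytest.raises(ValidationError):
            lilliefors_test(np.array([1.0, 2.0, 3.0]))


class TestRankSum:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rank_sum_test(x, x).p_value == 1.0

    def test_disjoint_three_vs_three_exact(self):
        res = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert res.test_name == "mann-whitney-exact"
        assert res.p_value == pytest.approx(0.1)

    def test_exact_and_asymptotic_agree(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            from scipy.stats import mannwhitneyu

            p_exact = mannwhitneyu(x, y, method="exact").pvalue
            p_asym = mannwhitneyu(x, y, method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_test([], [1.0])

    def test_null_type_one_error(self):
        rng = np.random.default_rng(4)
        rej = sum(
            rank_sum_test(rng.standard_normal(20), rng.standard_normal(20)).p_value < 0.05
            for _ in range(1000)
        )
        assert abs(rej / 1000 - 0.05) < 0.02


class TestKruskalPosthoc:
    def test_identical_groups_share_a_letter(self):
        g = np.arange(10.0)
        res = kruskal_posthoc([g, g + 0.01, g - 0.01])
        assert len(set(res.letters)) == 1

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        res = kruskal_posthoc([a, b])
        assert res.letters[0] != res.letters[1]
        assert res.kruskal_p < 0.05

    def test_letters_encode_significance_graph(self):
        """Exhaustive check: groups share a letter iff corrected p >= alpha."""
        rng = np.random.default_rng(6)
        shifts = [0.0, 0.3, 3.0, 3.2, 8.0]
        groups = [rng.normal(s, 1.0, 12) for s in shifts]
        res = kruskal_posthoc(groups)
        k = len(groups)
        for i in range(k):
            for j in range(i + 1, k):
                share = bool(set(res.letters[i]) & set(res.letters[j]))
                assert share == (res.pairwise_p[i, j] >= res.alpha)

    def test_letter_display_matches_brute_force_on_random_graphs(self):
        """The clique cover reproduces arbitrary NS adjacency structures."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(2, 6))
            ns = np.zeros((k, k), dtype=bool)
            for i in range(k):
                for j in range(i + 1, k):
                    ns[i, j] = ns[j, i] = rng.random() < 0.5
            letters = compact_letter_display(ns)
            for i in range(k):
                assert letters[i]  # every group carries at least one letter
                for j in range(i + 1, k):
                    share = bool(set(letters[i]) & set(letters[j]))
                    assert share == bool(ns[i, j])

    def test_bonferroni_cap(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(0, 1, 8) for _ in range(4)]
        res = kruskal_posthoc(groups)
        off_diag = res.pairwise_p[~np.isnan(res.pairwise_p)]
        assert np.all(off_diag <= 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_posthoc([np.arange(5.0)])


class TestKS:
    def test_identical_samples_d_zero(self):
        x = np.arange(10.0)
        assert ks_two_sample(x, x).statistic == 0.0

    def test_disjoint_supports_d_one(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.statistic == 1.0

    def test_d_matches_sup_over_jump_points_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.normal(size=15)
            y = rng.normal(0.5, 1.2, size=12)
            d = ks_two_sample(x, y).statistic
            pooled = np.concatenate([x, y])
            sup = max(
                abs(np.mean(x <= t) - np.mean(y <= t)) for t in pooled
            )
            assert d == pytest.approx(sup, abs=1e-12)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(10)
        rej = sum(
            ks_two_sample(rng.standard_normal(100), rng.standard_normal(100)).p_value < 0.05
            for _ in range(1000)
        )
        assert abs(rej / 1000 - 0.05) < 0.02


class TestTTests:
    def test_symmetric_sample_t_zero(self):
        res = one_sample_t([1.0, 2.0, 3.0], 2.0)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_p_matches_sign_flip_oracle(self):
        """Sign-flip enumeration approximates the t p-value for n = 10."""
        rng = np.random.default_rng(11)
        x = rng.normal(0.3, 1.0, 10)
        p_t = one_sample_t(x, 0.0).p_value
        centered = x  # null: symmetric around 0
        t_obs = abs(centered.mean())
        flips = 0
        total = 2**10
        for mask in range(total):
            signs = 1 - 2 * ((mask >> np.arange(10)) & 1)
            flips += abs((centered * signs).mean()) >= t_obs - 1e-12
        assert abs(p_t - flips / total) < 0.02

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValidationError):
            one_sample_t(np.ones(5), 1.0)

    def test_two_sample_t_reports_effect_size(self):
        rng = np.random.default_rng(12)
        res = two_sample_t(rng.normal(0, 1, 30), rng.normal(1, 1, 30))
        assert res.effect_size is not None and res.effect_size > 0.3


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 5000)
        y = rng.normal(1, 1, 5000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.06)

    def test_affine_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(2, 3, 40)
        y = rng.normal(5, 3, 40)
        d0 = cohens_d(x, y)
        d1 = cohens_d(4 * x + 7, 4 * y + 7)
        assert d0 == pytest.approx(d1)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d(np.ones(5), np.ones(5))


class TestPowerAndSampleSize:
    def test_null_effect_power_equals_alpha(self):
        spec = PowerSpec(mu=0.0, sigma=1.0, delta=1.0, alpha=0.05)
        null = PowerSpec(mu=0.0, sigma=1.0, delta=1e-12, alpha=0.05)
        assert t_power(20, null) == pytest.approx(0.05, abs=1e-6)
        assert t_power(20, spec) > 0.9

    def test_power_strictly_increasing_in_n(self):
        spec = PowerSpec(mu=0.0, sigma=1.0, delta=0.5)
        powers = [t_power(n, spec) for n in range(2, 80)]
        assert np.all(np.diff(powers) > 0)

    def test_power_matches_monte_carlo(self):
        """10^5 simulated one-sample t-tests at n = 10, d = 1."""
        spec = PowerSpec(mu=0.0, sigma=1.0, delta=1.0)
        analytic = t_power(10, spec)
        rng = np.random.default_rng(15)
        n, reps = 10, 100_000
        x = rng.standard_normal((reps, n)) + 1.0
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        from scipy.stats import t as tdist

        tc = tdist.ppf(0.975, n - 1)
        mc = np.mean(np.abs(t) > tc)
        assert abs(analytic - mc) < 0.01

    @pytest.mark.parametrize(
        "mu,sigma,delta,expected",
        [(0.15, 0.1, 0.05, 34), (0.5, 0.2, 0.3, 6)],
    )
    def test_reported_sample_sizes_reproduced(self, mu, sigma, delta, expected):
        assert sample_size_t(PowerSpec(mu=mu, sigma=sigma, delta=delta)) == expected

    @pytest.mark.parametrize("d", [0.3, 0.5, 1.0, 1.5])
    def test_sample_size_is_exact_bracket(self, d):
        spec = PowerSpec(mu=0.0, sigma=1.0, delta=d)
        n0 = sample_size_t(spec)
        assert t_power(n0, spec) >= 0.8
        if n0 > 2:
            assert t_power(n0 - 1, spec) < 0.8

    def test_zero_delta_rejected(self):
        with pytest.raises(ValidationError):
            sample_size_t(PowerSpec(mu=0.0, sigma=1.0, delta=0.0))


class TestSelectTest:
    def test_gaussian_samples_take_t_branch(self):
        rng = np.random.default_rng(16)
        hits = 0
        for i in range(20):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50)
            res = select_test(x, y, n_mc=400, seed=i)
            hits += res.test_name == "two-sample-t"
        assert hits >= 18

    def test_skewed_sample_takes_rank_branch(self):
        rng = np.random.default_rng(17)
        x = rng.lognormal(0, 1.5, 80)
        y = rng.standard_normal(80)
        res = select_test(x, y, n_mc=400, seed=0)
        assert res.test_name.startswith("mann-whitney")

    def test_branch_label_always_populated(self):
        rng = np.random.default_rng(18)
        res = select_test(rng.standard_normal(30), rng.standard_normal(30), n_mc=200, seed=1)
        assert res.test_name


class TestAssayFormulas:
    @pytest.mark.parametrize(
        "na,nb,total,expected", [(10, 10, 20, 0.0), (20, 0, 20, 1.0), (12, 6, 20, 0.3)]
    )
    def test_preference_index(self, na, nb, total, expected):
        assert preference_index(na, nb, total) == pytest.approx(expected)

    def test_preference_index_validation(self):
        with pytest.raises(ValidationError):
            preference_index(1, 1, 0)
        with pytest.raises(ValidationError):
            preference_index(15, 10, 20)

    @pytest.mark.parametrize("adults,larvae,expected", [(8, 10, 0.8), (0, 10, 0.0), (10, 10, 1.0)])
    def test_survival_ratio(self, adults, larvae, expected):
        assert survival_ratio(adults, larvae) == pytest.approx(expected)

    def test_survival_ratio_validation(self):
        with pytest.raises(ValidationError):
            survival_ratio(5, 0)
        with pytest.raises(ValidationError):
            survival_ratio(11, 10)

    @pytest.mark.parametrize("count,window,expected", [(30, 60, 30.0), (0, 60, 0.0), (15, 30, 30.0)])
    def test_mhc_rate(self, count, window, expected):
        assert mhc_rate(count, window) == pytest.approx(expected)

    def test_mhc_rate_validation(self):
        with pytest.raises(ValidationError):
            mhc_rate(10, 0)
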