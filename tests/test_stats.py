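import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from collmove import (
    SimulationConfig,
    ValidationError,
    compute_dai,
    compute_hwi,
    eigenvector_centrality,
    kruskal_wallis,
    ks_normality,
    run_test_battery,
    simulate_study,
    spearman,
    t_test_independent,
)


def brute_force_spearman_p(x, y):
    """Exhaustive two-sided permutation p-value for Spearman's rho."""
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def rho(a, b):
        ac, bc = a - a.mean(), b - b.mean()
        return float(ac @ bc / math.sqrt((ac @ ac) * (bc @ bc)))

    obs = abs(rho(rx, ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        hits += abs(rho(rx, np.asarray(perm))) >= obs - 1e-12
    return hits / total


class TestSpearman:
    def test_concordant_and_discordant_extremes(self):
        x = [1.0, 2.0, 3.0, 5.0, 8.0]
        assert spearman(x, x).statistic == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_monotone_transform_preserves_perfect_correlation(self):
        x = np.array([0.1, 0.5, 2.0, 7.0, 9.0, 20.0])
        assert spearman(x, np.exp(x / 10)).statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_full_enumeration_at_n8(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=8), rng.normal(size=8)
        result = spearman(x, y)
        assert result.p_value == pytest.approx(brute_force_spearman_p(x, y), abs=1e-12)
        assert "exact" in result.method

    def test_matches_reference_implementation_on_random_fixtures(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(11, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            if rng.uniform() < 0.3:  # inject ties
                x = np.round(x)
            result = spearman(x, y)
            ref = sps.spearmanr(x, y)
            assert result.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert result.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestKruskalWallis:
    def test_identical_groups_have_zero_statistic(self):
        result = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_twelve_groups_have_df_eleven(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=6) for _ in range(12)]
        assert kruskal_wallis(groups).df == 11

    def test_two_group_case_equals_rank_sum_normal_approximation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.normal(size=9), rng.normal(size=13)
            h = kruskal_wallis([a, b])
            ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic", use_continuity=False)
            assert h.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            g = int(rng.integers(2, 7))
            groups = [np.round(rng.normal(size=rng.integers(3, 12)), 1) for _ in range(g)]
            result = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert result.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert result.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([[1.0, 2.0], []])


class TestTTest:
    def test_identical_samples_give_zero_t(self):
        a = [1.0, 2.0, 3.0]
        result = t_test_independent(a, a)
        assert result.statistic == 0.0 and result.p_value == pytest.approx(1.0)

    def test_4_vs_8_gives_df_10(self):
        rng = np.random.default_rng(0)
        assert t_test_independent(rng.normal(size=4), rng.normal(size=8)).df == 10

    def test_textbook_pooled_t(self):
        result = t_test_independent([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert result.statistic == pytest.approx(-math.sqrt(1.5), abs=1e-10)
        assert result.statistic == pytest.approx(-1.2247, abs=1e-4)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 15))
            b = rng.normal(size=rng.integers(2, 15))
            result = t_test_independent(a, b)
            ref = sps.ttest_ind(a, b, equal_var=True)
            assert result.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert result.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValidationError):
            t_test_independent([2.0, 2.0], [3.0, 3.0])


class TestKSNormality:
    def test_large_normal_sample_not_rejected(self):
        x = np.random.default_rng(5).normal(size=500)
        assert ks_normality(x).p_value > 0.05

    def test_skewed_sample_rejected(self):
        x = np.random.default_rng(6).exponential(size=200)
        assert ks_normality(x).p_value < 0.01

    def test_statistic_matches_brute_force_sup_difference(self):
        rng = np.random.default_rng(7)
        x = rng.normal(2.0, 3.0, size=40)
        result = ks_normality(x)
        mu, sd = x.mean(), x.std(ddof=1)
        grid = np.sort(x)
        n = len(x)
        sup = 0.0
        for i, v in enumerate(grid):
            c = sps.norm.cdf(v, mu, sd)
            sup = max(sup, abs((i + 1) / n - c), abs(i / n - c))
        assert result.statistic == pytest.approx(sup, abs=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=rng.integers(10, 60))
            result = ks_normality(x)
            ref = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)), mode="asymp")
            assert result.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert result.p_value == pytest.approx(ref.pvalue, abs=1e-8)


class TestBattery:
    def _report(self, study):
        ids = study.adult_ids
        cent = eigenvector_centrality(compute_hwi(study.events, ids))
        cent_dai = eigenvector_centrality(compute_dai(study.bouts, study.roster, ids))
        return run_test_battery(study.roster, study.events, cent, cent_dai)

    def test_selective_data_shows_positive_rank_centrality(self, selective_study):
        report = self._report(selective_study)
        assert report["rank_vs_centrality_male"]["statistic"] > 0.5
        assert report["rank_vs_centrality_female"]["statistic"] > 0.5
        assert report["hwi_vs_dai_centrality"]["statistic"] > 0.5
        assert report["sex_centrality_t"]["df"] == 10
        assert report["centrality_heterogeneity_kw"]["df"] == 11

    def test_anonymous_data_shows_no_rank_effect_on_average(self):
        rhos = []
        for seed in range(8):
            study = simulate_study(
                SimulationConfig(rule="anonymous", n_events=171, seed=50 + seed)
            )
            cent = eigenvector_centrality(compute_hwi(study.events, study.adult_ids))
            report = run_test_battery(study.roster, study.events, cent, None)
            rhos.append(report["rank_vs_centrality_female"]["statistic"])
        assert abs(np.mean(rhos)) < 0.35

    def test_report_is_deterministic(self, selective_study):
        assert self._report(selective_study) == self._report(selective_study)

    def test_missing_input_error_names_stage(self, selective_study):
        with pytest.raises(ValidationError, match="events"):
            run_test_battery(selective_study.roster, [], None)
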