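import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from trabfd.errors import InsufficientDataError, InvalidArgumentError
from trabfd.stats import (
    chi_square_independence,
    chi_square_power,
    kruskal_wallis,
    pearson_correlation,
    pooled_summary,
    required_sample_size,
    shapiro_wilk,
)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_all_constant_data(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.H == 0.0
        assert res.p_value == 1.0

    def test_two_small_groups_vs_permutation_oracle(self):
        # exact null distribution by enumerating all label assignments
        groups = [[1.0, 2.0], [3.0, 4.0]]
        observed = kruskal_wallis(groups)
        pooled = [1.0, 2.0, 3.0, 4.0]
        h_values = []
        for combo in itertools.combinations(range(4), 2):
            g1 = [pooled[i] for i in combo]
            g2 = [pooled[i] for i in range(4) if i not in combo]
            h_values.append(kruskal_wallis([g1, g2]).H)
        exact_p = np.mean([h >= observed.H - 1e-12 for h in h_values])
        # H for perfect separation of {1,2} vs {3,4}: mean ranks 1.5 and 3.5
        assert observed.H == pytest.approx(12 / (4 * 5) * (2 * 1.0 + 2 * 1.0))
        assert exact_p == pytest.approx(2 / 6)  # two of six splits separate fully

    def test_matches_scipy_with_ties(self, rng):
        groups = [rng.integers(0, 6, size=n).astype(float) for n in (8, 11, 9)]
        res = kruskal_wallis(groups)
        h_ref, p_ref = sps.kruskal(*groups)
        assert res.H == pytest.approx(h_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_mean_rank_identity(self, rng):
        groups = [rng.normal(size=n) for n in (5, 9, 13)]
        res = kruskal_wallis(groups)
        n = sum(len(g) for g in groups)
        total = sum(len(g) * mr for g, mr in zip(groups, res.mean_ranks))
        assert total == pytest.approx(n * (n + 1) / 2)

    def test_monotone_transform_invariance(self, rng):
        groups = [rng.normal(loc=m, size=10) for m in (0, 1, 3)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.H == pytest.approx(b.H)
        assert a.mean_ranks == pytest.approx(b.mean_ranks)

    def test_too_few_groups_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kruskal_wallis([[1, 2, 3]])


class TestPearsonCorrelation:
    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, -2 * x + 5)
        assert res.r == pytest.approx(-1.0)
        assert res.p_value == pytest.approx(0.0)

    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        res = pearson_correlation(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)

    def test_null_p_distribution_uniform(self, rng):
        # independent x, y: p-values should be ~Uniform(0,1)
        pvals = []
        for _ in range(1000):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            pvals.append(pearson_correlation(x, y).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_zero_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_tiny_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            pearson_correlation([1, 2], [3, 4])


class TestChiSquareIndependence:
    def test_uniform_table_chi2_zero(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association(self):
        res = chi_square_independence([[20, 0], [0, 20]])
        assert res.chi2 == pytest.approx(40.0)
        assert res.df == 1

    def test_random_table_matches_direct_formula(self, rng):
        obs = rng.integers(1, 30, size=(5, 4)).astype(float)
        res = chi_square_independence(obs)
        row, col, total = obs.sum(1), obs.sum(0), obs.sum()
        chi2 = sum((obs[i, j] - row[i] * col[j] / total) ** 2
                   / (row[i] * col[j] / total)
                   for i in range(5) for j in range(4))
        assert res.chi2 == pytest.approx(chi2)
        assert res.df == 12
        ref = sps.chi2_contingency(obs, correction=False)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(InvalidArgumentError):
            chi_square_independence([[0, 0], [5, 5]])


class TestChiSquarePower:
    def test_reference_design_reproduced(self):
        spec = chi_square_power(0.5, 70, 12, 0.05)
        assert spec.noncentrality == pytest.approx(17.5)
        assert spec.critical_chi2 == pytest.approx(21.0260698, abs=5e-8)
        assert spec.power == pytest.approx(0.8046698, abs=5e-8)

    def test_vanishing_effect_power_tends_to_alpha(self):
        spec = chi_square_power(1e-6, 70, 12, 0.05)
        assert spec.power == pytest.approx(0.05, abs=1e-4)

    def test_power_monotone_in_n(self):
        p70 = chi_square_power(0.5, 70, 12, 0.05).power
        p140 = chi_square_power(0.5, 140, 12, 0.05).power
        assert p140 > p70

    def test_matches_monte_carlo_goodness_of_fit(self, rng):
        # simulate the alternative: 13-cell multinomial with effect size 0.5
        k = 13
        p0 = np.full(k, 1.0 / k)
        c = math.sqrt(0.25 / (k * (k - 1)))
        delta = np.array([c if i % 2 == 0 else -c for i in range(k - 1)] + [0.0])
        delta[-1] = -delta[:-1].sum()
        p1 = p0 + delta
        w = math.sqrt((delta ** 2 / p0).sum())
        assert w == pytest.approx(0.5, rel=0.05)
        spec = chi_square_power(w, 70, 12, 0.05)
        reps = 10_000
        tables = rng.multinomial(70, p1, size=reps)
        expected = 70 * p0
        stat = ((tables - expected) ** 2 / expected).sum(axis=1)
        mc_power = (stat > spec.critical_chi2).mean()
        se = math.sqrt(mc_power * (1 - mc_power) / reps)
        assert abs(mc_power - spec.power) < 3 * se + 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidArgumentError):
            chi_square_power(0.0, 70, 12)
        with pytest.raises(InvalidArgumentError):
            chi_square_power(0.5, 70, 12, alpha=1.5)


class TestRequiredSampleSize:
    def test_reference_design(self):
        assert required_sample_size(0.5, 12, 0.05, 0.80) == 70

    def test_tiny_target_gives_small_n(self):
        assert required_sample_size(0.5, 12, 0.05, 0.0501) <= 5

    def test_monotone_in_target_power(self):
        n80 = required_sample_size(0.5, 12, 0.05, 0.80)
        n90 = required_sample_size(0.5, 12, 0.05, 0.90)
        assert n90 >= n80

    def test_bad_target_rejected(self):
        with pytest.raises(InvalidArgumentError):
            required_sample_size(0.5, 12, 0.05, 0.04)


class TestShapiroWilk:
    def test_w_bounded(self, rng):
        w, _ = shapiro_wilk(rng.normal(size=50))
        assert 0 < w <= 1

    def test_null_p_distribution_uniform(self, rng):
        pvals = [shapiro_wilk(rng.normal(size=50))[1] for _ in range(1000)]
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001

    def test_bimodal_rejected_strongly(self, rng):
        x = np.concatenate([np.zeros(25), np.full(25, 100.0)])
        x += rng.normal(scale=0.5, size=50)
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(InvalidArgumentError):
            shapiro_wilk([3.0] * 10)


class TestPooledSummary:
    def test_bone_loss_total_row(self):
        mean, sd = pooled_summary([12.1, 25.4, 57.9, 77.0],
                                  [2.6, 4.7, 6.1, 10.3], [15] * 4)
        assert round(mean, 1) == 43.1
        assert round(sd, 1) == 26.7

    def test_fd_total_row(self):
        mean, sd = pooled_summary([1.21, 1.21, 1.19, 1.11, 1.02],
                                  [0.07, 0.06, 0.05, 0.05, 0.11], [15] * 5)
        assert round(mean, 2) == 1.15
        assert round(sd, 2) == 0.10

    def test_single_group_identity(self):
        mean, sd = pooled_summary([10.0], [2.0], [8])
        assert mean == pytest.approx(10.0)
        assert sd == pytest.approx(2.0)

    def test_equal_groups_zero_spread_returns_common_sd(self):
        mean, sd = pooled_summary([5.0, 5.0, 5.0], [1.3, 1.3, 1.3], [10, 10, 10])
        assert mean == pytest.approx(5.0)
        # the N-1 denominator shrinks the within-group SS by (N-k)/(N-1)
        assert sd == pytest.approx(1.3 * math.sqrt(27 / 29))

    def test_matches_raw_data_pooling(self, rng):
        groups = [rng.normal(loc=m, size=12) for m in (0.0, 2.0, 5.0)]
        mean, sd = pooled_summary([g.mean() for g in groups],
                                  [g.std(ddof=1) for g in groups],
                                  [len(g) for g in groups])
        pooled = np.concatenate(groups)
        assert mean == pytest.approx(pooled.mean())
        assert sd == pytest.approx(pooled.std(ddof=1))
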