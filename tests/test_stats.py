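"""Exact rank inference, descriptives, power search and questionnaire
scoring."""

from itertools import combinations
from math import comb

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from kneeprop.stats import (
    PowerSpec,
    anova_power,
    describe,
    exact_p_from_u,
    exact_u_distribution,
    mann_whitney,
    qq_normality_corr,
    required_sample_size,
    score_imi,
    score_ueq,
    ueq_quality_aggregates,
)


def brute_force_u_counts(n1, n2):
    """Enumerate all C(n1+n2, n1) rank assignments (the independent
    oracle)."""
    counts = np.zeros(n1 * n2 + 1, dtype=np.int64)
    for xs in combinations(range(n1 + n2), n1):
        xs = set(xs)
        u = sum(1 for i in xs for j in range(n1 + n2) if j not in xs and i > j)
        counts[u] += 1
    return counts


class TestExactDistribution:
    def test_smallest_case_by_hand(self):
        np.testing.assert_array_equal(exact_u_distribution(1, 1), [1, 1])

    def test_total_mass_and_symmetry(self):
        counts = exact_u_distribution(7, 7)
        assert counts.sum() == comb(14, 7) == 3432
        np.testing.assert_array_equal(counts, counts[::-1])

    def test_lower_tail_frozen_value(self):
        counts = exact_u_distribution(7, 7)
        assert counts[:9].sum() == 65  # P(U <= 8) = 65/3432 by enumeration

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 9) for n2 in range(n1, 9)])
    def test_matches_brute_force(self, n1, n2):
        np.testing.assert_array_equal(exact_u_distribution(n1, n2),
                                      brute_force_u_counts(n1, n2))

    def test_sizes_too_large_rejected(self):
        with pytest.raises(ValueError):
            exact_u_distribution(13, 13)


class TestMannWhitney:
    def test_complete_separation(self):
        r = mann_whitney(range(11, 18), range(1, 8))
        assert r.U == 49.0
        assert r.p == pytest.approx(1 / 3432)
        assert r.method == "exact"

    def test_identical_samples_midpoint(self):
        r = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4], "two_sided")
        assert r.U == 8.0  # n1*n2/2

    def test_published_u_statistics_reproduce_printed_p(self):
        """U=41 and U=42 with n=7 per arm give two-sided exact p-values
        .0379 and .0262, printing as .04 and .03 (the one-sided tails are
        .019 and .013)."""
        assert exact_p_from_u(41, 7, 7, "two_sided") == pytest.approx(130 / 3432)
        assert exact_p_from_u(42, 7, 7, "two_sided") == pytest.approx(90 / 3432)
        assert round(exact_p_from_u(41, 7, 7, "two_sided"), 2) == 0.04
        assert round(exact_p_from_u(42, 7, 7, "two_sided"), 2) == 0.03
        assert exact_p_from_u(41, 7, 7, "one_sided_greater") == pytest.approx(65 / 3432)

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=8)
            ours = mann_whitney(x, y, "two_sided")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.U == pytest.approx(ref.statistic)
            assert ours.p == pytest.approx(ref.pvalue)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=7), rng.normal(size=7)
        a = mann_whitney(x, y)
        b = mann_whitney(np.exp(x), np.exp(y))
        assert a.U == b.U and a.p == b.p

    def test_ties_fall_back_to_normal_approx(self):
        r = mann_whitney([1, 2, 2, 3], [2, 3, 4, 4])
        assert r.method == "normal_approx"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_null_rejection_rate_at_alpha(self, rng):
        """One-sided exact test at α=.05, n=7 vs 7: the achievable size is
        the largest upper-tail probability below .05 (167/3432 ≈ .0487);
        the empirical rate over 2000 null replicates must sit within
        Monte-Carlo tolerance of it."""
        n_rej = 0
        reps = 2000
        for _ in range(reps):
            x, y = rng.normal(size=7), rng.normal(size=7)
            n_rej += mann_whitney(x, y).p < 0.05
        rate = n_rej / reps
        counts = exact_u_distribution(7, 7)
        tails = np.cumsum(counts[::-1])[::-1] / counts.sum()
        size = tails[tails < 0.05].max()
        assert size == pytest.approx(167 / 3432)
        assert abs(rate - size) < 3 * np.sqrt(size * (1 - size) / reps)


class TestDescribe:
    @pytest.mark.parametrize(
        "vals, med",
        [(list(range(1, 8)), 4.0), ([1, 2, 3, 4], 2.5)],
    )
    def test_median(self, vals, med):
        assert describe(vals)[0] == med

    def test_matches_sort_based_oracle(self, rng):
        vals = rng.normal(size=1000)
        med, q1, q3 = describe(vals)
        s = np.sort(vals)

        def interp(p):
            h = p * (s.size - 1)
            lo = int(np.floor(h))
            return s[lo] + (h - lo) * (s[min(lo + 1, s.size - 1)] - s[lo])

        assert med == pytest.approx(interp(0.5))
        assert q1 == pytest.approx(interp(0.25))
        assert q3 == pytest.approx(interp(0.75))


class TestPower:
    def test_monotone_in_effect_size(self):
        base = required_sample_size(PowerSpec(effect_f=0.5))
        big = required_sample_size(PowerSpec(effect_f=1.0))
        assert big <= base

    def test_tiny_target_power_gives_minimal_n(self):
        assert required_sample_size(PowerSpec(target_power=1e-9)) == 4

    def test_against_numerical_integration_oracle(self):
        """Power at a candidate N equals direct numerical integration of
        the noncentral-F density above the critical value."""
        from scipy.integrate import quad

        spec = PowerSpec()
        n = 10
        df1, df2 = 1, n - 2
        lam = spec.effect_f**2 * n * 2 / (1 + spec.rho)
        fcrit = sps.f.ppf(0.95, df1, df2)
        oracle, _ = quad(lambda x: sps.ncf.pdf(x, df1, df2, lam), fcrit, np.inf)
        assert anova_power(n, spec) == pytest.approx(oracle, abs=1e-6)

    def test_search_returns_first_qualifying_n(self):
        spec = PowerSpec()
        n = required_sample_size(spec)
        assert anova_power(n, spec) >= 0.80
        assert anova_power(n - 2, spec) < 0.80


class TestQuestionnaires:
    def test_imi_modes(self):
        items = {"interest_enjoyment": [5] * 7}
        assert score_imi(items, mode="sum")["interest_enjoyment"] == 35.0
        assert score_imi(items, mode="mean")["interest_enjoyment"] == 5.0
        assert score_imi(items, mode="centered_sum")["interest_enjoyment"] == 7.0

    def test_imi_reverse_items(self):
        items = {"pressure_tension": [2, 2, 6, 1, 1]}
        scored = score_imi(items, reverse_map={"pressure_tension": [3]}, mode="sum")
        assert scored["pressure_tension"] == 2 + 2 + (8 - 6) + 1 + 1

    def test_imi_all_midpoint(self):
        assert score_imi({"perceived_choice": [4] * 7}, mode="mean")["perceived_choice"] == 4.0

    def test_imi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_imi({"interest_enjoyment": [0, 5]})

    def test_ueq_reported_aggregates(self):
        """The pragmatic/hedonic aggregates recomputed from the reported
        dimension means round to 2.49/2.27 (feedback arm) and 2.43/1.80
        (control arm)."""
        eg = ueq_quality_aggregates(
            {"perspicuity": 2.821, "efficiency": 2.143, "dependability": 2.500,
             "stimulation": 2.536, "novelty": 2.000}
        )
        assert round(eg["pragmatic"], 2) == 2.49
        assert round(eg["hedonic"], 2) == 2.27
        cg = ueq_quality_aggregates(
            {"perspicuity": 2.714, "efficiency": 2.286, "dependability": 2.286,
             "stimulation": 1.929, "novelty": 1.679}
        )
        assert round(cg["pragmatic"], 2) == 2.43
        assert round(cg["hedonic"], 2) == 1.80

    def test_ueq_ceiling(self):
        items = {d: [3] * 4 for d in
                 ("attractiveness", "perspicuity", "efficiency", "dependability",
                  "stimulation", "novelty")}
        scored = score_ueq(items)
        assert scored["pragmatic"] == 3.0 and scored["hedonic"] == 3.0
        assert all(scored[d] == 3.0 for d in items)

    def test_ueq_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_ueq({"novelty": [4, 0]})


def test_qq_correlation_flags_heavy_tails(rng):
    normal = rng.normal(size=200)
    heavy = rng.standard_cauchy(size=200)
    assert qq_normality_corr(normal) > 0.99
    assert qq_normality_corr(heavy) < qq_normality_corr(normal)
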