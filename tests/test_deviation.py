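"""Deviation statistics: RF metric, bootstrap variance, multinomial null."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from aperates.deviation import (
    BootstrapDegenerateError,
    NullCache,
    RFResult,
    bootstrap_rf_variance,
    branch_deviation_test,
    rf_score,
    rf_z_test,
    simulate_null,
    summarize_deviations,
)
from aperates.phylo import BRANCHES
from aperates.rates import MeanTree, family_tree, pc_branch_length
from aperates.sites import FamilyCounts

REF_PROBS = [0.1174, 0.1115, 0.0372, 0.1542, 0.5797]
_REF_SUM = sum(REF_PROBS)
REF_PROBS = [p / _REF_SUM for p in REF_PROBS]


def fc(family_id, L, **n):
    counts = {b: 0 for b in BRANCHES}
    counts.update(n)
    return FamilyCounts(family_id, L, counts)


def tree(*vals):
    return dict(zip(BRANCHES, vals))


class TestRFScore:
    def test_zero_when_equal(self):
        t = tree(0.003, 0.003, 0.001, 0.004, 0.015)
        assert rf_score(t, t) == 0.0

    def test_hand_arithmetic(self):
        a = tree(0.004, 0.003, 0.001, 0.004, 0.015)
        mean = tree(0.003, 0.003, 0.001, 0.004, 0.015)
        assert rf_score(a, mean) == pytest.approx(0.001)

    @given(
        st.lists(st.floats(0, 0.5, allow_nan=False), min_size=5, max_size=5),
        st.lists(st.floats(0, 0.5, allow_nan=False), min_size=5, max_size=5),
        st.lists(st.floats(0, 0.5, allow_nan=False), min_size=5, max_size=5),
    )
    @settings(max_examples=200, deadline=None)
    def test_metric_axioms(self, a, b, c):
        ta, tb, tc = tree(*a), tree(*b), tree(*c)
        assert rf_score(ta, tb) >= 0
        assert rf_score(ta, tb) == rf_score(tb, ta)
        assert rf_score(ta, ta) == 0
        assert rf_score(ta, tc) <= rf_score(ta, tb) + rf_score(tb, tc) + 1e-12


class TestBootstrapVariance:
    MEAN = MeanTree(
        pc=tree(0.003, 0.003, 0.001, 0.004, 0.015), n_families_used=1, n_zero_excluded=0
    )

    def test_all_identical_family_has_zero_variance(self):
        zbar, v = bootstrap_rf_variance(fc("f", 200), self.MEAN, B=200, seed=1)
        assert v == 0.0
        assert zbar == pytest.approx(sum(self.MEAN.pc.values()))

    def test_fixed_seed_is_deterministic(self):
        family = fc("f", 300, human=3, gibbon=7)
        r1 = bootstrap_rf_variance(family, self.MEAN, B=500, seed=9)
        r2 = bootstrap_rf_variance(family, self.MEAN, B=500, seed=9)
        assert r1 == r2

    def test_matches_naive_per_column_resampling_oracle(self):
        """Grouped-multinomial bootstrap agrees with literally resampling
        columns one by one (independent implementation, larger B)."""
        family = fc("f", 500, human=6, chimp=4, internal=2, gorilla=8, gibbon=25)
        _, v = bootstrap_rf_variance(family, self.MEAN, B=1000, seed=3)

        labels = np.repeat(np.arange(6), [6, 4, 2, 8, 25, 455])
        rng = np.random.default_rng(12345)
        mean_vec = np.array([self.MEAN.pc[b] for b in BRANCHES])
        B = 10_000
        idx = rng.integers(0, 500, size=(B, 500))
        sampled = labels[idx]
        counts = np.stack([(sampled == k).sum(axis=1) for k in range(5)], axis=1)
        z = np.abs(-np.log1p(-counts / 500) - mean_vec).sum(axis=1)
        v_oracle = z.var(ddof=1)
        assert abs(v - v_oracle) <= 0.1 * v_oracle

    def test_saturating_family_aborts(self):
        family = fc("f", 3, gibbon=2, human=1)  # tiny L: replicates saturate
        with pytest.raises(BootstrapDegenerateError):
            bootstrap_rf_variance(family, self.MEAN, B=500, seed=2)


class TestRFZTest:
    def test_zero_score_gives_p_one(self):
        (r,) = rf_z_test([RFResult("f", z=0.0, zbar=0.0, V=0.0)])
        assert r.Z == 0.0 and r.p == 1.0 and not r.untestable

    def test_z_quantile(self):
        (r,) = rf_z_test([RFResult("f", z=1.959964, zbar=1.9, V=1.0)])
        assert r.p == pytest.approx(0.05, abs=1e-4)

    def test_degenerate_nonzero_score_flagged_untestable(self):
        (r,) = rf_z_test([RFResult("f", z=0.5, zbar=0.5, V=0.0)])
        assert r.untestable and math.isnan(r.q)

    def test_benjamini_hochberg_step_up(self):
        # two-sided p-values 0.01, 0.02, 0.04, 0.8 at alpha = 0.05:
        # step-up thresholds are 0.0125, 0.025, 0.0375, 0.05, so exactly
        # the first two are rejected (0.04 > 0.0375).
        zs = [stats.norm.isf(p / 2) for p in (0.01, 0.02, 0.04, 0.8)]
        results = rf_z_test(
            [RFResult(f"f{i}", z=z, zbar=z, V=1.0) for i, z in enumerate(zs)]
        )
        rejected = [r.family_id for r in results if r.q < 0.05]
        assert rejected == ["f0", "f1"]
        assert results[2].q == pytest.approx(0.04 * 4 / 3, rel=1e-6)


class TestSimulateNull:
    def test_single_event_frequencies_match_probs(self):
        null = simulate_null(1, REF_PROBS, S=100_000, seed=4)
        for bi, b in enumerate(BRANCHES):
            freq = null.marginals[bi, 1] / null.S
            se = math.sqrt(REF_PROBS[bi] * (1 - REF_PROBS[bi]) / null.S)
            assert abs(freq - REF_PROBS[bi]) <= 3 * se

    def test_degenerate_probs_put_all_events_on_one_branch(self):
        null = simulate_null(7, [1.0, 0.0, 0.0, 0.0, 0.0], S=1000, seed=5)
        assert null.marginals[0, 7] == 1000
        assert null.branch_pvalue("human", 7) == 1.0

    def test_marginal_matches_binomial_within_kolmogorov_distance(self):
        null = simulate_null(40, REF_PROBS, S=100_000, seed=6)
        for bi in range(5):
            emp_cdf = np.cumsum(null.marginals[bi]) / null.S
            exact_cdf = stats.binom.cdf(np.arange(41), 40, REF_PROBS[bi])
            assert np.abs(emp_cdf - exact_cdf).max() < 0.01

    def test_determinism_and_cache(self):
        a = simulate_null(15, REF_PROBS, S=20_000, seed=7)
        b = simulate_null(15, REF_PROBS, S=20_000, seed=7)
        assert np.array_equal(a.marginals, b.marginals)
        cache = NullCache(REF_PROBS, S=20_000, seed=7)
        assert cache.get(15) is cache.get(15)
        assert np.array_equal(cache.get(15).marginals, a.marginals)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_null(0, REF_PROBS)
        with pytest.raises(ValueError):
            simulate_null(5, [0.5, 0.5, 0.5, 0, 0])


class TestBranchDeviationTest:
    def test_median_observation_is_not_significant(self):
        null = simulate_null(10, [0.5, 0.5, 0.0, 0.0, 0.0], S=50_000, seed=8)
        family = fc("f", 100, human=5, chimp=5)
        rows = branch_deviation_test(family, null)
        by = {r.branch: r for r in rows}
        assert by["human"].p == 1.0  # at the null median, capped
        assert not by["human"].significant

    def test_extreme_observation_hits_simulation_floor(self):
        # all 50 events on gibbon: p bounded by twice one replicate
        cache = NullCache(REF_PROBS, S=100_000, seed=9)
        family = fc("f", 500, gibbon=50)
        rows = branch_deviation_test(family, cache)
        by = {r.branch: r for r in rows}
        assert by["gibbon"].p <= 2 / 100_000
        assert by["gibbon"].direction == "faster" and by["gibbon"].significant

    def test_zero_substitution_family_skipped_with_p_one(self):
        rows = branch_deviation_test(fc("f", 100), NullCache(REF_PROBS, S=1000))
        assert all(r.p == 1.0 and not r.significant for r in rows)

    def test_adjusted_threshold_is_alpha_over_branches(self):
        # default alpha 0.05 over 5 branches: significant iff p < 0.01
        cache = NullCache(REF_PROBS, S=100_000, seed=10)
        rows = []
        for i, n_gib in enumerate(range(0, 26)):
            rows.extend(
                branch_deviation_test(fc(f"f{i}", 500, gibbon=n_gib, human=25 - n_gib), cache)
            )
        assert any(r.significant for r in rows) and any(not r.significant for r in rows)
        for r in rows:
            assert r.significant == (r.p < 0.05 / 5)

    def test_direction_matches_sign_of_departure(self):
        cache = NullCache(REF_PROBS, S=50_000, seed=11)
        rows = branch_deviation_test(fc("f", 500, gibbon=40, human=1), cache)
        by = {r.branch: r for r in rows}
        assert by["gibbon"].direction == "faster"
        assert by["human"].direction == "slower"


def test_summarize_deviations_groups_single_and_combination():
    cache = NullCache(REF_PROBS, S=100_000, seed=12)
    rows = []
    rows.extend(branch_deviation_test(fc("solo", 500, gorilla=20, gibbon=10), cache))
    rows.extend(branch_deviation_test(fc("combo", 500, gibbon=60), cache))
    df = summarize_deviations(rows)
    gor = df[df.branches == "gorilla"].iloc[0]
    assert gor.higher_than_expected >= 0  # column structure present
    assert set(df.columns) == {
        "branches",
        "lower_than_expected",
        "higher_than_expected",
        "mixed_direction",
    }
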