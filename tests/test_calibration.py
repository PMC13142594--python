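"""Multiple-testing corrections, chance thresholds, bootstrap CIs and
flag aggregation, checked against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shortcut_audit import (
    AggregationPolicy,
    DetectorResult,
    ValidationError,
    aggregate,
    bootstrap_ci,
    chance_threshold,
    correct_pvalues,
)
from shortcut_audit.results import ConvergenceLevel

from conftest import make_dataset


# --- independent brute-force oracles -----------------------------------
def oracle_bonferroni(p):
    return np.minimum(1.0, np.asarray(p) * len(p))


def oracle_holm(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def oracle_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m * p[idx] / (rank + 1))
        adj[idx] = min(1.0, running)
    return adj


ORACLES = {"bonferroni": oracle_bonferroni, "holm": oracle_holm, "fdr_bh": oracle_bh}


class TestCorrections:
    def test_bonferroni_closed_form(self):
        np.testing.assert_allclose(
            correct_pvalues([0.01, 0.2], "bonferroni"), [0.02, 0.4]
        )

    def test_bh_step_up_example(self):
        np.testing.assert_allclose(
            correct_pvalues([0.01, 0.02, 0.04], "fdr_bh"), [0.03, 0.03, 0.04]
        )

    def test_single_pvalue_identity(self):
        for method in ORACLES:
            np.testing.assert_allclose(correct_pvalues([0.01], method), [0.01])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10),
        st.sampled_from(sorted(ORACLES)),
    )
    def test_matches_brute_force_oracle(self, p, method):
        np.testing.assert_allclose(
            correct_pvalues(p, method), ORACLES[method](p), atol=1e-12
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_fwer_methods_never_decrease_p(self, p):
        for method in ("bonferroni", "holm"):
            adj = correct_pvalues(p, method)
            assert np.all(adj >= np.asarray(p) - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            correct_pvalues([0.5, 1.5])


class TestChanceThreshold:
    def test_accuracy_statistic_near_chance(self):
        ds = make_dataset(n=1000, d=4, seed=0)

        def stat(E, a):
            # best single-threshold accuracy on dim 0 sign
            return max(((E[:, 0] > 0) == (a == 1)).mean(),
                       ((E[:, 0] > 0) == (a == 0)).mean())

        thr = chance_threshold(ds, "group", stat, permutations=100, seed=1)
        assert 0.5 < thr < 0.58

    def test_constant_statistic(self):
        ds = make_dataset(n=50, d=3, seed=0)
        thr = chance_threshold(ds, "group", lambda E, a: 0.42, permutations=60)
        assert thr == pytest.approx(0.42)

    def test_too_few_permutations_rejected(self):
        ds = make_dataset(n=50, d=3, seed=0)
        with pytest.raises(ValidationError):
            chance_threshold(ds, "group", lambda E, a: 0.0, permutations=10)


class TestBootstrapCI:
    def test_degenerate_values(self):
        assert bootstrap_ci([0.3] * 5, B=200) == (0.3, 0.3)

    def test_binary_values_bracket_mean(self):
        lo, hi = bootstrap_ci([0, 1] * 5, B=1000, seed=0)
        assert lo <= 0.5 <= hi
        assert hi - lo < 0.7

    def test_validation(self):
        with pytest.raises(ValidationError):
            bootstrap_ci([1.0], B=200)
        with pytest.raises(ValidationError):
            bootstrap_ci([0, 1], B=10)


def _results(n_flags, n_total, flag_names=None):
    out = []
    names = flag_names or [f"m{i}" for i in range(n_total)]
    for i, name in enumerate(names):
        flag = i < n_flags
        out.append(
            DetectorResult(
                method_name=name,
                score=0.9 if flag else 0.1,
                threshold=0.5,
                flag=flag,
            )
        )
    return out


class TestAggregate:
    def test_eight_of_twelve_is_high(self):
        agg = aggregate(_results(8, 12))
        assert agg.agreement == 8 and agg.denominator == 12
        assert agg.risk_score == pytest.approx(8 / 12)
        assert agg.convergence_level is ConvergenceLevel.HIGH

    def test_adjusted_counts_exclude_uncalibrated_trio(self):
        names = [
            "hbac", "probe", "frequency", "bias_direction", "sis",
            "demographic_parity", "equalized_odds", "statistical",
            "geometric", "intersectional", "group_dro", "gce", "ssa",
        ]
        # flags on the first seven -> 7/13 raw, 4/10 adjusted
        agg = aggregate(_results(7, 13, names))
        assert (agg.agreement, agg.denominator) == (7, 13)
        assert (agg.adjusted_agreement, agg.adjusted_denominator) == (4, 10)

    def test_no_flags_is_none_level(self):
        agg = aggregate(_results(0, 12))
        assert agg.agreement == 0 and agg.risk_score == 0.0
        assert agg.convergence_level is ConvergenceLevel.NONE

    def test_zero_applicable_rejected(self):
        na = [DetectorResult.not_applicable("m", "why")]
        with pytest.raises(ValidationError):
            aggregate(na)

    @pytest.mark.parametrize("den", range(1, 14))
    def test_bands_exhaustive_over_denominators(self, den):
        """Convergence banding arithmetic for every denominator 1..13."""
        policy = AggregationPolicy()
        for agree in range(den + 1):
            level = policy.level(agree, den)
            hi = math.ceil(7 / 12 * den - 1e-9)
            mod = math.ceil(5 / 12 * den - 1e-9)
            if agree >= hi:
                assert level is ConvergenceLevel.HIGH
            elif agree >= mod:
                assert level is ConvergenceLevel.MODERATE
            elif agree >= 1:
                assert level is ConvergenceLevel.LOW
            else:
                assert level is ConvergenceLevel.NONE
        if den == 12:
            assert policy.level(7, 12) is ConvergenceLevel.HIGH
            assert policy.level(6, 12) is not ConvergenceLevel.HIGH

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 13), st.data())
    def test_order_invariant_and_monotone(self, den, data):
        flags = data.draw(st.lists(st.booleans(), min_size=den, max_size=den))
        results = [
            DetectorResult(f"m{i}", 0.9 if f else 0.1, 0.5, f)
            for i, f in enumerate(flags)
        ]
        agg = aggregate(results)
        perm = data.draw(st.permutations(results))
        agg2 = aggregate(perm)
        assert (agg.agreement, agg.denominator, agg.risk_score) == (
            agg2.agreement, agg2.denominator, agg2.risk_score
        )
        # adding one flagged result never decreases agreement/R/level
        more = results + [DetectorResult("extra", 0.9, 0.5, True)]
        agg3 = aggregate(more)
        assert agg3.agreement == agg.agreement + 1
        assert agg3.risk_score >= agg.risk_score
        order = list(ConvergenceLevel)
        assert order.index(agg3.convergence_level) >= order.index(
            agg.convergence_level
        )
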