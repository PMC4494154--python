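"""Closed-form estimators, the removal MLE, and their validity diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import recapture as rc


# ---------------------------------------------------------------------------
# closed-form point estimates (hand-computed expected values)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "estimator, counts, expected",
    [
        (rc.removal_two_occasion, (500, 0, 0), 500.0),
        (rc.removal_two_occasion, (500, 375, 250), 500**2 / 250),
        (rc.removal_two_occasion, (300, 65, 70), 300**2 / 230),
        (rc.lincoln_petersen, (500, 375, 250), 500 * 625 / 375),
        (rc.lincoln_petersen, (300, 65, 35), 300 * 100 / 65),
        (rc.lincoln_petersen, (10, 10, 0), 10.0),
        (rc.chapman, (500, 375, 250), 501 * 626 / 376),
        (rc.chapman, (300, 65, 35), 301 * 101 / 66),
        (rc.chapman, (0, 0, 0), 1.0),
    ],
)
def test_closed_form_estimates(estimator, counts, expected):
    res = estimator(rc.TwoOccasionCounts(*counts))
    assert res.valid
    assert res.estimate == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize(
    "estimator, counts, reason",
    [
        (rc.removal_two_occasion, (100, 50, 100), "n1<=n2"),
        (rc.removal_two_occasion, (100, 50, 150), "n1<=n2"),
        (rc.lincoln_petersen, (10, 0, 5), "m=0"),
    ],
)
def test_undefined_estimates_are_flagged_not_raised(estimator, counts, reason):
    res = estimator(rc.TwoOccasionCounts(*counts))
    assert not res.valid
    assert res.invalid_reason == reason


def test_count_invariants_rejected():
    with pytest.raises(ValueError):
        rc.TwoOccasionCounts(-1, 0, 0)
    with pytest.raises(ValueError):
        rc.TwoOccasionCounts(5, 6, 0)  # recaptures exceed occasion-1 total


# ---------------------------------------------------------------------------
# Chao estimators
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "M, f, expected",
    [
        (5, {1: 10, 2: 5}, (4 / 5) * 100 / 10),
        (10, {2: 7}, 0.0),  # no singletons -> no estimated unseen
        (2, {1: 12, 2: 4}, (1 / 2) * 144 / 8),
    ],
)
def test_chao_unseen(M, f, expected):
    res = rc.chao_unseen(rc.FrequencyCounts(M, f))
    assert res.valid
    assert res.estimate == pytest.approx(expected, rel=1e-12)


def test_chao_population_adds_observed_count():
    freqs = rc.FrequencyCounts(5, {1: 10, 2: 5, 3: 35})
    assert freqs.s == 50
    res = rc.chao_population(freqs)
    assert res.valid and res.estimate == pytest.approx(58.0)
    # empty register
    empty = rc.chao_population(rc.FrequencyCounts(10, {}))
    assert empty.valid and empty.estimate == 0.0


def test_chao_invalid_without_doubletons():
    res = rc.chao_unseen(rc.FrequencyCounts(6, {1: 9}))
    assert not res.valid and res.invalid_reason == "f2=0"
    pop = rc.chao_population(rc.FrequencyCounts(6, {1: 9}))
    assert not pop.valid and pop.invalid_reason == "f2=0"


def test_chao_poisson_limit():
    assert rc.chao_poisson_limit(10, 5).estimate == pytest.approx(10.0)
    assert rc.chao_poisson_limit(0, 3).estimate == 0.0
    # binomial form converges to the Poisson form as M grows
    big = rc.chao_unseen(rc.FrequencyCounts(10**6, {1: 10, 2: 5}))
    assert abs(big.estimate - 10.0) < 1e-5


def test_frequency_counts_invariants():
    with pytest.raises(ValueError):
        rc.FrequencyCounts(1, {1: 3})  # M < 2
    with pytest.raises(ValueError):
        rc.FrequencyCounts(3, {4: 1})  # capture count above M
    with pytest.raises(ValueError):
        rc.FrequencyCounts(3, {1: 2}, s=5)  # s inconsistent with frequencies


# ---------------------------------------------------------------------------
# removal-assumption diagnostic
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cells, cond, uncond, ok",
    [
        ((0.30, 0.20, 0.25, 0.25), 0.50, 0.50, True),
        ((0.065, 0.235, 0.035, 0.665), 0.05, 0.30, False),
        ((0.25, 0.25, 0.25, 0.25), 0.50, 0.50, True),
    ],
)
def test_removal_assumption_diagnostic(cells, cond, uncond, ok):
    c, u, satisfied = rc.removal_assumption_diagnostic(rc.CellProbabilities(*cells))
    assert c == pytest.approx(cond, abs=1e-12)
    assert u == pytest.approx(uncond, abs=1e-12)
    assert satisfied is ok


def test_removal_assumption_diagnostic_undefined():
    with pytest.raises(ValueError):
        rc.removal_assumption_diagnostic(rc.CellProbabilities(0.6, 0.4, 0.0, 0.0))


# ---------------------------------------------------------------------------
# removal maximum likelihood (general M)
# ---------------------------------------------------------------------------


def test_removal_mle_matches_two_occasion_closed_form():
    res = rc.removal_mle([500, 250])
    assert res.valid
    assert res.N_hat == pytest.approx(1000.0, rel=1e-6)
    assert res.p_hat == pytest.approx(0.5, rel=1e-6)


def test_removal_mle_boundary_all_removed_at_once():
    res = rc.removal_mle([300, 0])
    assert res.valid
    assert res.N_hat == 300.0 and res.p_hat == 1.0


def test_removal_mle_no_interior_maximum():
    res = rc.removal_mle([100, 100])
    assert not res.valid and res.invalid_reason == "no interior maximum"
    # increasing removals are even worse
    assert not rc.removal_mle([10, 20, 30]).valid


def test_removal_mle_three_occasions_exact_solution():
    # u = (150, 90, 54) are the exact expected removals for N=375, p=0.4:
    # 375*0.4 = 150, 225*0.4 = 90, 135*0.4 = 54, so the estimating
    # equations are solved exactly by (375, 0.4).
    res = rc.removal_mle([150, 90, 54])
    assert res.valid
    assert res.N_hat == pytest.approx(375.0, rel=1e-6)
    assert res.p_hat == pytest.approx(0.4, rel=1e-6)


def test_removal_mle_maximizes_its_own_likelihood():
    u = np.array([120, 70, 45, 30])
    res = rc.removal_mle(u)
    assert res.valid
    best = rc.core._removal_loglik(res.N_hat, res.p_hat, u)
    for dN in (-5.0, 5.0):
        for dp in (-0.02, 0.02):
            assert rc.core._removal_loglik(res.N_hat + dN, res.p_hat + dp, u) < best


def test_removal_mle_input_errors():
    with pytest.raises(ValueError):
        rc.removal_mle([5])  # single occasion
    with pytest.raises(ValueError):
        rc.removal_mle([3, -1])
    with pytest.raises(ValueError):
        rc.removal_mle([0, 0])


# ---------------------------------------------------------------------------
# invariants (property-based)
# ---------------------------------------------------------------------------

counts_strategy = st.tuples(
    st.integers(1, 5000), st.integers(0, 5000), st.integers(0, 5000)
).map(lambda t: rc.TwoOccasionCounts(t[0], min(t[1], t[0]), t[2]))


@settings(derandomize=True, max_examples=200)
@given(counts=counts_strategy, k=st.integers(2, 20))
def test_scale_equivariance(counts, k):
    """Multiplying all counts by k multiplies LP and removal estimates by k."""
    scaled = rc.TwoOccasionCounts(k * counts.n1, k * counts.m, k * counts.n2)
    lp, lp_k = rc.lincoln_petersen(counts), rc.lincoln_petersen(scaled)
    if lp.valid:
        assert lp_k.estimate == pytest.approx(k * lp.estimate, rel=1e-12)
    rm, rm_k = rc.removal_two_occasion(counts), rc.removal_two_occasion(scaled)
    assert rm.valid == rm_k.valid
    if rm.valid:
        assert rm_k.estimate == pytest.approx(k * rm.estimate, rel=1e-12)


@settings(derandomize=True, max_examples=200)
@given(counts=counts_strategy)
def test_valid_estimates_bounded_below_by_observed(counts):
    """Any valid estimate is at least the number of observed individuals."""
    observed = counts.observed
    for est in (rc.removal_two_occasion, rc.lincoln_petersen, rc.chapman):
        res = est(counts)
        if res.valid:
            assert res.estimate >= observed - 1e-9


@settings(derandomize=True, max_examples=200)
@given(M=st.integers(2, 30), f1=st.integers(1, 10**4), f2=st.integers(1, 10**4))
def test_chao_monotonicity(M, f1, f2):
    """Chao's unseen estimate grows with singletons, shrinks with doubletons."""
    base = rc.chao_unseen(rc.FrequencyCounts(M, {1: f1, 2: f2})).estimate
    more_f1 = rc.chao_unseen(rc.FrequencyCounts(M, {1: f1 + 1, 2: f2})).estimate
    more_f2 = rc.chao_unseen(rc.FrequencyCounts(M, {1: f1, 2: f2 + 1})).estimate
    assert more_f1 > base > more_f2


@settings(derandomize=True, max_examples=200)
@given(n1=st.integers(2, 10**4), n2=st.integers(0, 10**4))
def test_removal_increasing_in_new_second_occasion_captures(n1, n2):
    n2 = min(n2, n1 - 2)
    if n2 < 0:
        return
    lo = rc.removal_two_occasion(rc.TwoOccasionCounts(n1, 0, n2)).estimate
    hi = rc.removal_two_occasion(rc.TwoOccasionCounts(n1, 0, n2 + 1)).estimate
    assert hi > lo
    assert lo >= n1 + n2 - 1e-9  # valid removal estimate covers the observed


@settings(derandomize=True, max_examples=50)
@given(f1=st.integers(1, 1000), f2=st.integers(1, 1000))
def test_chao_binomial_form_converges_to_poisson_form(f1, f2):
    poisson = rc.chao_poisson_limit(f1, f2).estimate
    prev_gap = None
    for M in (10, 100, 1000):
        gap = abs(rc.chao_unseen(rc.FrequencyCounts(M, {1: f1, 2: f2})).estimate - poisson)
        if prev_gap is not None:
            assert gap <= prev_gap + 1e-12
        prev_gap = gap
    # the gap at M occasions is exactly poisson/M
    assert prev_gap == pytest.approx(poisson / 1000, rel=1e-9)
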