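"""Likelihood machinery against enumeration oracles, plus recovery checks."""

import itertools
import math

import numpy as np
import pytest

from colext import (
    PresenceSeries,
    RatePair,
    SiteObservations,
    filter_labile,
    fit_rates,
    fit_rates_detectability,
    negative_log_likelihood,
    simulate_presence,
)
from colext.estimation import (
    GroupRates,
    _forward_nll_site,
    _nll_from_counts,
    transition_counts,
)
from colext.markov import transition_matrix
from colext.synthetic import SyntheticSpec


def brute_force_nll(rates: RatePair, series: PresenceSeries) -> float:
    """Independent oracle: explicit product over every consecutive pair."""
    loglik = 0.0
    for obs in series.sites.values():
        det = obs.detections.any(axis=2)
        for row in det:
            for j in range(len(obs.times) - 1):
                p = transition_matrix(rates, obs.times[j + 1] - obs.times[j])
                loglik += math.log(p[int(row[j]), int(row[j + 1])])
    return -loglik


def test_single_interval_likelihood_is_closed_form():
    times = np.array([0.0, 7.0])
    series = PresenceSeries(
        ("a",), {"s": SiteObservations(times, np.array([[1, 1]], dtype=bool))}
    )
    rp = RatePair(0.3, 0.2)
    expected = -math.log(transition_matrix(rp, 7.0)[1, 1])
    assert negative_log_likelihood(rp, series) == pytest.approx(expected, abs=1e-12)


def test_impossible_transition_yields_infinite_nll(two_taxon_series):
    # c = 0 cannot produce the observed 0 -> 1 transitions
    assert negative_log_likelihood(RatePair(0.0, 0.1), two_taxon_series) == math.inf
    assert negative_log_likelihood(RatePair(0.0, 0.0), two_taxon_series) == math.inf


def test_likelihood_matches_product_oracle(likelihood_series):
    for c, e in [(0.05, 0.02), (0.3, 0.3), (1.0, 0.1)]:
        rp = RatePair(c, e)
        assert negative_log_likelihood(rp, likelihood_series) == pytest.approx(
            brute_force_nll(rp, likelihood_series), abs=1e-10
        )


def test_mle_within_one_step_of_exhaustive_grid(two_taxon_series):
    fit = fit_rates(two_taxon_series)[0]
    dts, counts = transition_counts(two_taxon_series)
    grid = np.logspace(-4, 1, 200)
    nlls = np.array(
        [[_nll_from_counts(c, e, dts, counts) for e in grid] for c in grid]
    )
    ci, ei = np.unravel_index(np.argmin(nlls), nlls.shape)
    step = grid[1] / grid[0]
    assert grid[ci] / step <= fit.c <= grid[ci] * step
    assert grid[ei] / step <= fit.e <= grid[ei] * step
    assert -fit.log_likelihood <= nlls[ci, ei] + 1e-8


def test_group_fit_recovers_shared_rates_and_error_shrinks_with_pool_size():
    errs = {}
    for n in (50, 500):
        spec = SyntheticSpec(
            n_taxa=n,
            times=tuple(float(t) for t in range(24)),
            rate_model="fixed",
            c=0.2,
            e=0.1,
            seed=7,
        )
        series, _ = simulate_presence(spec)
        fit = fit_rates(series)[0]
        errs[n] = abs(fit.c / 0.2 - 1) + abs(fit.e / 0.1 - 1)
        assert fit.converged and not fit.boundary
    assert errs[500] < 0.2  # ~23 transitions per taxon: a tight joint fit
    assert errs[500] < errs[50]


def test_irregular_gaps_are_handled_by_per_pair_intervals():
    times = tuple(float(t) for t in [0, 30, 45, 120, 150, 240, 300, 330, 390, 480])
    spec = SyntheticSpec(
        n_taxa=400, times=times, rate_model="fixed", c=0.02, e=0.01, seed=11
    )
    series, _ = simulate_presence(spec)
    fit = fit_rates(series)[0]
    assert fit.c == pytest.approx(0.02, rel=0.15)
    assert fit.e == pytest.approx(0.01, rel=0.15)


def test_all_present_group_pins_extinction_at_boundary():
    times = np.arange(6.0)
    det = np.ones((3, 6), dtype=bool)
    series = PresenceSeries(
        ("a", "b", "c"), {"s": SiteObservations(times, det)}
    )
    fit = fit_rates(series)[0]
    assert fit.boundary
    assert fit.e == pytest.approx(1e-6, rel=1e-2)  # lower rate bound


def test_all_absent_group_raises():
    times = np.arange(5.0)
    series = PresenceSeries(
        ("a",), {"s": SiteObservations(times, np.zeros((1, 5), dtype=bool))}
    )
    with pytest.raises(ValueError, match="never observed"):
        fit_rates(series)


def test_estimates_invariant_to_taxon_order_and_labels(two_taxon_series):
    joint = fit_rates(two_taxon_series, {"a": "g", "b": "g"})[0]
    flipped = two_taxon_series.subset(["b", "a"])
    joint_flipped = fit_rates(flipped, {"a": "h", "b": "h"})[0]
    assert joint.c == pytest.approx(joint_flipped.c, rel=1e-6)
    assert joint.e == pytest.approx(joint_flipped.e, rel=1e-6)


# --- imperfect detectability -------------------------------------------------


def enumerate_latent_paths_nll(c, e, d, times, y, r) -> float:
    """Oracle: sum over all 2^T latent presence paths."""
    rp = RatePair(c, e)
    pi = c / (c + e)
    total = 0.0
    for path in itertools.product([0, 1], repeat=len(times)):
        prob = pi if path[0] else 1.0 - pi
        for j in range(1, len(times)):
            prob *= transition_matrix(rp, times[j] - times[j - 1])[path[j - 1], path[j]]
        for j, x in enumerate(path):
            if x:
                prob *= math.comb(r, int(y[j])) * d ** y[j] * (1 - d) ** (r - y[j])
            elif y[j] > 0:
                prob = 0.0
        total += prob
    return -math.log(total)


def test_forward_algorithm_matches_path_enumeration():
    times = np.array([0.0, 10.0, 15.0, 45.0])
    y = np.array([[2, 0, 1, 2], [0, 0, 3, 1]])
    for c, e, d in [(0.05, 0.02, 0.8), (0.2, 0.3, 0.5)]:
        expected = sum(
            enumerate_latent_paths_nll(c, e, d, times, row, 3) for row in y
        )
        got = _forward_nll_site(c, e, d, times, y, 3)
        assert got == pytest.approx(expected, abs=1e-10)


def test_detectability_requires_replicates(two_taxon_series):
    with pytest.raises(ValueError, match="fit_rates"):
        fit_rates_detectability(two_taxon_series)


def test_perfect_detection_reduces_to_collapsed_fit():
    spec = SyntheticSpec(
        n_taxa=300,
        times=tuple(float(t) for t in range(24)),
        rate_model="fixed",
        c=0.25,
        e=0.12,
        replicates=2,
        detection="bernoulli",
        d=1.0,
        seed=3,
    )
    series, _ = simulate_presence(spec)
    latent = fit_rates_detectability(series, fix_d=1.0)[0]
    collapsed = fit_rates(series.collapse_replicates())[0]
    # the latent fit also models the initial state, so agreement is
    # asymptotic in series length rather than exact
    assert latent.c == pytest.approx(collapsed.c, rel=0.05)
    assert latent.e == pytest.approx(collapsed.e, rel=0.05)


# --- labile filter -----------------------------------------------------------


def _fit(p: float) -> GroupRates:
    return GroupRates("g", RatePair(0.1, 1.0 / p), -1.0, 5, True, False)


def test_labile_filter_threshold_is_quarter_of_min_interval():
    kept, excluded, frac = filter_labile([_fit(7.4), _fit(7.6)], min_interval=30.0)
    assert [f.rates.persistence for f in excluded] == [pytest.approx(7.4)]
    assert [f.rates.persistence for f in kept] == [pytest.approx(7.6)]
    assert frac == pytest.approx(0.5)


def test_labile_filter_keeps_long_persistence_and_counts_fraction():
    fits = [_fit(p) for p in [100.0, 200.0, 50.0]]
    kept, excluded, frac = filter_labile(fits, min_interval=30.0)
    assert excluded == [] and frac == 0.0
    mixed = [_fit(p) for p in [1.0, 2.0, 100.0, 100.0, 100.0, 100.0, 100.0, 100.0]]
    _, excl, frac = filter_labile(mixed, min_interval=30.0)
    assert len(excl) == 2 and frac == pytest.approx(0.25)


def test_labile_filter_empty_input():
    kept, excluded, frac = filter_labile([], min_interval=30.0)
    assert kept == [] and excluded == [] and frac == 0.0
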