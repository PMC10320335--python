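"""Log-log trade-off regression, slope tests and coherence statistics."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from colext import (
    compare_slopes,
    exclude_taxa_and_correlate,
    loglog_tradeoff_fit,
    taxonomic_coherence,
)
from colext.tradeoff import test_slope_equals as slope_vs
from colext.tradeoff import spearman


def test_exact_tradeoff_points_give_slope_minus_one():
    c = np.logspace(-2, 1, 50)
    fit = loglog_tradeoff_fit(c, 2.0 / c)
    assert fit.slope == pytest.approx(-1.0, abs=1e-10)
    assert fit.intercept == pytest.approx(math.log(2.0), abs=1e-10)
    assert fit.spearman_rho == pytest.approx(-1.0)
    assert fit.ci_lower <= fit.slope <= fit.ci_upper


def test_confidence_interval_covers_generating_slope():
    rng = np.random.default_rng(17)
    c = np.exp(rng.uniform(-4, 0, 200))
    p = 5.0 * c**-0.7 * np.exp(rng.normal(0, 0.3, 200))
    fit = loglog_tradeoff_fit(c, p)
    assert fit.ci_lower < -0.7 < fit.ci_upper


def test_slope_invariant_to_time_unit_rescaling():
    rng = np.random.default_rng(4)
    c = np.exp(rng.uniform(-4, 0, 80))
    p = 3.0 / c * np.exp(rng.normal(0, 0.2, 80))
    daily = loglog_tradeoff_fit(c, p)
    monthly = loglog_tradeoff_fit(c * 30.0, p / 30.0)
    assert monthly.slope == pytest.approx(daily.slope, abs=1e-10)
    # intercept shifts by (1 + slope) log 30 under the unit change
    assert monthly.intercept == pytest.approx(
        daily.intercept - (1.0 + daily.slope) * math.log(30.0), abs=1e-9
    )


def test_rejects_nonpositive_rates_listing_offenders():
    with pytest.raises(ValueError, match="indices \\[1\\]"):
        loglog_tradeoff_fit([0.1, -0.2, 0.3], [1.0, 2.0, 3.0])


def test_slope_test_against_minus_one():
    c = np.logspace(-2, 1, 50)
    t, df, p = slope_vs(loglog_tradeoff_fit(c, 2.0 / c))
    assert df == 48
    assert abs(t) < 1e-6 and p > 0.999
    # noiseless slope -2 alternative: rejected at any conventional level
    t2, _, p2 = slope_vs(loglog_tradeoff_fit(c, 2.0 / c**2))
    assert p2 < 1e-12
    # testing against the fitted slope itself is the identity case
    rng = np.random.default_rng(3)
    noisy = loglog_tradeoff_fit(c, 2.0 / c * np.exp(rng.normal(0, 0.2, 50)))
    t3, _, p3 = slope_vs(noisy, value=noisy.slope)
    assert t3 == pytest.approx(0.0, abs=1e-12) and p3 == pytest.approx(1.0)


def test_degenerate_collinear_input_flags_exact_comparison():
    c = np.logspace(-2, 1, 50)
    fit = loglog_tradeoff_fit(c, 2.0 / c)
    if fit.slope_se == 0.0:
        t, _, p = slope_vs(fit, value=fit.slope)
        assert (t, p) == (0.0, 1.0)


def test_compare_slopes_on_identical_data_is_null():
    rng = np.random.default_rng(9)
    c = np.exp(rng.uniform(-3, 0, 40))
    p = 2.0 / c * np.exp(rng.normal(0, 0.2, 40))
    fit = loglog_tradeoff_fit(c, p, "core")
    comp = compare_slopes(fit, loglog_tradeoff_fit(c, p, "satellite"))
    assert comp.t == pytest.approx(0.0, abs=1e-8)
    assert comp.p == pytest.approx(1.0, abs=1e-6)
    assert comp.df == 2 * 40 - 4


def test_compare_slopes_power_against_distinct_slopes():
    rejections = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        c1 = np.exp(rng.uniform(-4, 0, 100))
        c2 = np.exp(rng.uniform(-4, 0, 100))
        fa = loglog_tradeoff_fit(c1, 2.0 / c1 * np.exp(rng.normal(0, 0.3, 100)), "a")
        fb = loglog_tradeoff_fit(c2, 2.0 * c2**-0.3 * np.exp(rng.normal(0, 0.3, 100)), "b")
        comp = compare_slopes(fa, fb)
        assert np.sign(comp.t) == np.sign(fa.slope - fb.slope)
        if comp.p < 0.01:
            rejections += 1
    assert rejections >= 19


def test_taxonomic_coherence_detects_clusters_and_respects_preconditions():
    rng = np.random.default_rng(12)
    centers = {"g1": (-3.0, 3.0), "g2": (-1.0, 1.0), "g3": (-2.0, 0.0)}
    c, p, g = [], [], []
    for name, (lc, lp) in centers.items():
        c += list(10.0 ** (lc + rng.normal(0, 0.05, 12)))
        p += list(10.0 ** (lp + rng.normal(0, 0.05, 12)))
        g += [name] * 12
    h, pval = taxonomic_coherence(c, p, g)
    assert pval < 0.01
    with pytest.raises(ValueError):
        taxonomic_coherence([0.1, 0.2], [1.0, 2.0], ["x", "y"])


def test_taxonomic_coherence_null_is_calibrated():
    ps = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        c = np.exp(rng.normal(-2, 1, 40))
        p = np.exp(rng.normal(2, 1, 40))
        g = np.repeat([f"g{i}" for i in range(5)], 8)
        ps.append(taxonomic_coherence(c, p, g)[1])
    assert 0.3 < np.median(ps) < 0.7


def test_exclusion_reanalysis():
    c = np.logspace(-2, 0, 30)
    p = 2.0 / c
    rng = np.random.default_rng(6)
    noise_c = np.exp(rng.uniform(-4, 0, 15))
    noise_p = np.exp(rng.uniform(-1, 3, 15))
    taxa = [f"clean{i}" for i in range(30)] + [f"noise{i}" for i in range(15)]
    call = np.concatenate([c, noise_c])
    pall = np.concatenate([p, noise_p])
    before, after, p_after = exclude_taxa_and_correlate(
        call, pall, taxa, [f"noise{i}" for i in range(15)]
    )
    assert abs(after) > abs(before)
    assert after == pytest.approx(-1.0)
    b2, a2, _ = exclude_taxa_and_correlate(call, pall, taxa, [])
    assert b2 == a2 == before
    with pytest.raises(ValueError):
        exclude_taxa_and_correlate(call, pall, taxa, taxa[:-2])


def test_exact_spearman_p_for_small_samples():
    # perfectly monotone n = 5: two of 5! = 120 pairings reach |rho| = 1
    rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(2.0 / 120.0)
    # matches a direct enumeration on an arbitrary n = 5 sample
    x = np.array([0.3, 1.2, 0.1, 2.0, 0.7])
    y = np.array([5.0, 1.0, 4.0, 2.5, 3.0])
    rho_obs = stats.spearmanr(x, y).statistic
    count = sum(
        abs(stats.spearmanr(x, np.array(y)[list(perm)]).statistic) >= abs(rho_obs) - 1e-12
        for perm in itertools.permutations(range(5))
    )
    _, p_ours = spearman(x, y)
    assert p_ours == pytest.approx(count / 120.0)


def test_rma_variant_and_welch_comparison():
    c = np.logspace(-2, 1, 50)
    exact = loglog_tradeoff_fit(c, 2.0 / c, method="rma")
    assert exact.slope == pytest.approx(-1.0, abs=1e-10)
    # symmetric noise on both axes: RMA stays at -1 while OLS attenuates
    rng = np.random.default_rng(14)
    lc_true = rng.uniform(-4, 0, 400)
    lc = lc_true + rng.normal(0, 0.5, 400)  # measurement error on the regressor
    lp = np.log(2.0) - lc_true + rng.normal(0, 0.5, 400)
    ols = loglog_tradeoff_fit(np.exp(lc), np.exp(lp))
    rma = loglog_tradeoff_fit(np.exp(lc), np.exp(lp), method="rma")
    assert abs(rma.slope + 1.0) < abs(ols.slope + 1.0)
    # Welch comparison agrees with the pooled test on identical data
    fit = loglog_tradeoff_fit(np.exp(lc), np.exp(lp), "a")
    comp = compare_slopes(fit, loglog_tradeoff_fit(np.exp(lc), np.exp(lp), "b"),
                          method="welch")
    assert comp.t == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError):
        compare_slopes(fit, fit, method="bogus")
    with pytest.raises(ValueError):
        loglog_tradeoff_fit(c, 2.0 / c, method="bogus")
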