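"""Occupancy-abundance statistics, the Chow scan, and the lognormal RAD fit."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from colext import (
    PresenceSeries,
    SiteObservations,
    chow_statistic,
    lognormal_rad_deviance,
    occupancy_abundance,
    split_core_satellite,
)


def _series_with_counts(counts: np.ndarray, taxa=None) -> PresenceSeries:
    times = np.arange(float(counts.shape[1]))
    taxa = taxa or tuple(f"t{i}" for i in range(counts.shape[0]))
    return PresenceSeries(
        taxa, {"s": SiteObservations(times, counts > 0, counts)}
    )


def test_occupancy_and_max_abundance():
    counts = np.zeros((2, 12), dtype=int)
    counts[0, :6] = [1, 2, 3, 4, 5, 6]
    counts[1, 1:3] = [3, 17]
    table = occupancy_abundance(_series_with_counts(counts))
    assert table.set_index("taxon").loc["t0", "occupancy"] == pytest.approx(0.5)
    assert table.set_index("taxon").loc["t1", "max_abundance"] == 17


def test_occupancy_abundance_invariant_to_sample_order_and_drops_absent():
    rng = np.random.default_rng(5)
    counts = rng.poisson(1.0, (6, 10))
    counts[3] = 0  # never detected
    t1 = occupancy_abundance(_series_with_counts(counts))
    perm = rng.permutation(10)
    shuffled = _series_with_counts(counts[:, perm])
    t2 = occupancy_abundance(shuffled)
    assert "t3" not in set(t1["taxon"])
    pd.testing.assert_frame_equal(t1, t2)


def test_chow_statistic_zero_on_a_single_line():
    x = np.linspace(0.0, 1.0, 30)
    y = 2.0 + 3.0 * x
    assert chow_statistic(x, y, 15) == pytest.approx(0.0, abs=1e-12)


def test_chow_statistic_matches_hand_computed_rss():
    rng = np.random.default_rng(2)
    x = np.sort(rng.uniform(0, 1, 20))
    y = x + rng.normal(0, 0.3, 20)
    k = 9

    def rss(xs, ys):
        beta = np.polyfit(xs, ys, 1)
        return float(((ys - np.polyval(beta, xs)) ** 2).sum())

    num = (rss(x, y) - rss(x[:k], y[:k]) - rss(x[k:], y[k:])) / 2
    den = (rss(x[:k], y[:k]) + rss(x[k:], y[k:])) / (20 - 4)
    assert chow_statistic(x, y, k) == pytest.approx(num / den, rel=1e-9)


def test_chow_scan_peaks_at_true_break_for_noiseless_segments():
    x = np.linspace(0.0, 1.0, 40)
    y = np.where(x < 0.5, 0.2 + x, 1.4 - 1.5 * (x - 0.5))
    f = [chow_statistic(x, y, k) for k in range(4, 37)]
    # both segments fit exactly only at the true break
    assert 4 + int(np.argmax(f)) == 20
    assert np.isinf(f[16])


def test_split_recovers_generated_regimes(two_regime):
    table, truth = two_regime
    scan = split_core_satellite(table)
    assert scan.significant
    assert scan.occupancy_threshold == pytest.approx(0.5, abs=0.05)
    agreement = (scan.labels.loc[truth.index] == truth).mean()
    assert agreement >= 0.95
    assert (
        table["occupancy"].min()
        < scan.occupancy_threshold
        < table["occupancy"].max()
    )


def test_split_is_deterministic(two_regime):
    table, _ = two_regime
    a = split_core_satellite(table)
    b = split_core_satellite(table.sample(frac=1.0, random_state=1))
    assert a.occupancy_threshold == b.occupancy_threshold
    pd.testing.assert_series_equal(a.labels.sort_index(), b.labels.sort_index())


def test_single_line_data_flags_no_significant_break():
    rng = np.random.default_rng(8)
    occ = np.sort(rng.uniform(0.05, 0.95, 60))
    table = pd.DataFrame(
        {
            "taxon": [f"t{i:03d}" for i in range(60)],
            "occupancy": occ,
            "log10_max_abundance": 1.0 + 2.0 * occ,
        }
    )
    scan = split_core_satellite(table)
    assert not scan.significant
    assert scan.occupancy_threshold is None
    with pytest.raises(ValueError):
        scan.labels


def test_tied_maxima_resolve_to_the_lowest_occupancy_candidate():
    # mirror-symmetric configuration: F(i) = F(n - i) exactly
    occ = np.round(np.linspace(0.1, 0.9, 24), 6)
    y = np.where((occ > 0.35) & (occ < 0.65), 1.0, 0.0)
    table = pd.DataFrame(
        {"taxon": [f"t{i:02d}" for i in range(24)], "occupancy": occ,
         "log10_max_abundance": y}
    )
    scan = split_core_satellite(table)
    f = scan.f_statistics
    ties = scan.candidates[f == np.nanmax(f)]
    assert scan.significant
    assert scan.break_index == ties.min()


def test_split_preconditions():
    small = pd.DataFrame(
        {"taxon": list("abcde"), "occupancy": np.linspace(0.1, 0.9, 5),
         "log10_max_abundance": np.ones(5)}
    )
    with pytest.raises(ValueError):
        split_core_satellite(small)
    const = pd.DataFrame(
        {"taxon": [f"t{i}" for i in range(12)], "occupancy": np.full(12, 0.4),
         "log10_max_abundance": np.arange(12.0)}
    )
    with pytest.raises(ValueError):
        split_core_satellite(const)


# --- lognormal rank-abundance fit -------------------------------------------


def _lognormal_abundances(a=6.0, b=-1.2, s=60):
    from scipy.stats import norm

    z = norm.ppf((np.arange(1, s + 1) - 0.5) / s)
    return np.round(np.exp(a + b * z))


def test_lognormal_rad_self_consistency():
    ab = _lognormal_abundances()
    fit = lognormal_rad_deviance(ab)
    assert fit.deviance / fit.n_taxa < 0.01
    assert np.all(np.diff(fit.fitted) < 0)  # strictly decreasing in rank
    assert fit.scale < 0


def test_lognormal_rad_scaling_sanity():
    ab = _lognormal_abundances()
    f1 = lognormal_rad_deviance(ab)
    f2 = lognormal_rad_deviance(ab * 10)
    assert f2.intercept > f1.intercept
    assert np.sign(f2.scale) == np.sign(f1.scale)
    assert f2.deviance >= 0


def test_lognormal_rad_requires_five_taxa():
    with pytest.raises(ValueError):
        lognormal_rad_deviance([5, 4, 3, 2])


def test_lognormal_rad_matches_vegan(tmp_path):
    """Independent oracle: R vegan's rad.lognormal on the same abundances."""
    ab = np.sort(_lognormal_abundances(5.0, -1.0, 40) + 1)[::-1]
    csv = tmp_path / "ab.csv"
    pd.DataFrame({"x": ab.astype(int)}).to_csv(csv, index=False)
    script = (
        f"suppressMessages(library(vegan));"
        f"x <- read.csv('{csv}')$x;"
        f"cat(deviance(rad.lognormal(x)))"
    )
    proc = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert proc.returncode == 0, proc.stderr
    vegan_deviance = float(proc.stdout.strip().split()[-1])
    ours = lognormal_rad_deviance(ab).deviance
    assert ours == pytest.approx(vegan_deviance, rel=1e-5)
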