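"""Reference simulation studies exercising the full pipeline.

Two end-to-end designs, both desk-scale:

* the *equalized recovery* study: a fitness-equalized community (fixed
  k, colonization spread over two decades) is simulated, per-taxon rates
  are re-estimated from the presence-absence series, labile and boundary
  fits are dropped, and the log-log persistence-colonization slope is
  fitted, pooled over seeds.  Under perfect estimation the slope is the
  trade-off exponent -1.
* the *SAD-only null* study: a static community observed through finite
  multinomial sequencing depth, so every apparent colonization and
  extinction is a sampling artefact; the same per-taxon estimation and
  regression are applied per seed.

The defaults are the study conditions used throughout: 300 taxa, k = 2,
c log-uniform in [0.02, 2] per month, 24 monthly samples.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .estimation import GroupRates, filter_labile, fit_rates
from .series import PresenceSeries
from .synthetic import SyntheticSpec, simulate_equalized, simulate_sad_detection
from .tradeoff import TradeoffFit, loglog_tradeoff_fit

__all__ = ["fit_per_taxon", "equalized_slope_study", "sad_null_slopes"]

MONTHLY_24 = tuple(float(t) for t in range(24))


def fit_per_taxon(series: PresenceSeries) -> list[GroupRates]:
    """One rate pair per taxon, skipping taxa never observed present."""
    observed = [
        t
        for i, t in enumerate(series.taxa)
        if any(obs.detections[i].any() for obs in series.sites.values())
    ]
    return fit_rates(series.subset(observed), {t: t for t in observed})


def _usable(fits: Sequence[GroupRates], min_interval: float | None):
    if min_interval is not None:
        fits = filter_labile(fits, min_interval).kept
    return [f for f in fits if not f.boundary and f.e > 0]


def equalized_slope_study(
    seeds: Iterable[int],
    n_taxa: int = 300,
    times: tuple[float, ...] = MONTHLY_24,
    k: float = 2.0,
    c_range: tuple[float, float] = (0.02, 2.0),
) -> TradeoffFit:
    """Pooled log-log slope of estimated (c, p) for equalized communities.

    For each seed: simulate, estimate per taxon, apply the
    quarter-of-minimum-interval persistence filter, drop boundary fits;
    the OLS of log persistence on log colonization pools the kept points
    of every seed.
    """
    min_interval = float(np.diff(times).min())
    cs: list[float] = []
    ps: list[float] = []
    for seed in seeds:
        spec = SyntheticSpec(
            n_taxa=n_taxa, times=times, k=k, c_range=c_range, seed=int(seed)
        )
        series, _ = simulate_equalized(spec)
        for f in _usable(fit_per_taxon(series), min_interval):
            cs.append(f.c)
            ps.append(f.rates.persistence)
    return loglog_tradeoff_fit(cs, ps, component="equalized")


def sad_null_slopes(
    seeds: Iterable[int],
    n_taxa: int = 300,
    times: tuple[float, ...] = MONTHLY_24,
    depth: int = 2000,
) -> list[TradeoffFit]:
    """Per-seed log-log fits under the SAD-only (no dynamics) null.

    Apparent rates are pure detection artefacts.  The labile filter is
    not applied here: apparent extinction rates under the null are so
    large that it would empty the point set; the null regression is over
    all non-boundary per-taxon fits.
    """
    out = []
    for seed in seeds:
        spec = SyntheticSpec(
            n_taxa=n_taxa, times=times, dynamics=False, depth=depth, seed=int(seed)
        )
        series, _ = simulate_sad_detection(spec)
        usable = _usable(fit_per_taxon(series), None)
        fit = loglog_tradeoff_fit(
            [f.c for f in usable],
            [f.rates.persistence for f in usable],
            component=f"null_seed_{seed}",
        )
        out.append(fit)
    return out
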