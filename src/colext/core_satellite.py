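"""Core/satellite partition of a community via a structural break.

Core taxa are abundant and persistent; satellite taxa occasional and
rare.  Because sequence pipelines discard singletons, the classical
route (lognormal core vs log-series satellite abundance distributions)
is not available, so the split is located instead as a structural break
in the relation between occupancy and log10 maximum abundance: a Chow
F statistic is scanned over intermediate breakpoints of the
occupancy-ordered points, the break with the largest F is kept, and the
occupancy threshold is the mean occupancy of the two points flanking
that break.  Taxa strictly above the threshold are core.

The core's rank-abundance curve is then summarized by a lognormal fit
(Poisson GLM of abundance on normal quantiles of scaled ranks), whose
residual deviance measures how closely the core follows a lognormal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .series import PresenceSeries

__all__ = [
    "occupancy_abundance",
    "chow_statistic",
    "ChowScan",
    "split_core_satellite",
    "LognormalRadFit",
    "lognormal_rad_deviance",
]


def occupancy_abundance(series: PresenceSeries) -> pd.DataFrame:
    """Per-taxon occupancy and maximum abundance, pooled over sites.

    Occupancy is the fraction of samples (site x time x replicate) in
    which the taxon was detected; max_abundance is its largest observed
    count.  Taxa never detected are dropped (with no counts there is
    nothing to place on the abundance axis).
    """
    det_cols = []
    count_cols = []
    for name, obs in series.sites.items():
        if obs.counts is None:
            raise ValueError(f"site {name!r} has no counts; occupancy-abundance needs them")
        det_cols.append(obs.detections.reshape(obs.n_taxa, -1))
        count_cols.append(obs.counts.reshape(obs.n_taxa, -1))
    det = np.concatenate(det_cols, axis=1)
    counts = np.concatenate(count_cols, axis=1)
    occupancy = det.mean(axis=1)
    max_abundance = counts.max(axis=1)
    table = pd.DataFrame(
        {
            "taxon": series.taxa,
            "occupancy": occupancy,
            "max_abundance": max_abundance,
        }
    )
    table = table[table["occupancy"] > 0].reset_index(drop=True)
    table["log10_max_abundance"] = np.log10(table["max_abundance"])
    return table


def _rss(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of a simple linear regression."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise ValueError("degenerate segment: constant predictor")
    return float(yc @ yc - (xc @ yc) ** 2 / sxx)


def chow_statistic(x: np.ndarray, y: np.ndarray, break_index: int) -> float:
    """Chow F statistic for a single regression break at ``break_index``.

    Points ``[:break_index]`` form the left segment, ``[break_index:]``
    the right; each side needs >= 3 points.  F compares the pooled
    single-line fit against the two-line fit:

        F = ((RSS_pooled - RSS1 - RSS2) / 2) / ((RSS1 + RSS2) / (n - 4))
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if not 3 <= break_index <= n - 3:
        raise ValueError("both segments need at least 3 points")
    if np.any(np.diff(x) < 0):
        raise ValueError("x must be sorted ascending")
    rss_pooled = _rss(x, y)
    rss1 = _rss(x[:break_index], y[:break_index])
    rss2 = _rss(x[break_index:], y[break_index:])
    yc = y - y.mean()
    tol = 1e-12 * max(float(yc @ yc), 1.0)  # exact fits leave rounding residue
    num = rss_pooled - rss1 - rss2
    denom = (rss1 + rss2) / (n - 4)
    if denom <= tol:
        return float(np.inf) if num > tol else 0.0
    return float((num / 2.0) / denom)


@dataclass(frozen=True)
class ChowScan:
    """Result of the structural-break scan over occupancy-ordered points."""

    table: pd.DataFrame  # taxon, occupancy, log10_max_abundance, (label)
    candidates: np.ndarray  # break indices scanned
    f_statistics: np.ndarray
    break_index: int | None
    f_max: float | None
    f_critical: float
    occupancy_threshold: float | None
    significant: bool

    @property
    def labels(self) -> pd.Series:
        if not self.significant:
            raise ValueError("no significant structural break: labels undefined")
        return self.table.set_index("taxon")["label"]


def split_core_satellite(
    table: pd.DataFrame,
    trim: float = 0.10,
    alpha: float = 0.05,
    order_by: str = "occupancy",
    response: str = "log10_max_abundance",
    threshold_from: str = "observed",
) -> ChowScan:
    """Locate the occupancy threshold separating core from satellite taxa.

    Points are ordered by ``order_by`` (default occupancy; ties broken
    by taxon id) and the Chow F statistic of ``response`` on that
    variable is scanned over every intermediate breakpoint, trimming
    ``trim`` of the points (min 3) at each end.  The argmax break (ties
    -> lowest ordering value) sets the threshold: the mean occupancy of
    the last left-segment point and the first right-segment point.  Core
    taxa are those with occupancy strictly above the threshold.  If no
    candidate F exceeds the pointwise 0.05 critical value of F(2, n-4)
    the scan is returned flagged non-significant, with no labels.

    The opposite orientation (``order_by="log10_max_abundance"``,
    ``response="occupancy"``) is available for sensitivity analysis;
    there ``threshold_from="fitted"`` replaces the flanking points'
    observed occupancies with the two regression lines' fitted values.
    """
    if threshold_from not in ("observed", "fitted"):
        raise ValueError("threshold_from must be 'observed' or 'fitted'")
    if len(table) < 10:
        raise ValueError("need at least 10 taxa to scan for a structural break")
    if table["occupancy"].nunique() < 2:
        raise ValueError("all occupancies identical: no break to find")
    ordered = table.sort_values([order_by, "taxon"], kind="stable").reset_index(
        drop=True
    )
    x = ordered[order_by].to_numpy(dtype=float)
    y = ordered[response].to_numpy(dtype=float)
    n = x.size
    margin = max(3, int(np.ceil(trim * n)))
    candidates = np.arange(margin, n - margin + 1)
    f_stats = np.full(candidates.shape, np.nan)
    for j, idx in enumerate(candidates):
        try:
            f_stats[j] = chow_statistic(x, y, int(idx))
        except ValueError:  # degenerate segment (constant occupancy run)
            continue
    f_critical = float(stats.f.ppf(1.0 - alpha, 2, n - 4))
    valid = ~np.isnan(f_stats)
    if not valid.any() or np.nanmax(f_stats) <= f_critical:
        return ChowScan(
            table=ordered,
            candidates=candidates,
            f_statistics=f_stats,
            break_index=None,
            f_max=float(np.nanmax(f_stats)) if valid.any() else None,
            f_critical=f_critical,
            occupancy_threshold=None,
            significant=False,
        )
    f_max = float(np.nanmax(f_stats))
    best = int(candidates[valid][np.argmax(f_stats[valid])])  # first max = lowest order
    occ = ordered["occupancy"].to_numpy(dtype=float)
    if threshold_from == "fitted" and response == "occupancy":
        left = np.polyval(np.polyfit(x[:best], y[:best], 1), x[best - 1])
        right = np.polyval(np.polyfit(x[best:], y[best:], 1), x[best])
        threshold = float((left + right) / 2.0)
    else:
        threshold = float((occ[best - 1] + occ[best]) / 2.0)
    ordered = ordered.assign(
        label=np.where(ordered["occupancy"] > threshold, "core", "satellite")
    )
    return ChowScan(
        table=ordered,
        candidates=candidates,
        f_statistics=f_stats,
        break_index=best,
        f_max=f_max,
        f_critical=f_critical,
        occupancy_threshold=threshold,
        significant=True,
    )


@dataclass(frozen=True)
class LognormalRadFit:
    """Lognormal rank-abundance fit: abundance ~ exp(a + b z_rank)."""

    intercept: float  # a (log scale)
    scale: float  # b; negative when abundance falls with rank
    deviance: float
    n_taxa: int
    fitted: np.ndarray  # expected abundance by descending rank


def lognormal_rad_deviance(abundances) -> LognormalRadFit:
    """Fit a lognormal rank-abundance model and report residual deviance.

    Abundances are ranked descending; rank r of S maps to the standard
    normal quantile z_r = Phi^-1((r - 0.5) / S), and expected abundance
    exp(a + b z_r) is fitted by a Poisson GLM with log link.  A small
    residual deviance indicates the abundances follow a lognormal
    rank-abundance curve closely.
    """
    a = np.sort(np.asarray(abundances, dtype=float))[::-1]
    if a.size < 5:
        raise ValueError("need at least 5 taxa for a rank-abundance fit")
    if np.any(a < 1):
        raise ValueError("abundances must be >= 1")
    s = a.size
    z = stats.norm.ppf((np.arange(1, s + 1) - 0.5) / s)
    model = sm.GLM(a, sm.add_constant(z), family=sm.families.Poisson())
    res = model.fit()
    return LognormalRadFit(
        intercept=float(res.params[0]),
        scale=float(res.params[1]),
        deviance=float(res.deviance),
        n_taxa=int(s),
        fitted=np.asarray(res.fittedvalues),
    )
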