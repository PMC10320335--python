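"""Quantifying the colonization-persistence trade-off.

Under fitness equalization the colonization-to-extinction ratio k = c e
is constant across taxa, so persistence p = 1/e satisfies p = k / c and
log p regressed on log c has slope -1 (intercept K = log k).  This
module fits that regression, tests the slope against -1, compares core
vs satellite slopes with a pooled interaction t-test, and checks
taxonomic coherence of the (c, p) cloud with a Kruskal-Wallis test on
intra- vs inter-group pairwise distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.spatial.distance import pdist

__all__ = [
    "TradeoffFit",
    "SlopeComparison",
    "spearman",
    "loglog_tradeoff_fit",
    "test_slope_equals",
    "compare_slopes",
    "taxonomic_coherence",
    "exclude_taxa_and_correlate",
]


@dataclass(frozen=True)
class TradeoffFit:
    """OLS fit of log persistence on log colonization for one component."""

    component: str
    n: int
    slope: float
    intercept: float
    slope_se: float
    ci_lower: float
    ci_upper: float
    spearman_rho: float
    spearman_p: float
    log_c: np.ndarray
    log_p: np.ndarray

    @property
    def k_hat(self) -> float:
        """exp(intercept): the fitted fitness constant when slope = -1."""
        return math.exp(self.intercept)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho with an exact permutation p-value for n < 10.

    For n >= 10 the asymptotic t approximation is used; below that the
    p-value is the exact two-sided tail over all n! pairings.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rho, p_asym = stats.spearmanr(x, y)
    if n >= 10:
        return float(rho), float(p_asym)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    norm = float(np.linalg.norm(rxc) * np.linalg.norm(ry - ry.mean()))
    if norm == 0.0:
        return float(rho), 1.0
    perms = np.array(list(itertools.permutations(range(n))))
    # permutation preserves the rank mean, so Pearson-of-ranks reduces to
    # a dot product with the centred fixed ranks
    rho_null = (ry[perms] @ rxc) / norm
    p_exact = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    return float(rho), p_exact


def _check_positive(c, p):
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    bad = np.flatnonzero((c <= 0) | (p <= 0))
    if bad.size:
        raise ValueError(f"non-positive rates at indices {bad.tolist()}")
    return c, p


def loglog_tradeoff_fit(
    c, p, component: str = "all", method: str = "ols"
) -> TradeoffFit:
    """Regression of log p on log c with t-based 95% CI and Spearman rho.

    ``method`` is ``"ols"`` (default) or ``"rma"`` (reduced major axis,
    a sensitivity option since both rates are estimates; the RMA slope
    is sign(r)·sd(log p)/sd(log c) with the OLS standard error).
    Natural logarithms are used internally; the slope is invariant to
    the base and to rescaling the time unit of both rates.
    """
    if method not in ("ols", "rma"):
        raise ValueError("method must be 'ols' or 'rma'")
    c, p = _check_positive(c, p)
    n = c.size
    if n < 3:
        raise ValueError("need at least 3 (c, p) points")
    log_c = np.log(c)
    log_p = np.log(p)
    res = sm.OLS(log_p, sm.add_constant(log_c)).fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    intercept = float(res.params[0])
    if method == "rma":
        r = np.corrcoef(log_c, log_p)[0, 1]
        slope = float(np.sign(r) * log_p.std(ddof=1) / log_c.std(ddof=1))
        intercept = float(log_p.mean() - slope * log_c.mean())
    tcrit = stats.t.ppf(0.975, n - 2)
    rho, p_rho = spearman(c, p)
    return TradeoffFit(
        component=component,
        n=int(n),
        slope=slope,
        intercept=intercept,
        slope_se=se,
        ci_lower=slope - tcrit * se,
        ci_upper=slope + tcrit * se,
        spearman_rho=rho,
        spearman_p=p_rho,
        log_c=log_c,
        log_p=log_p,
    )


def test_slope_equals(fit: TradeoffFit, value: float = -1.0) -> tuple[float, int, float]:
    """Two-sided t-test of the fitted slope against a reference value.

    Returns (t, df, p) with t = (slope - value) / SE and df = n - 2.
    A zero SE (perfectly collinear points) degenerates to p = 1 when the
    slope equals the value exactly and p = 0 otherwise.
    """
    if fit.n < 4:
        raise ValueError("slope test needs n >= 4")
    df = fit.n - 2
    tol = 1e-9 * max(abs(fit.slope), 1.0)
    if fit.slope_se <= tol:
        # perfectly collinear points: the comparison is exact
        if abs(fit.slope - value) <= tol:
            return 0.0, df, 1.0
        return math.copysign(math.inf, fit.slope - value), df, 0.0
    t = (fit.slope - value) / fit.slope_se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


@dataclass(frozen=True)
class SlopeComparison:
    """Pooled interaction t-test of slope equality between two components."""

    t: float
    df: int
    p: float
    fit_a: TradeoffFit
    fit_b: TradeoffFit


def compare_slopes(
    fit_a: TradeoffFit, fit_b: TradeoffFit, method: str = "pooled"
) -> SlopeComparison:
    """Test slope_a = slope_b between two components.

    ``"pooled"`` (default) fits log p ~ log c * component on the pooled
    points; the interaction coefficient estimates slope_a - slope_b and
    its t statistic (df = n_a + n_b - 4) tests equality.  ``"welch"``
    instead uses the two fits' separate standard errors with
    Welch-Satterthwaite degrees of freedom.
    """
    if fit_a.n < 4 or fit_b.n < 4:
        raise ValueError("both components need n >= 4")
    if method == "pooled":
        x = np.concatenate([fit_a.log_c, fit_b.log_c])
        y = np.concatenate([fit_a.log_p, fit_b.log_p])
        g = np.concatenate([np.ones(fit_a.n), np.zeros(fit_b.n)])
        design = sm.add_constant(np.column_stack([x, g, x * g]))
        res = sm.OLS(y, design).fit()
        t = float(res.tvalues[3])
        df = fit_a.n + fit_b.n - 4
    elif method == "welch":
        va, vb = fit_a.slope_se**2, fit_b.slope_se**2
        t = float((fit_a.slope - fit_b.slope) / math.sqrt(va + vb))
        df = int(
            (va + vb) ** 2 / (va**2 / (fit_a.n - 2) + vb**2 / (fit_b.n - 2))
        )
    else:
        raise ValueError("method must be 'pooled' or 'welch'")
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return SlopeComparison(t=t, df=df, p=p, fit_a=fit_a, fit_b=fit_b)


def taxonomic_coherence(
    c,
    p,
    groups: Sequence[str],
) -> tuple[float, float]:
    """Kruskal-Wallis test of intra- vs inter-group (log c, log p) distances.

    Points (one per low-rank taxon, e.g. genus) live in
    (log10 c, log10 p) space; Euclidean pairwise distances are classed
    intra (same higher-rank group, e.g. phylum) or inter, and the two
    distance samples are compared.  A small p indicates that members of
    the same higher taxon sit closer together than members of different
    ones: taxonomic coherence of the colonization-persistence strategy.
    """
    c, p = _check_positive(c, p)
    groups = np.asarray(groups)
    if groups.size != c.size:
        raise ValueError("one group label per point required")
    labels, counts = np.unique(groups, return_counts=True)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 higher-rank groups with >= 2 members each")
    pts = np.column_stack([np.log10(c), np.log10(p)])
    dists = pdist(pts)
    ii, jj = np.triu_indices(c.size, k=1)
    intra = dists[groups[ii] == groups[jj]]
    inter = dists[groups[ii] != groups[jj]]
    if intra.size == 0 or inter.size == 0:
        raise ValueError("need both intra- and inter-group pairs")
    h, pval = stats.kruskal(intra, inter)
    return float(h), float(pval)


def exclude_taxa_and_correlate(
    c,
    p,
    taxa: Sequence[str],
    exclude: Sequence[str] = (),
) -> tuple[float, float, float]:
    """Spearman rho of (c, p) before and after excluding listed taxa.

    Supports sensitivity reanalyses such as dropping classes that harbour
    spore-forming taxa.  Returns (rho_before, rho_after, p_after).
    """
    c, p = _check_positive(c, p)
    taxa = np.asarray(taxa)
    if taxa.size != c.size:
        raise ValueError("one taxon label per point required")
    rho_before, _ = spearman(c, p)
    keep = ~np.isin(taxa, np.asarray(list(exclude)))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points remain after exclusion")
    rho_after, p_after = spearman(c[keep], p[keep])
    return float(rho_before), float(rho_after), float(p_after)
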