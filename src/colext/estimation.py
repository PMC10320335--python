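"""Maximum-likelihood estimation of colonization/extinction rates.

Rates are estimated from irregularly sampled presence-absence series by
maximizing the product, over consecutive sample pairs, of the two-state
chain's transition probabilities evaluated at each pair's own interval
length.  The first observation of every series is conditioned on, not
modelled, so no stationarity assumption enters the fit.  A group (taxon,
guild, or partition block) is fitted jointly: all member taxa and all
sites contribute transitions to one likelihood.

An imperfect-detectability variant treats presence as a latent two-state
chain observed through per-replicate Bernoulli detections (probability
``d`` given presence, no false positives) and evaluates the likelihood
with the forward algorithm.

Observed rates for microbial data are *effective* rates: a detection
failure after a detection success counts as an extinction whether or not
the taxon truly left, and vice versa for colonizations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import binom

from .markov import RatePair, transition_matrix
from .series import PresenceSeries

__all__ = [
    "GroupRates",
    "DetectabilityFit",
    "transition_counts",
    "negative_log_likelihood",
    "fit_rates",
    "fit_rates_detectability",
    "filter_labile",
    "LabileFilterResult",
]

RATE_BOUNDS = (1e-6, 1e3)
#: fixed multi-start grid (per-time-unit rates), one axis each for c and e
START_GRID = (1e-3, 1e-1, 1e1)
_XTOL = 1e-8


@dataclass(frozen=True)
class GroupRates:
    """MLE rate pair for one group, with fit diagnostics.

    ``boundary`` is set when a direction of transition was never observed
    or the estimate is pinned at a rate bound; such estimates are not
    interior maxima and should be treated with caution downstream.
    """

    group: str
    rates: RatePair
    log_likelihood: float
    n_transitions: int
    converged: bool
    boundary: bool

    @property
    def c(self) -> float:
        return self.rates.c

    @property
    def e(self) -> float:
        return self.rates.e

    @property
    def persistence(self) -> float:
        return self.rates.persistence


@dataclass(frozen=True)
class DetectabilityFit(GroupRates):
    """GroupRates plus a per-replicate detection probability d in [0, 1]."""

    d: float = 1.0


def transition_counts(
    series: PresenceSeries, taxa: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate observed transitions over taxa, sites and sample pairs.

    Replicates are collapsed (detected iff any replicate detected).
    Returns ``(dts, counts)`` where ``dts`` (D,) are the unique interval
    lengths and ``counts`` (D, 2, 2) the number of observed s -> s'
    transitions over each interval length.
    """
    idx = None if taxa is None else series.taxon_index(taxa)
    all_dts: list[np.ndarray] = []
    all_codes: list[np.ndarray] = []
    for obs in series.sites.values():
        if obs.n_times < 2:
            continue
        det = obs.detections.any(axis=2)
        if idx is not None:
            det = det[idx]
        frm = det[:, :-1].astype(np.int8)
        to = det[:, 1:].astype(np.int8)
        code = (2 * frm + to).ravel()
        dts = np.broadcast_to(np.diff(obs.times), frm.shape).ravel()
        all_dts.append(dts)
        all_codes.append(code)
    if not all_dts:
        return np.empty(0), np.zeros((0, 2, 2))
    dts = np.concatenate(all_dts)
    codes = np.concatenate(all_codes)
    uniq, inv = np.unique(dts, return_inverse=True)
    counts = np.zeros((uniq.size, 4))
    np.add.at(counts, (inv, codes), 1.0)
    return uniq, counts.reshape(-1, 2, 2)


def _nll_from_counts(c: float, e: float, dts: np.ndarray, counts: np.ndarray) -> float:
    """-log likelihood from aggregated transition counts.

    Returns +inf (never raises) when a zero-probability transition has
    positive count, e.g. an observed colonization under c = 0.
    """
    total = c + e
    nll = 0.0
    flat = counts.reshape(-1, 4)
    for dt, (n00, n01, n10, n11) in zip(dts, flat):
        if total <= 0.0:
            # frozen chain: only self-transitions possible
            if n01 or n10:
                return math.inf
            continue
        pi = c / total
        mix = -math.expm1(-total * dt)  # 1 - exp(-(c+e) dt)
        p01 = pi * mix
        p10 = (1.0 - pi) * mix
        for n, p in ((n00, 1.0 - p01), (n01, p01), (n10, p10), (n11, 1.0 - p10)):
            if n:
                if p <= 0.0:
                    return math.inf
                nll -= n * math.log(p)
    return nll


def negative_log_likelihood(
    rates: RatePair, series: PresenceSeries, taxa: Sequence[str] | None = None
) -> float:
    """-log likelihood of the observed transitions under a rate pair.

    Sums over taxa, sites, and consecutive sample pairs; each pair uses
    its own interval length.  First observations are conditioned on.
    """
    dts, counts = transition_counts(series, taxa)
    if counts.sum() == 0:
        raise ValueError("no observed transitions: need >= 2 time points per site")
    return _nll_from_counts(rates.c, rates.e, dts, counts)


def _maximize(objective, starts, n_params: int):
    """Deterministic multi-start Nelder-Mead; returns (best_x, best_f, success)."""
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="Nelder-Mead",
            options={"xatol": _XTOL, "fatol": _XTOL, "maxiter": 400 * n_params},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x, best.fun, bool(best.success)


def _fit_group_counts(group: str, dts: np.ndarray, counts: np.ndarray) -> GroupRates:
    flat = counts.sum(axis=0).ravel()  # n00, n01, n10, n11 pooled over dt
    n_transitions = int(flat.sum())
    if n_transitions == 0:
        raise ValueError(f"group {group!r}: no observed transitions")
    if flat[2] + flat[3] == 0 and flat[1] == 0:
        raise ValueError(f"group {group!r}: taxa never observed present")
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])

    def objective(theta: np.ndarray) -> float:
        t = np.clip(theta, lo, hi)
        return _nll_from_counts(math.exp(t[0]), math.exp(t[1]), dts, counts)

    starts = [
        (math.log(c0), math.log(e0)) for c0 in START_GRID for e0 in START_GRID
    ]
    x, fval, success = _maximize(objective, starts, 2)
    c, e = np.exp(np.clip(x, lo, hi))
    no_colonization = flat[1] == 0
    no_extinction = flat[2] == 0
    pinned = bool(
        min(abs(math.log(c) - lo), abs(math.log(c) - hi)) < 1e-3
        or min(abs(math.log(e) - lo), abs(math.log(e) - hi)) < 1e-3
    )
    return GroupRates(
        group=group,
        rates=RatePair(float(c), float(e)),
        log_likelihood=-fval,
        n_transitions=n_transitions,
        converged=success,
        boundary=bool(no_colonization or no_extinction or pinned),
    )


def _groups(series: PresenceSeries, grouping: Mapping[str, str] | None):
    if grouping is None:
        return {"all": list(series.taxa)}
    members: dict[str, list[str]] = {}
    for taxon in series.taxa:
        if taxon in grouping:
            members.setdefault(str(grouping[taxon]), []).append(taxon)
    if not members:
        raise ValueError("grouping assigns no taxon present in the series")
    return {g: members[g] for g in sorted(members)}


def fit_rates(
    series: PresenceSeries, grouping: Mapping[str, str] | None = None
) -> list[GroupRates]:
    """MLE of (c, e) per group from presence-absence transitions.

    ``grouping`` maps taxon id -> group label; taxa sharing a label are
    fitted jointly (their transitions pool into one likelihood), and taxa
    absent from the map are ignored.  ``None`` fits the whole community
    as a single group ``"all"`` (the species-equivalence assumption).
    Deterministic given the data: optimization restarts from a fixed
    3x3 log-grid of rate pairs.
    """
    out = []
    for group, members in _groups(series, grouping).items():
        dts, counts = transition_counts(series, members)
        out.append(_fit_group_counts(group, dts, counts))
    return out


def _forward_nll_site(
    c: float, e: float, d: float, times: np.ndarray, y: np.ndarray, r: int
) -> float:
    """-log likelihood of detection-count series under latent dynamics.

    ``y`` (S, T) holds the number of detecting replicates out of ``r``.
    Latent presence follows the (c, e) chain started at stationarity;
    each replicate detects a present taxon independently with
    probability d and an absent taxon never.
    """
    total = c + e
    pi = c / total
    n_taxa, n_times = y.shape
    # emission probabilities for every possible detection count 0..r
    emit_present = binom.pmf(np.arange(r + 1), r, d)
    emit_absent = np.zeros(r + 1)
    emit_absent[0] = 1.0
    alpha = np.tile([1.0 - pi, pi], (n_taxa, 1))
    loglik = 0.0
    dts = np.diff(times)
    for t in range(n_times):
        if t > 0:
            alpha = alpha @ transition_matrix(RatePair(c, e), dts[t - 1])
        alpha = alpha * np.column_stack([emit_absent[y[:, t]], emit_present[y[:, t]]])
        norm = alpha.sum(axis=1)
        if np.any(norm <= 0.0):
            return math.inf
        loglik += float(np.log(norm).sum())
        alpha /= norm[:, None]
    return -loglik


def fit_rates_detectability(
    series: PresenceSeries,
    grouping: Mapping[str, str] | None = None,
    fix_d: float | None = None,
) -> list[DetectabilityFit]:
    """Joint MLE of (c, e, d) under imperfect per-replicate detection.

    Requires >= 2 replicates (with a single replicate d is confounded
    with the rates; use :func:`fit_rates`).  The latent initial state is
    integrated over the stationary distribution of the candidate rates.
    ``fix_d`` fixes the detection probability instead of estimating it.
    """
    if series.n_replicates < 2:
        raise ValueError(
            "detectability fit needs >= 2 replicates per survey; "
            "with one replicate d is unidentifiable -- use fit_rates"
        )
    lo, hi = math.log(RATE_BOUNDS[0]), math.log(RATE_BOUNDS[1])
    out = []
    for group, members in _groups(series, grouping).items():
        idx = series.taxon_index(members)
        site_data = []
        n_transitions = 0
        for obs in series.sites.values():
            if obs.n_times < 2:
                continue
            y = obs.detections[idx].sum(axis=2)
            site_data.append((obs.times, y, obs.n_replicates))
            n_transitions += y.shape[0] * (y.shape[1] - 1)

        def nll(c: float, e: float, d: float) -> float:
            return sum(
                _forward_nll_site(c, e, d, times, y, r) for times, y, r in site_data
            )

        if fix_d is not None:
            if not 0.0 < fix_d <= 1.0:
                raise ValueError("fix_d must lie in (0, 1]")

            def objective(theta):
                t = np.clip(theta, lo, hi)
                return nll(math.exp(t[0]), math.exp(t[1]), fix_d)

            starts = [(math.log(c0), math.log(e0)) for c0 in START_GRID for e0 in START_GRID]
            x, fval, success = _maximize(objective, starts, 2)
            c, e = np.exp(np.clip(x[:2], lo, hi))
            d = float(fix_d)
        else:

            def objective(theta):
                t = np.clip(theta[:2], lo, hi)
                z = float(np.clip(theta[2], -12.0, 12.0))
                return nll(math.exp(t[0]), math.exp(t[1]), 1.0 / (1.0 + math.exp(-z)))

            starts = [
                (math.log(c0), math.log(e0), z0)
                for c0 in (0.05, 0.5)
                for e0 in (0.05, 0.5)
                for z0 in (0.0, 2.0)
            ]
            x, fval, success = _maximize(objective, starts, 3)
            c, e = np.exp(np.clip(x[:2], lo, hi))
            d = 1.0 / (1.0 + math.exp(-float(np.clip(x[2], -12.0, 12.0))))
        pinned = bool(
            min(abs(math.log(c) - lo), abs(math.log(c) - hi)) < 1e-3
            or min(abs(math.log(e) - lo), abs(math.log(e) - hi)) < 1e-3
        )
        out.append(
            DetectabilityFit(
                group=group,
                rates=RatePair(float(c), float(e)),
                log_likelihood=-fval,
                n_transitions=n_transitions,
                converged=success,
                boundary=pinned,
                d=d,
            )
        )
    return out


class LabileFilterResult(NamedTuple):
    kept: list[GroupRates]
    excluded: list[GroupRates]
    excluded_fraction: float


def filter_labile(
    fits: Sequence[GroupRates], min_interval: float
) -> LabileFilterResult:
    """Exclude fits whose persistence is under a quarter of the minimal
    inter-sample interval.

    Rate estimates for very labile taxa (in and out between consecutive
    samples) are biased, so groups with persistence 1/e below
    ``min_interval / 4`` are set aside.  Returns the kept and excluded
    lists (disjoint, exhaustive) and the excluded fraction.
    """
    if min_interval <= 0:
        raise ValueError("min_interval must be positive")
    threshold = min_interval / 4.0
    kept = [f for f in fits if f.rates.persistence >= threshold]
    excluded = [f for f in fits if f.rates.persistence < threshold]
    frac = len(excluded) / len(fits) if fits else 0.0
    return LabileFilterResult(kept, excluded, frac)
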