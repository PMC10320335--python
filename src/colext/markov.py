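"""Closed-form machinery of the two-state colonization-extinction model.

A taxon is either absent (0) or present (1) in a local community and
switches state as a continuous-time Markov chain: colonization at rate
``c`` (0 -> 1) and extinction at rate ``e`` (1 -> 0).  The occupancy
probability pi(t) obeys

    dpi/dt = c (1 - pi) - e pi,

whose stationary solution is pi* = c / (c + e) = k / (1 + k) with
k = c / e the colonization-to-extinction ratio.  ``k`` measures fitness
in these dynamics (expected colonizations per residence time), and
persistence is the expected residence time p = 1 / e.  Fitness
equalization (constant k across taxa) therefore predicts the trade-off
p = k / c, i.e. slope -1 of log p against log c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RatePair",
    "TradeoffCurve",
    "stationary_occupancy",
    "transition_matrix",
    "transition_probabilities",
    "tradeoff_persistence",
]

#: states, in matrix order
ABSENT, PRESENT = 0, 1


@dataclass(frozen=True)
class RatePair:
    """A colonization/extinction rate pair (per day).

    Derived quantities: ``k`` (dimensionless fitness ratio c/e),
    ``persistence`` (expected residence time 1/e, days) and
    ``stationary_occupancy`` (pi* = k/(1+k)).  ``k`` and ``persistence``
    require e > 0.
    """

    c: float
    e: float

    def __post_init__(self) -> None:
        if self.c < 0 or self.e < 0:
            raise ValueError(f"rates must be non-negative, got c={self.c}, e={self.e}")

    @property
    def k(self) -> float:
        if self.e <= 0:
            raise ValueError("k = c/e requires e > 0")
        return self.c / self.e

    @property
    def persistence(self) -> float:
        if self.e <= 0:
            raise ValueError("persistence = 1/e requires e > 0")
        return 1.0 / self.e

    @property
    def stationary_occupancy(self) -> float:
        return stationary_occupancy(self)


def stationary_occupancy(rates: RatePair) -> float:
    """Stationary presence probability pi* = c/(c+e) = k/(1+k).

    Raises
    ------
    ValueError
        If c = e = 0 (the chain has no dynamics; occupancy undefined).
    """
    total = rates.c + rates.e
    if total <= 0:
        raise ValueError("stationary occupancy undefined when c = e = 0")
    return rates.c / total


def transition_matrix(rates: RatePair, dt: float) -> np.ndarray:
    """Transition probabilities of the two-state chain over an interval.

    Returns the row-stochastic 2x2 matrix ``P`` with ``P[s, s']`` the
    probability of being in state ``s'`` a time ``dt`` after being in
    state ``s`` (state 0 = absent, 1 = present):

        P(0 -> 1) = pi* (1 - exp(-(c+e) dt))
        P(1 -> 1) = (c + e exp(-(c+e) dt)) / (c + e)

    ``dt = 0`` yields the identity.  Uses expm1 so that small
    ``(c+e) dt`` does not suffer catastrophic cancellation.
    """
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    if dt == 0:
        return np.eye(2)
    total = rates.c + rates.e
    if total <= 0:
        raise ValueError("transition probabilities undefined for c = e = 0, dt > 0")
    pi = rates.c / total
    # 1 - exp(-(c+e) dt), computed stably
    mix = -math.expm1(-total * dt)
    p01 = pi * mix
    p10 = (1.0 - pi) * mix
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


# Name used in the estimation/simulation layers; identical computation.
transition_probabilities = transition_matrix


@dataclass(frozen=True)
class TradeoffCurve:
    """A generic colonization-persistence trade-off p = k * c**alpha.

    ``alpha = -1`` is the fitness-equalized case: every point satisfies
    p * c = k exactly, i.e. log p = K - log c with intercept K = log k.
    """

    k: float
    alpha: float = -1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")

    @property
    def intercept(self) -> float:
        """K = log k, the intercept of the log-log trade-off line."""
        return math.log(self.k)

    def persistence(self, c):
        return tradeoff_persistence(self, c)


def tradeoff_persistence(curve: TradeoffCurve, c):
    """Persistence p = k * c**alpha on a trade-off curve (vectorized).

    Raises a ValueError on non-positive colonization rates.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= 0):
        raise ValueError("colonization rate must be positive on the trade-off curve")
    out = curve.k * c_arr**curve.alpha
    return out if out.ndim else float(out)
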