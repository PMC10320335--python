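"""AIC comparison of site-partition models.

Which sites share a colonization-extinction pair?  Every set partition
of the site labels defines a model: sites in the same block share one
(c, e) pair, fitted jointly.  Models are ranked by AIC and summarized by
Akaike weights w = exp(-dAIC/2) / sum exp(-dAIC/2); the weight of
evidence for a hypothesis (e.g. "at least two same-basin lakes share a
pair") is the summed weight of the partitions satisfying it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .estimation import GroupRates, _fit_group_counts, transition_counts
from .series import PresenceSeries

__all__ = [
    "Partition",
    "PartitionFit",
    "enumerate_partitions",
    "fit_partition_models",
    "akaike_weights",
    "evidence_for",
]

#: partition = tuple of blocks, each block a tuple of site labels
Partition = tuple[tuple[str, ...], ...]

MAX_SITES = 12  # Bell(13) ~ 2.7e7: refuse to enumerate beyond this


def _canonical(partition: Sequence[Sequence[str]]) -> Partition:
    blocks = tuple(tuple(sorted(b)) for b in partition)
    return tuple(sorted(blocks, key=lambda b: b[0]))


def enumerate_partitions(sites: Sequence[str]) -> list[Partition]:
    """All set partitions of the site labels, canonically ordered.

    Blocks are sorted by their smallest member; the partition list is
    ordered by block count, then lexicographically.  Refuses more than
    12 sites (Bell-number explosion).
    """
    labels = list(sites)
    if len(set(labels)) != len(labels):
        raise ValueError("site labels must be unique")
    if not labels:
        raise ValueError("need at least one site")
    if len(labels) > MAX_SITES:
        raise ValueError(
            f"{len(labels)} sites would give too many partitions (limit {MAX_SITES}); "
            "supply an explicit model set instead"
        )

    def rec(items: list[str]) -> list[list[list[str]]]:
        if not items:
            return [[]]
        first, rest = items[0], items[1:]
        out = []
        for sub in rec(rest):
            for i in range(len(sub)):
                out.append(sub[:i] + [[first] + sub[i]] + sub[i + 1 :])
            out.append([[first]] + sub)
        return out

    parts = {_canonical(p) for p in rec(labels)}
    return sorted(parts, key=lambda p: (len(p), p))


@dataclass(frozen=True)
class PartitionFit:
    """One partition model: per-block rate fits, AIC and Akaike weight."""

    partition: Partition
    block_fits: tuple[GroupRates, ...]
    log_likelihood: float
    n_params: int
    aic: float
    weight: float

    def label(self) -> str:
        return " | ".join("+".join(b) for b in self.partition)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Akaike weights from AIC values; invariant to a common offset."""
    a = np.asarray(aics, dtype=float)
    rel = np.exp(-(a - a.min()) / 2.0)
    return rel / rel.sum()


def fit_partition_models(
    series: PresenceSeries,
    partitions: Sequence[Partition] | None = None,
    corrected: bool = False,
) -> list[PartitionFit]:
    """Fit every partition model and weight them by AIC.

    Each block pools the transitions of all its sites (all taxa as one
    guild) into a single joint (c, e) likelihood; a model spends two
    parameters per block.  ``partitions`` defaults to all set partitions
    of the series' sites.  ``corrected`` switches to AICc, with the
    total transition count as the sample size.
    """
    sites = sorted(series.sites)
    if partitions is None:
        partitions = enumerate_partitions(sites)
    if not partitions:
        raise ValueError("empty model set")
    fits = []
    for partition in partitions:
        canon = _canonical(partition)
        covered = sorted(s for b in canon for s in b)
        if covered != sites:
            raise ValueError(
                f"partition {canon} does not cover the sites {sites} exactly"
            )
        block_fits = []
        loglik = 0.0
        for block in canon:
            sub = series.select_sites(block)
            dts, counts = transition_counts(sub)
            try:
                fit = _fit_group_counts("+".join(block), dts, counts)
            except ValueError as err:
                raise ValueError(f"partition {canon}, block {block}: {err}") from err
            block_fits.append(fit)
            loglik += fit.log_likelihood
        n_params = 2 * len(canon)
        fits.append((canon, tuple(block_fits), loglik, n_params))
    aics = [2.0 * npar - 2.0 * ll for _, _, ll, npar in fits]
    if corrected:
        n_obs = sum(f.n_transitions for f in fits[0][1])
        aics = [
            aic + 2.0 * npar * (npar + 1) / max(n_obs - npar - 1, 1)
            for aic, (_, _, _, npar) in zip(aics, fits)
        ]
    weights = akaike_weights(aics)
    return [
        PartitionFit(p, bf, ll, npar, aic, float(w))
        for (p, bf, ll, npar), aic, w in zip(fits, aics, weights)
    ]


def evidence_for(
    fits: Sequence[PartitionFit], predicate: Callable[[Partition], bool]
) -> float:
    """Summed Akaike weight of the partitions satisfying a predicate."""
    if not fits:
        raise ValueError("empty model set")
    return float(sum(f.weight for f in fits if predicate(f.partition)))
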