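"""Container for temporally sampled presence-absence (and count) data.

A :class:`PresenceSeries` holds, per site, an ordered vector of sampling
times (irregular spacing allowed) and a detection array of shape
(taxa, times, replicates).  Counts, when available, align with the
detections; a detection is 1 iff the aligned count is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SiteObservations", "PresenceSeries"]


@dataclass(frozen=True)
class SiteObservations:
    """Observations of one site: times (T,), detections (S, T, R), counts optional."""

    times: np.ndarray
    detections: np.ndarray
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        det = np.asarray(self.detections)
        if det.ndim == 2:  # allow unreplicated (S, T) input
            det = det[:, :, None]
        det = det.astype(bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "detections", det)
        if times.ndim != 1 or det.ndim != 3 or det.shape[1] != times.size:
            raise ValueError(
                f"detections shape {det.shape} incompatible with {times.size} times"
            )
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing within a site")
        if self.counts is not None:
            counts = np.asarray(self.counts)
            if counts.ndim == 2:
                counts = counts[:, :, None]
            if counts.shape != det.shape:
                raise ValueError("counts must align with detections")
            if np.any(counts < 0):
                raise ValueError("counts must be non-negative")
            if not np.array_equal(counts > 0, det):
                raise ValueError("detection must be 1 iff the aligned count is > 0")
            object.__setattr__(self, "counts", counts)

    @property
    def n_taxa(self) -> int:
        return self.detections.shape[0]

    @property
    def n_times(self) -> int:
        return self.detections.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.detections.shape[2]


@dataclass(frozen=True)
class PresenceSeries:
    """Taxa x ordered irregular sample times x optional replicates, per site."""

    taxa: tuple[str, ...]
    sites: dict[str, SiteObservations] = field(default_factory=dict)

    def __post_init__(self) -> None:
        taxa = tuple(self.taxa)
        object.__setattr__(self, "taxa", taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxon ids must be unique")
        for name, obs in self.sites.items():
            if obs.n_taxa != len(taxa):
                raise ValueError(
                    f"site {name!r} has {obs.n_taxa} taxon rows, expected {len(taxa)}"
                )

    @property
    def n_replicates(self) -> int:
        return max((obs.n_replicates for obs in self.sites.values()), default=1)

    def taxon_index(self, taxa) -> np.ndarray:
        lookup = {t: i for i, t in enumerate(self.taxa)}
        try:
            return np.array([lookup[t] for t in taxa], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown taxon {err.args[0]!r}") from None

    def subset(self, taxa) -> "PresenceSeries":
        """Restrict to the given taxa (order preserved as given)."""
        idx = self.taxon_index(taxa)
        sites = {
            name: SiteObservations(
                obs.times,
                obs.detections[idx],
                None if obs.counts is None else obs.counts[idx],
            )
            for name, obs in self.sites.items()
        }
        return PresenceSeries(tuple(taxa), sites)

    def select_sites(self, names) -> "PresenceSeries":
        return PresenceSeries(self.taxa, {n: self.sites[n] for n in names})

    def collapse_replicates(self) -> "PresenceSeries":
        """Collapse the replicate axis: detected iff any replicate detected.

        Counts, when present, are summed across replicates.
        """
        sites = {}
        for name, obs in self.sites.items():
            det = obs.detections.any(axis=2)[:, :, None]
            counts = None
            if obs.counts is not None:
                counts = obs.counts.sum(axis=2)[:, :, None]
            sites[name] = SiteObservations(obs.times, det, counts)
        return PresenceSeries(self.taxa, sites)
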