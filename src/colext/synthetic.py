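"""Synthetic communities for exercising every stage of the pipeline.

Generators for: presence-absence trajectories of the two-state
colonization-extinction chain at specified (c_i, e_i); fitness-equalized
communities (fixed k = c/e, colonization spread over decades); SAD-based
detection where apparent colonizations and extinctions arise purely from
finite sequencing depth (the null against which the trade-off signal is
contrasted); replicated surveys with imperfect detection; and small
deterministic fixtures.

All generators are deterministic under a fixed seed, with an independent
random substream per taxon, so enlarging the pool never reshuffles the
trajectories of existing taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .markov import RatePair, stationary_occupancy, transition_matrix
from .series import PresenceSeries, SiteObservations

__all__ = [
    "SyntheticSpec",
    "simulate_presence",
    "simulate_equalized",
    "simulate_sad_detection",
    "simulate_two_regime_table",
    "make_fixtures",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study design of a simulated community.

    Times are in the study's time unit (days by convention) and may be
    irregular; rates are per the same unit.  ``rate_model`` selects how
    per-taxon rates arise: a shared ``fixed`` pair (species equivalence),
    ``equalized`` (c log-uniform over ``c_range``, e = c/k: fitness
    equalization), or ``independent`` (c and e each log-uniform, no
    constraint).  Detection is ``perfect``, ``bernoulli`` (per-replicate
    probability d given presence) or ``depth`` (multinomial read counts
    at sequencing depth ``depth`` over SAD-drawn relative abundances).
    """

    n_taxa: int = 300
    times: tuple[float, ...] = tuple(float(t) for t in range(24))
    rate_model: str = "equalized"
    c: float = 0.2
    e: float = 0.1
    k: float = 2.0
    c_range: tuple[float, float] = (0.02, 2.0)
    e_range: tuple[float, float] = (0.01, 1.0)
    replicates: int = 1
    detection: str = "perfect"
    d: float = 1.0
    depth: int = 2000
    dynamics: bool = True
    core_fraction: float = 0.2
    lognormal_meanlog: float = 4.0
    lognormal_sdlog: float = 1.0
    logseries_p: float = 0.99
    abundance_jitter_sd: float = 0.0
    site: str = "site1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if len(self.times) < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing, length >= 2")
        if not 0.0 < self.d <= 1.0:
            raise ValueError("d must lie in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.rate_model not in ("fixed", "equalized", "independent"):
            raise ValueError(f"unknown rate model {self.rate_model!r}")
        if self.detection not in ("perfect", "bernoulli", "depth"):
            raise ValueError(f"unknown detection model {self.detection!r}")


#: substream purposes: separate keys so e.g. rate draws never share stream
#: positions with trajectory draws
_TRAJECTORY, _SAMPLE, _RATES, _ABUNDANCE = 0, 1, 2, 3


def _taxon_rng(seed: int, index: int, purpose: int = _TRAJECTORY) -> np.random.Generator:
    """Independent substream for taxon ``index``: stable under pool growth."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(purpose, index))
    )


def _sample_rng(seed: int, t_index: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_SAMPLE, t_index, rep))
    )


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if lo <= 0 or hi < lo:
        raise ValueError("range must be positive with lo <= hi")
    if lo == hi:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_rates(spec: SyntheticSpec) -> list[RatePair]:
    rates = []
    for i in range(spec.n_taxa):
        rng = _taxon_rng(spec.seed, i, _RATES)
        if spec.rate_model == "fixed":
            rates.append(RatePair(spec.c, spec.e))
        elif spec.rate_model == "equalized":
            c = _loguniform(rng, *spec.c_range)
            rates.append(RatePair(c, c / spec.k))
        else:
            c = _loguniform(rng, *spec.c_range)
            e = _loguniform(rng, *spec.e_range)
            rates.append(RatePair(c, e))
    return rates


def _truth_frame(taxa, rates: list[RatePair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "taxon": taxa,
            "c": [r.c for r in rates],
            "e": [r.e for r in rates],
            "k": [r.k for r in rates],
            "persistence": [r.persistence for r in rates],
            "pi_star": [stationary_occupancy(r) for r in rates],
        }
    )


def _latent_trajectory(
    rng: np.random.Generator,
    rates: RatePair,
    times: np.ndarray,
    initial: int | None = None,
) -> np.ndarray:
    pi = stationary_occupancy(rates)
    x = np.empty(times.size, dtype=bool)
    x[0] = rng.random() < pi if initial is None else bool(initial)
    for j, dt in enumerate(np.diff(times)):
        p_present = transition_matrix(rates, dt)[int(x[j]), 1]
        x[j + 1] = rng.random() < p_present
    return x


def simulate_presence(
    spec: SyntheticSpec,
    rates: list[RatePair] | None = None,
    initial: int | None = None,
) -> tuple[PresenceSeries, pd.DataFrame]:
    """Simulate presence-absence trajectories under the two-state chain.

    Each taxon starts present with its stationary probability (unless
    ``initial`` forces a state) and is propagated across consecutive
    sampling times with the exact interval transition probabilities.
    Detection is perfect or per-replicate Bernoulli(d), per the spec.
    Returns the observed series and the true per-taxon rate table.
    """
    if spec.detection == "depth":
        raise ValueError("use simulate_sad_detection for depth-based detection")
    times = np.asarray(spec.times, dtype=float)
    if rates is None:
        rates = _draw_rates(spec)
    taxa = tuple(f"t{i:04d}" for i in range(spec.n_taxa))
    det = np.zeros((spec.n_taxa, times.size, spec.replicates), dtype=bool)
    for i, rp in enumerate(rates):
        rng = _taxon_rng(spec.seed, i)
        x = _latent_trajectory(rng, rp, times, initial)
        if spec.detection == "perfect":
            det[i] = x[:, None]
        else:
            det[i] = x[:, None] & (rng.random((times.size, spec.replicates)) < spec.d)
    series = PresenceSeries(taxa, {spec.site: SiteObservations(times, det)})
    return series, _truth_frame(taxa, rates)


def simulate_equalized(spec: SyntheticSpec) -> tuple[PresenceSeries, pd.DataFrame]:
    """Simulate a fitness-equalized community: fixed k, c spread in log.

    Every taxon satisfies c * p = k exactly by construction, so a
    downstream log-log fit of estimated persistence on colonization
    should recover slope -1.  Warns when the colonization range is
    degenerate (the slope is then unidentifiable downstream).
    """
    spec = replace(spec, rate_model="equalized")
    if spec.c_range[0] == spec.c_range[1]:
        warnings.warn(
            "degenerate colonization range: trade-off slope unidentifiable",
            UserWarning,
            stacklevel=2,
        )
    return simulate_presence(spec)


def _draw_abundances(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Latent absolute abundances: lognormal core block, log-series rest.

    Returns (abundances, is_core).  Taxa substreams keep draws stable
    under pool growth.
    """
    n_core = int(round(spec.core_fraction * spec.n_taxa))
    abund = np.empty(spec.n_taxa)
    is_core = np.zeros(spec.n_taxa, dtype=bool)
    for i in range(spec.n_taxa):
        rng = _taxon_rng(spec.seed, i, _ABUNDANCE)
        if i < n_core:
            abund[i] = np.exp(rng.normal(spec.lognormal_meanlog, spec.lognormal_sdlog))
            is_core[i] = True
        else:
            # inverse-CDF draw from the log-series distribution
            u = rng.random()
            x, cdf, pk = 1, 0.0, 0.0
            norm = -np.log1p(-spec.logseries_p)
            while True:
                pk = spec.logseries_p**x / (x * norm)
                cdf += pk
                if u <= cdf or x > 10_000:
                    break
                x += 1
            abund[i] = float(x)
    return abund, is_core


def simulate_sad_detection(
    spec: SyntheticSpec,
    rates: list[RatePair] | None = None,
) -> tuple[PresenceSeries, pd.DataFrame]:
    """Simulate read counts: SAD abundances sampled at finite depth.

    Latent presence either follows the two-state chain (``dynamics``
    true) or is static all-present (``dynamics`` false: the SAD-only
    null, where every apparent colonization or extinction is a sampling
    artefact).  Present taxa contribute their latent abundance (with
    optional per-sample lognormal jitter) to a multinomial draw of
    ``depth`` reads per sample; detection is count > 0.
    """
    times = np.asarray(spec.times, dtype=float)
    abund, is_core = _draw_abundances(spec)
    if spec.dynamics:
        if rates is None:
            rates = _draw_rates(spec)
        presence = np.stack(
            [
                _latent_trajectory(_taxon_rng(spec.seed, i), rp, times)
                for i, rp in enumerate(rates)
            ]
        )
    else:
        presence = np.ones((spec.n_taxa, times.size), dtype=bool)
        rates = None
    taxa = tuple(f"t{i:04d}" for i in range(spec.n_taxa))
    counts = np.zeros((spec.n_taxa, times.size, spec.replicates), dtype=np.int64)
    for t in range(times.size):
        for rep in range(spec.replicates):
            rng = _sample_rng(spec.seed, t, rep)
            weights = abund * presence[:, t]
            if spec.abundance_jitter_sd > 0:
                weights = weights * np.exp(
                    rng.normal(0.0, spec.abundance_jitter_sd, spec.n_taxa)
                )
            total = weights.sum()
            if total <= 0:
                continue
            counts[:, t, rep] = rng.multinomial(spec.depth, weights / total)
    series = PresenceSeries(
        taxa,
        {spec.site: SiteObservations(times, counts > 0, counts)},
    )
    truth = (
        _truth_frame(taxa, rates)
        if rates is not None
        else pd.DataFrame({"taxon": taxa})
    )
    truth["abundance"] = abund
    truth["sad_class"] = np.where(is_core, "lognormal", "logseries")
    return series, truth


def simulate_two_regime_table(
    n_taxa: int = 120,
    break_occupancy: float = 0.5,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Occupancy/log-abundance points with a structural break.

    Satellite regime (occupancy below the break): shallow line; core
    regime (above): steeper, offset line.  Gaussian noise on the
    response.  Returns the table and the true labels.
    """
    rng = np.random.default_rng(seed)
    n_sat = n_taxa // 2
    n_core = n_taxa - n_sat
    occ_sat = rng.uniform(0.05, break_occupancy - 0.01, n_sat)
    occ_core = rng.uniform(break_occupancy + 0.01, 0.98, n_core)
    occ = np.concatenate([occ_sat, occ_core])
    truth = np.array(["satellite"] * n_sat + ["core"] * n_core)
    y = np.where(
        truth == "satellite",
        0.5 + 1.0 * occ,
        0.2 + 3.5 * occ,
    ) + rng.normal(0.0, noise_sd, n_taxa)
    table = pd.DataFrame(
        {
            "taxon": [f"t{i:04d}" for i in range(n_taxa)],
            "occupancy": occ,
            "log10_max_abundance": y,
            "max_abundance": np.round(10.0**y).astype(int).clip(min=1),
        }
    )
    return table, pd.Series(truth, index=table["taxon"], name="true_label")


def make_fixtures(out_dir: str | Path | None = None) -> dict:
    """Small deterministic fixtures used across the test-suite.

    ``likelihood``: a 3-taxon x 4-time series with irregular intervals,
    small enough for exhaustive path enumeration.  ``two_regime``: an
    occupancy-abundance table with a known break at occupancy 0.5.
    ``duplicated_site``: two sites carrying identical observations.
    Written as TSV when ``out_dir`` is given; byte-identical across runs.
    """
    times = np.array([0.0, 10.0, 15.0, 45.0])
    det = np.array(
        [
            [1, 1, 0, 1],
            [0, 1, 1, 1],
            [1, 0, 0, 0],
        ],
        dtype=bool,
    )
    likelihood = PresenceSeries(
        ("taxA", "taxB", "taxC"), {"s1": SiteObservations(times, det)}
    )
    two_regime_table, two_regime_truth = simulate_two_regime_table(seed=1234)
    dup_times = np.arange(12.0)
    rng = np.random.default_rng(99)
    dup_det = rng.random((8, dup_times.size)) < 0.5
    duplicated_site = PresenceSeries(
        tuple(f"g{i}" for i in range(8)),
        {
            "siteA": SiteObservations(dup_times, dup_det),
            "siteB": SiteObservations(dup_times, dup_det.copy()),
        },
    )
    fixtures = {
        "likelihood": likelihood,
        "two_regime": (two_regime_table, two_regime_truth),
        "duplicated_site": duplicated_site,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(det.astype(int), index=likelihood.taxa, columns=times).to_csv(
            out / "likelihood_detections.tsv", sep="\t"
        )
        two_regime_table.to_csv(out / "two_regime.tsv", sep="\t", index=False)
        two_regime_truth.to_csv(out / "two_regime_truth.tsv", sep="\t")
        pd.DataFrame(
            dup_det.astype(int), index=duplicated_site.taxa, columns=dup_times
        ).to_csv(out / "duplicated_site.tsv", sep="\t")
    return fixtures
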