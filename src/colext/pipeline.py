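"""End-to-end analysis: rates -> labile filter -> core/satellite -> trade-off.

For each requested taxonomic rank the pipeline aggregates counts,
estimates a colonization/extinction pair per taxon (guild), drops labile
taxa (persistence under a quarter of the minimal sampling interval),
splits the community at the occupancy structural break, fits the log-log
persistence-colonization regression per component, tests the slope
against the fitness-equalization prediction of -1, and compares core vs
satellite slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core_satellite, estimation, tradeoff
from .io import CommunityDataset

__all__ = ["PipelineResult", "run_pipeline", "rates_frame", "partition_frame"]


def rates_frame(fits) -> pd.DataFrame:
    """Per-group rate table (CSV schema: group, c, e, k, persistence, ...)."""
    rows = []
    for f in fits:
        rows.append(
            {
                "group": f.group,
                "c": f.c,
                "e": f.e,
                "k": f.rates.k if f.e > 0 else np.nan,
                "persistence": f.persistence if f.e > 0 else np.nan,
                "loglik": f.log_likelihood,
                "n_transitions": f.n_transitions,
                "converged": f.converged,
                "boundary": f.boundary,
                **({"d": f.d} if hasattr(f, "d") else {}),
            }
        )
    return pd.DataFrame(rows)


def partition_frame(fits) -> pd.DataFrame:
    """Partition model report: one row per partition, ranked by AIC."""
    best = min(f.aic for f in fits)
    rows = [
        {
            "partition": f.label(),
            "n_blocks": len(f.partition),
            "loglik": f.log_likelihood,
            "n_params": f.n_params,
            "aic": f.aic,
            "delta_aic": f.aic - best,
            "weight": f.weight,
        }
        for f in fits
    ]
    return pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)


@dataclass
class PipelineResult:
    """Tables produced by one pipeline run (one row group per rank)."""

    rates: pd.DataFrame
    core_satellite: pd.DataFrame
    tradeoff: pd.DataFrame

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rates.to_csv(out / "rates.csv", index=False)
        self.core_satellite.to_csv(out / "core_satellite.csv", index=False)
        self.tradeoff.to_csv(out / "tradeoff.csv", index=False)


def _tradeoff_row(rank: str, fit: tradeoff.TradeoffFit) -> dict:
    t, df, p = tradeoff.test_slope_equals(fit, -1.0) if fit.n >= 4 else (np.nan,) * 3
    return {
        "rank": rank,
        "component": fit.component,
        "n": fit.n,
        "slope": fit.slope,
        "ci_lower": fit.ci_lower,
        "ci_upper": fit.ci_upper,
        "intercept": fit.intercept,
        "spearman_rho": fit.spearman_rho,
        "spearman_p": fit.spearman_p,
        "t_vs_minus1": t,
        "p_vs_minus1": p,
    }


def run_pipeline(
    dataset: CommunityDataset,
    ranks: tuple[str, ...] = ("family", "genus"),
    min_points: int = 10,
) -> PipelineResult:
    """Run the full analysis on a dataset at the requested ranks.

    Deterministic given the inputs.  Components with too few estimable
    taxa are skipped (the trade-off table then lacks those rows).
    """
    rate_rows, cs_rows, trade_rows = [], [], []
    for rank in ranks:
        agg = dataset.aggregate(rank)
        series = agg.to_presence_series()
        min_interval = min(
            float(np.diff(obs.times).min())
            for obs in series.sites.values()
            if obs.n_times >= 2
        )
        grouping = {t: t for t in series.taxa}
        # taxa never observed present cannot be fitted: drop them up front
        observed = [
            t
            for i, t in enumerate(series.taxa)
            if any(obs.detections[i].any() for obs in series.sites.values())
        ]
        fits = estimation.fit_rates(
            series.subset(observed), {t: grouping[t] for t in observed}
        )
        kept, excluded, frac = estimation.filter_labile(fits, min_interval)
        rf = rates_frame(fits)
        rf.insert(0, "rank", rank)
        rf["labile_excluded"] = rf["group"].isin({f.group for f in excluded})
        rate_rows.append(rf)

        table = core_satellite.occupancy_abundance(series)
        labels = {}
        scan = None
        if len(table) >= min_points and table["occupancy"].nunique() >= 2:
            scan = core_satellite.split_core_satellite(table)
            if scan.significant:
                labels = scan.labels.to_dict()
        cs = (scan.table if scan is not None else table).copy()
        cs.insert(0, "rank", rank)
        cs["occupancy_threshold"] = (
            scan.occupancy_threshold if scan is not None else np.nan
        )
        cs_rows.append(cs)

        usable = [f for f in kept if not f.boundary and f.e > 0]
        points = {
            "all": usable,
            "core": [f for f in usable if labels.get(f.group) == "core"],
            "satellite": [f for f in usable if labels.get(f.group) == "satellite"],
        }
        fits_by_component = {}
        for component, fs in points.items():
            if len(fs) < 3:
                continue
            fit = tradeoff.loglog_tradeoff_fit(
                [f.c for f in fs], [f.persistence for f in fs], component
            )
            fits_by_component[component] = fit
            trade_rows.append(_tradeoff_row(rank, fit))
        if "core" in fits_by_component and "satellite" in fits_by_component:
            ca, cb = fits_by_component["core"], fits_by_component["satellite"]
            if ca.n >= 4 and cb.n >= 4:
                comp = tradeoff.compare_slopes(ca, cb)
                for row in trade_rows:
                    if row["rank"] == rank and row["component"] in ("core", "satellite"):
                        row["slope_equality_t"] = comp.t
                        row["slope_equality_p"] = comp.p
    return PipelineResult(
        rates=pd.concat(rate_rows, ignore_index=True),
        core_satellite=pd.concat(cs_rows, ignore_index=True),
        tradeoff=pd.DataFrame(trade_rows),
    )
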