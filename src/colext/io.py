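"""Readers, writers and validation for the counts/metadata/taxonomy trio.

A community dataset is three delimited tables: a non-negative integer
count table (taxa x samples), sample metadata (sample id, time, site,
optional replicate), and a taxonomy table (taxon id plus ranks phylum
through genus).  TSV and CSV are both accepted; the delimiter is taken
from the file extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import PresenceSeries, SiteObservations

__all__ = ["CommunityDataset", "read_dataset", "write_dataset", "RANKS"]

RANKS = ("phylum", "class", "order", "family", "genus")

_META_REQUIRED = ("sample", "time", "site")


class ValidationError(ValueError):
    """Schema violation in an input table, with offender names."""


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)


@dataclass
class CommunityDataset:
    """Parsed and validated counts, metadata and taxonomy tables.

    ``counts``: taxa (index) x samples (columns), non-negative integers.
    ``metadata``: one row per sample: sample, time, site, replicate.
    ``taxonomy``: one row per taxon (index) with rank columns.
    ``warnings``: non-fatal validation findings (e.g. taxa lacking a
    taxonomy row, which are kept but cannot be aggregated by rank).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        meta = self.metadata
        missing_cols = [c for c in _META_REQUIRED if c not in meta.columns]
        if missing_cols:
            raise ValidationError(f"metadata lacks required columns: {missing_cols}")
        if "replicate" not in meta.columns:
            meta = meta.assign(replicate=1)
        if meta["sample"].duplicated().any():
            dups = meta.loc[meta["sample"].duplicated(), "sample"].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        if not np.issubdtype(np.asarray(meta["time"]).dtype, np.number):
            raise ValidationError("metadata time column must be numeric (days)")
        key = meta[["site", "time", "replicate"]]
        if key.duplicated().any():
            dups = key[key.duplicated()].to_dict("records")
            raise ValidationError(f"duplicate (site, time, replicate): {dups}")
        self.metadata = meta.set_index("sample", drop=False)
        orphan_samples = [s for s in self.counts.columns if s not in self.metadata.index]
        if orphan_samples:
            raise ValidationError(
                f"count columns missing from metadata: {orphan_samples}"
            )
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        unknown_taxa = [t for t in self.counts.index if t not in self.taxonomy.index]
        for t in unknown_taxa:
            self.warnings.append(f"taxon {t!r} has no taxonomy row")

    def aggregate(self, rank: str) -> "CommunityDataset":
        """Sum counts of taxa sharing the given taxonomy rank value."""
        if rank not in self.taxonomy.columns:
            raise ValidationError(
                f"unknown rank {rank!r}; taxonomy has {list(self.taxonomy.columns)}"
            )
        labels = self.taxonomy.reindex(self.counts.index)[rank]
        keep = labels.notna()
        agg = self.counts.loc[keep].groupby(labels[keep]).sum()
        agg.index.name = "taxon"
        rank_cols = [c for c in self.taxonomy.columns if c != "taxon"]
        upto = rank_cols[: rank_cols.index(rank) + 1]
        tax = self.taxonomy[upto].drop_duplicates(subset=[rank]).copy()
        tax.insert(0, "taxon", tax[rank])
        tax = tax.set_index(rank, drop=False)
        tax.index.name = "taxon"
        return CommunityDataset(agg, self.metadata.reset_index(drop=True), tax)

    def to_presence_series(self) -> PresenceSeries:
        """Arrange counts into per-site (taxa, times, replicates) arrays.

        Within a site every sampling time must carry the same number of
        replicates (missing combinations are rejected, not imputed).
        """
        taxa = tuple(self.counts.index)
        sites: dict[str, SiteObservations] = {}
        for site, meta in self.metadata.groupby("site"):
            times = np.sort(meta["time"].unique())
            reps_per_time = meta.groupby("time")["replicate"].count()
            n_rep = int(reps_per_time.iloc[0])
            if not (reps_per_time == n_rep).all():
                raise ValidationError(
                    f"site {site!r}: unequal replicate counts across times"
                )
            counts = np.zeros((len(taxa), times.size, n_rep), dtype=np.int64)
            for t_idx, t in enumerate(times):
                sample_ids = meta.loc[meta["time"] == t].sort_values("replicate")[
                    "sample"
                ]
                for r_idx, sid in enumerate(sample_ids):
                    counts[:, t_idx, r_idx] = self.counts[sid].to_numpy()
            sites[str(site)] = SiteObservations(times, counts > 0, counts)
        return PresenceSeries(taxa, sites)


def read_dataset(
    counts_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path,
    taxa_as: str = "rows",
) -> CommunityDataset:
    """Read and validate the counts/metadata/taxonomy trio.

    ``taxa_as`` states the count-table orientation explicitly ("rows" or
    "columns"); no guessing.  The first column of the counts and
    taxonomy tables is the taxon id.
    """
    if taxa_as not in ("rows", "columns"):
        raise ValueError("taxa_as must be 'rows' or 'columns'")
    counts = _read_table(counts_path)
    counts = counts.set_index(counts.columns[0])
    counts.index.name = "taxon"
    if taxa_as == "columns":
        counts = counts.T
    metadata = _read_table(metadata_path)
    taxonomy = _read_table(taxonomy_path)
    taxonomy = taxonomy.set_index(taxonomy.columns[0], drop=False)
    taxonomy.index.name = "taxon"
    return CommunityDataset(counts, metadata, taxonomy)


def write_dataset(dataset: CommunityDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables as TSV; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
    }
    self_counts = dataset.counts.copy()
    self_counts.insert(0, "taxon", self_counts.index)
    self_counts.to_csv(paths["counts"], sep="\t", index=False)
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    dataset.taxonomy.reset_index(drop=True).to_csv(
        paths["taxonomy"], sep="\t", index=False
    )
    return paths


def series_to_dataset(
    series: PresenceSeries,
    taxonomy: pd.DataFrame | None = None,
) -> CommunityDataset:
    """Flatten a PresenceSeries (with counts) back to the table trio."""
    rows = {t: {} for t in series.taxa}
    meta_rows = []
    for site, obs in series.sites.items():
        if obs.counts is None:
            raise ValueError("series has no counts; cannot form a count table")
        for t_idx, t in enumerate(obs.times):
            for rep in range(obs.n_replicates):
                sid = f"{site}_t{t_idx}_r{rep + 1}"
                meta_rows.append(
                    {"sample": sid, "time": float(t), "site": site, "replicate": rep + 1}
                )
                for s_idx, taxon in enumerate(series.taxa):
                    rows[taxon][sid] = int(obs.counts[s_idx, t_idx, rep])
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "taxon"
    metadata = pd.DataFrame(meta_rows)
    if taxonomy is None:
        taxonomy = pd.DataFrame(
            {"taxon": list(series.taxa)}
            | {rank: list(series.taxa) for rank in RANKS}
        ).set_index("taxon", drop=False)
        taxonomy.index.name = "taxon"
    return CommunityDataset(counts, metadata, taxonomy)
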