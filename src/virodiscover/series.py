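"""Annual discovery-count series and historical richness snapshots.

Counting conventions (consequential, so stated up front):

- Species level: a "discovery" is a new host–virus pair, so annual counts
  tally pairs and species richness equals the species' pair count.
- Family / order / all-mammal level: a discovery is the first detection of a
  distinct virus anywhere within the taxon; a virus later found in a second
  member species is not a new taxon-level discovery.
- Richness snapshots at year t use only pairs discovered in or before t, over
  a FIXED taxon universe (by default, taxa with >= 1 virus by the reference
  year), assigning 0 to taxa not yet sampled at t. This keeps n constant
  along a historical curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "Level",
    "Metric",
    "DiscoveryCountSeries",
    "RichnessSnapshot",
    "annual_counts",
    "richness_at",
    "accumulation_curve",
    "reference_universe",
]

_LEVEL_COL = {"species": "host_species", "family": "host_family", "order": "host_order"}


class Level(str, Enum):
    SPECIES = "species"
    FAMILY = "family"
    ORDER = "order"
    ALL = "all"


class Metric(str, Enum):
    TOTAL = "total"
    MEAN_SPECIES = "mean_species"


@dataclass
class DiscoveryCountSeries:
    """Annual counts of novel discoveries for one taxon over a contiguous year grid."""

    taxon: str
    level: str
    years: np.ndarray  # contiguous, ascending
    counts: np.ndarray  # non-negative integers, same length

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.years.shape != self.counts.shape:
            raise ValueError("years and counts must have equal length")
        if self.years.size and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be contiguous ascending")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return self.years.size


@dataclass
class RichnessSnapshot:
    """Per-taxon viral richness known by the snapshot year."""

    year: int
    level: str
    metric: str
    values: pd.Series  # index: taxon, values: non-negative richness


def _check_level(level, allow_all: bool = True) -> str:
    level = Level(level).value
    if level == "all" and not allow_all:
        raise ValueError("level 'all' not valid here")
    return level


def _first_detection_years(pairs: pd.DataFrame, level: str) -> pd.DataFrame:
    """(taxon, virus) -> earliest discovery year within the taxon.

    At species level this is the pair table itself (pairs are unique).
    """
    if level == "species":
        return pairs[["host_species", "virus", "discovery_year"]].rename(
            columns={"host_species": "taxon"}
        )
    if level == "all":
        g = pairs.groupby("virus", sort=False)["discovery_year"].min().reset_index()
        g["taxon"] = "all"
        return g[["taxon", "virus", "discovery_year"]]
    col = _LEVEL_COL[level]
    g = (
        pairs.groupby([col, "virus"], sort=False)["discovery_year"]
        .min()
        .reset_index()
        .rename(columns={col: "taxon"})
    )
    return g


def annual_counts(pairs: pd.DataFrame, taxon: str | None, level, year_range) -> DiscoveryCountSeries:
    """Annual counts of novel discoveries for ``taxon`` at ``level``.

    Zero-count years are materialized across the whole ``year_range``
    (required for correct count-likelihood fits downstream). Discoveries
    dated before ``year_range[0]`` are clipped out: an early first report is
    not a within-window discovery.

    Raises ``KeyError`` naming the taxon if it is absent at that level.
    """
    level = _check_level(level)
    y0, y1 = int(year_range[0]), int(year_range[1])
    if y0 > y1:
        raise ValueError(f"invalid year_range ({y0}, {y1})")

    fd = _first_detection_years(pairs, level)
    if level == "all":
        taxon = "all"
    else:
        if taxon is None:
            raise ValueError("taxon required for level != 'all'")
        present = set(pairs[_LEVEL_COL[level]].unique())
        if taxon not in present:
            raise KeyError(f"taxon {taxon!r} not present at level {level!r}")
        fd = fd[fd["taxon"] == taxon]

    years = np.arange(y0, y1 + 1)
    in_range = fd[(fd["discovery_year"] >= y0) & (fd["discovery_year"] <= y1)]
    tallies = in_range.groupby("discovery_year").size()
    counts = tallies.reindex(years, fill_value=0).to_numpy()
    return DiscoveryCountSeries(taxon=str(taxon), level=level, years=years, counts=counts)


def reference_universe(pairs: pd.DataFrame, level, year: int) -> pd.Index:
    """Taxa at ``level`` with >= 1 virus discovered by ``year`` (sorted)."""
    level = _check_level(level, allow_all=False)
    col = _LEVEL_COL[level]
    known = pairs[pairs["discovery_year"] <= year]
    return pd.Index(sorted(known[col].unique()), name=col)


def richness_at(
    pairs: pd.DataFrame,
    year: int,
    level,
    metric="total",
    universe=None,
    species_universe=None,
) -> RichnessSnapshot:
    """Viral richness per taxon using only pairs discovered by ``year``.

    Parameters
    ----------
    universe
        Fixed taxon set over which values are reported; taxa without any
        discovery by ``year`` get 0. Defaults to taxa with >= 1 virus in the
        whole pair table (i.e. by its latest year).
    metric
        ``total``: distinct viruses known in any member species.
        ``mean_species``: arithmetic mean of member species' totals
        (family/order level only). Member species default to every species of
        the taxon in ``pairs`` (the fixed reference universe, zeros included);
        pass ``species_universe`` to restrict.
    """
    level = _check_level(level, allow_all=False)
    metric = Metric(metric).value
    if metric == "mean_species" and level == "species":
        raise ValueError("metric 'mean_species' is undefined at species level")
    col = _LEVEL_COL[level]
    if universe is None:
        universe = pd.Index(sorted(pairs[col].unique()), name=col)
    else:
        universe = pd.Index(universe, name=col)
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")

    known = pairs[pairs["discovery_year"] <= year]
    if metric == "total":
        vals = known.groupby(col)["virus"].nunique()
        vals = vals.reindex(universe, fill_value=0).astype(int)
    else:
        sp_univ = (
            pd.Index(sorted(pairs["host_species"].unique()))
            if species_universe is None
            else pd.Index(species_universe)
        )
        sp_tot = (
            known.groupby("host_species")["virus"].nunique().reindex(sp_univ, fill_value=0)
        )
        sp_taxon = (
            pairs[["host_species", col]]
            .drop_duplicates("host_species")
            .set_index("host_species")[col]
            .reindex(sp_univ)
        )
        vals = sp_tot.groupby(sp_taxon).mean().reindex(universe, fill_value=0.0)
    return RichnessSnapshot(year=int(year), level=level, metric=metric, values=vals)


def accumulation_curve(pairs: pd.DataFrame, taxon: str | None, level, year_range):
    """Cumulative richness of ``taxon`` over ``year_range``.

    Returns ``(years, cumulative)``. The curve counts discoveries dated
    before the window start in its baseline, so the final value equals total
    richness at ``year_range[1]`` regardless of the window.
    """
    series = annual_counts(pairs, taxon, level, year_range)
    level = series.level
    fd = _first_detection_years(pairs, level)
    if level != "all":
        fd = fd[fd["taxon"] == series.taxon]
    baseline = int((fd["discovery_year"] < year_range[0]).sum())
    return series.years, baseline + np.cumsum(series.counts)
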