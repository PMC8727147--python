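"""Temporal rank-stability of viral-richness estimates.

For a fixed taxon universe, the stability curve traces Spearman's rho
between per-taxon richness at each historical year and richness at the
reference year (2018 by default). A flat curve near 1 means relative
richness has merely been filled in proportionally by later discovery; a
steep decline means discovery effort actively reordered which taxa look
virus-rich — the signature of effort shocks such as the post-SARS
intensification of bat surveillance.

Conventions: the universe is frozen at the reference year (taxa with >= 1
virus by then) so n is constant along a curve; historical snapshots backfill
zeros for taxa not yet sampled; ties take mid-ranks; a constant historical
snapshot (e.g. all zeros) has undefined rho, reported as NaN, never coerced
to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .series import Level, Metric, reference_universe, richness_at

__all__ = ["StabilityCurve", "spearman_rho", "stability_curve", "curve_summary"]

MIN_TAXA = 3
MIN_SPECIES_WITHIN_ORDER = 10


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with mid-ranks for ties.

    Pearson correlation of the mid-rank transforms of ``x`` and ``y``.
    Returns NaN (undefined) if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need >= 3 observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


@dataclass
class StabilityCurve:
    """Spearman rho of taxon richness vs the reference year, per historical year."""

    label: str
    reference_year: int
    years: np.ndarray  # ascending, ending at reference_year
    rho: np.ndarray  # in [-1, 1], NaN where undefined
    n_taxa: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.label, "year": self.years, "rho": self.rho, "n_taxa": self.n_taxa}
        )


def stability_curve(
    pairs: pd.DataFrame,
    level,
    metric="total",
    scope: dict | None = None,
    reference_year: int = 2018,
    start_year: int = 1960,
    min_species_within: int = MIN_SPECIES_WITHIN_ORDER,
) -> StabilityCurve:
    """Rank-stability curve of richness at ``level`` against ``reference_year``.

    Parameters
    ----------
    scope
        Optional pair-table filter, e.g. ``{"host_order": "Chiroptera"}`` for
        a within-order species-level curve. Within-order species curves
        require at least ``min_species_within`` member species with reference
        richness >= 1 (rho over fewer taxa is not meaningful).
    """
    level = Level(level).value
    metric = Metric(metric).value
    if level == "all":
        raise ValueError("stability curves are per taxonomic level; use species/family/order")
    scoped = pairs
    label_bits = []
    if scope:
        for col, val in scope.items():
            scoped = scoped[scoped[col] == val]
            label_bits.append(str(val))
        if scoped.empty:
            raise ValueError(f"scope {scope!r} selects no pairs")
    label_bits.append(f"{level}/{metric}")
    label = ":".join(label_bits)

    universe = reference_universe(scoped, level, reference_year)
    min_n = max(MIN_TAXA, min_species_within if (scope and level == "species") else MIN_TAXA)
    if len(universe) < min_n:
        raise ValueError(
            f"only {len(universe)} taxa with richness >= 1 at {reference_year} "
            f"for {label!r}; need >= {min_n}"
        )

    ref = richness_at(scoped, reference_year, level, metric, universe=universe).values.to_numpy()
    years = np.arange(start_year, reference_year + 1)
    rho = np.empty(years.size)
    for i, t in enumerate(years):
        snap = richness_at(scoped, int(t), level, metric, universe=universe).values.to_numpy()
        rho[i] = spearman_rho(snap, ref)
    return StabilityCurve(
        label=label, reference_year=reference_year, years=years, rho=rho, n_taxa=len(universe)
    )


def curve_summary(curve: StabilityCurve, thresholds) -> dict[float, int | None]:
    """Most recent year at which the curve is at or below each threshold.

    Scans backwards from the reference year; NaN (undefined) years are
    skipped; ``None`` if the curve never crosses the threshold.
    """
    out: dict[float, int | None] = {}
    for thr in np.atleast_1d(thresholds):
        crossed = None
        for year, r in zip(curve.years[::-1], curve.rho[::-1]):
            if np.isfinite(r) and r <= thr:
                crossed = int(year)
                break
        out[float(thr)] = crossed
    return out
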