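"""Order-level richness regressions on historical data snapshots.

At each snapshot year, order-level viral richness (distinct viruses with PCR
or isolation evidence discovered by that year) is regressed on log host
species richness, adjusting for sampling effort as log cumulative
virus-related citations, with a negative-binomial likelihood. Sweeping the
snapshot year asks when — if ever — the positive species-richness/viral-
richness association becomes detectable in the accumulating record.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = ["GlmResult", "build_snapshot", "fit_snapshot_glm", "snapshot_sweep"]

Z95 = 1.959963984540054
MIN_ROWS = 6


@dataclass
class GlmResult:
    """One snapshot regression: viral richness ~ log S + log(1 + citations)."""

    snapshot_year: int | None
    slope_logS: float
    se: float
    ci95: tuple[float, float]
    slope_logC: float
    dispersion: float  # NB2 alpha (0 under the Poisson fallback)
    positive_detected: bool
    family_used: str  # "negative_binomial" | "poisson"
    n_orders: int


def build_snapshot(
    pairs: pd.DataFrame,
    species_table: pd.DataFrame,
    citations_table: pd.DataFrame,
    year: int,
) -> pd.DataFrame:
    """Assemble one order-level snapshot row set for ``year``.

    Viral richness uses the stricter evidence rule: a pair contributes only
    if its earliest PCR-or-isolation report (the pair table's
    ``strict_year``) is at or before the snapshot year. Citations are summed
    over all years <= ``year``. Orders with zero viruses are retained.

    Parameters
    ----------
    species_table
        Columns ``order``, ``species_richness`` (described species per
        order; one row per order). Defines the order universe.
    citations_table
        Columns ``order``, ``year``, ``count`` (annual virus-related
        publication counts; may be pre-aggregated or one row per
        species-year provided an ``order`` column is present).

    Raises
    ------
    ValueError
        If an order in ``pairs`` is missing from ``species_table``.
    """
    species_table = species_table[["order", "species_richness"]].drop_duplicates("order")
    orders = pd.Index(sorted(species_table["order"].unique()), name="order")

    missing = set(pairs["host_order"].unique()) - set(orders)
    if missing:
        raise ValueError(
            f"order(s) present in pairs but missing from species table: {sorted(missing)}"
        )

    strict = pairs[pairs["strict_year"].notna() & (pairs["strict_year"] <= year)]
    richness = strict.groupby("host_order")["virus"].nunique().reindex(orders, fill_value=0)

    cites = (
        citations_table[citations_table["year"] <= year]
        .groupby("order")["count"]
        .sum()
        .reindex(orders, fill_value=0)
    )

    out = species_table.set_index("order").loc[orders].reset_index()
    out["viral_richness"] = richness.to_numpy().astype(int)
    out["citations"] = cites.to_numpy().astype(int)
    out["snapshot_year"] = int(year)
    return out


def fit_snapshot_glm(rows: pd.DataFrame, snapshot_year: int | None = None) -> GlmResult:
    """Negative-binomial regression of viral richness on log S and log(1+C).

    Citations enter as log(citations + 1) because zero-citation orders occur
    in early snapshots. The NB2 dispersion is estimated by maximum
    likelihood; if that fit degenerates (non-convergence or non-finite
    standard errors, typical at small n when the data are near-Poisson) the
    model falls back to a Poisson GLM with a logged warning.

    ``positive_detected`` is True when the Wald 95% CI on the log species
    richness coefficient lies entirely above zero.
    """
    if len(rows) < MIN_ROWS:
        raise ValueError(f"need >= {MIN_ROWS} orders, got {len(rows)}")
    if (rows["species_richness"] < 1).any():
        raise ValueError("species_richness must be >= 1 for every order")
    if snapshot_year is None and "snapshot_year" in rows:
        snapshot_year = int(rows["snapshot_year"].iloc[0])

    y = rows["viral_richness"].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("degenerate snapshot: viral richness identical across orders")
    X = np.column_stack(
        [
            np.ones(len(rows)),
            np.log(rows["species_richness"].to_numpy(dtype=float)),
            np.log1p(rows["citations"].to_numpy(dtype=float)),
        ]
    )

    # start the NB optimizer from the Poisson solution plus a moment estimate
    # of alpha; cold Newton starts fail on roughly half of small-n datasets
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu0 = pois.predict()
    alpha0 = max(float(np.sum((y - mu0) ** 2 - mu0) / np.sum(mu0**2)), 0.01)
    start = np.append(pois.params, alpha0)

    params = bse = None
    family_used, nb_alpha = "negative_binomial", np.nan
    nb = sm.NegativeBinomial(y, X)
    for method in ("newton", "bfgs", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small-n NB fits warn freely; we check below
                res = nb.fit(start_params=start, method=method, disp=0, maxiter=500)
        except Exception as exc:
            logger.debug("NB fit via %s raised %s", method, exc)
            continue
        # only the log-S slope needs a usable SE: a constant citations
        # column (legal input) leaves its own SE NaN by collinearity
        ok = (
            res.mle_retvals.get("converged", True)
            and np.all(np.isfinite(res.params))
            and np.isfinite(res.bse[1])
            and res.bse[1] > 0
        )
        if ok:
            params, bse = res.params, res.bse
            nb_alpha = float(res.params[-1])
            break

    if params is None:
        logger.warning("NB snapshot fit degenerated (n=%d); Poisson fallback", len(rows))
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        params, bse = res.params, res.bse
        family_used, nb_alpha = "poisson", 0.0

    slope, se = float(params[1]), float(bse[1])
    if not np.isfinite(se) or se <= 0:
        raise RuntimeError("snapshot GLM did not converge: non-finite standard error")
    ci = (slope - Z95 * se, slope + Z95 * se)
    return GlmResult(
        snapshot_year=snapshot_year,
        slope_logS=slope,
        se=se,
        ci95=ci,
        slope_logC=float(params[2]),
        dispersion=nb_alpha,
        positive_detected=bool(ci[0] > 0),
        family_used=family_used,
        n_orders=len(rows),
    )


def snapshot_sweep(
    pairs: pd.DataFrame,
    species_table: pd.DataFrame,
    citations_table: pd.DataFrame,
    years=(1990, 1995, 2000, 2005, 2010, 2015, 2020),
) -> tuple[list[GlmResult], pd.DataFrame]:
    """Fit the snapshot GLM at each year; failures are logged, not fatal.

    Returns the list of successful :class:`GlmResult` s and a detection
    table (year, positive_detected, error) covering every requested year.
    """
    years = list(years)
    if any(b <= a for a, b in zip(years, years[1:])):
        raise ValueError("years must be strictly ascending")
    results: list[GlmResult] = []
    rows = []
    for year in years:
        try:
            snap = build_snapshot(pairs, species_table, citations_table, year)
            res = fit_snapshot_glm(snap, snapshot_year=year)
        except (ValueError, RuntimeError) as exc:
            logger.warning("snapshot %d failed: %s", year, exc)
            rows.append({"year": year, "positive_detected": pd.NA, "error": str(exc)})
            continue
        results.append(res)
        rows.append({"year": year, "positive_detected": res.positive_detected, "error": ""})
    return results, pd.DataFrame(rows)
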