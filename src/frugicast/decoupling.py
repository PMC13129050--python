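"""Richness–function decoupling.

Richness and dispersal-function maps are put on a common 0–1 scale by
min–max normalization over a shared cell domain,
``x' = (x − min x) / (max x − min x)``, and the decoupling index is the
per-cell difference ``D = function' − richness'``, bounded in [−1, +1]:
negative where richness overestimates function, positive where it
underestimates it, zero under perfect agreement.  Cells are classified
with an agreement half-width ε around zero, and the strength of coupling
is quantified by an ordinary-least-squares fit of per-cell functional
change on richness change with heteroskedasticity-consistent (HC3)
standard errors, restricted to cells where the plant persists under both
climates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grids import BinaryRangeMap, GridSpec, check_same_grid

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedMap",
    "DecouplingMap",
    "DecouplingClassification",
    "RobustFit",
    "minmax_normalize",
    "decoupling_index",
    "classify_decoupling",
    "stable_cells",
    "fit_richness_function_model",
]


@dataclass
class NormalizedMap:
    """A map rescaled to [0, 1] over an explicit cell domain (boolean mask).

    Cells outside the domain are NaN.  A degenerate input (constant over the
    domain) normalizes to all zeros — flagged in the log — so downstream
    classification still runs.
    """

    values: np.ndarray
    domain: np.ndarray
    source_metric: str = ""

    def __post_init__(self) -> None:
        self.domain = np.asarray(self.domain, dtype=bool)
        if self.values.shape != self.domain.shape:
            raise ValueError("values and domain must share a shape")


@dataclass
class DecouplingMap:
    """Per-cell function-minus-richness index in [−1, 1]."""

    D: np.ndarray
    metric: str
    scenario: str
    domain: np.ndarray = field(repr=False)


@dataclass
class DecouplingClassification:
    """Share of the domain where richness over-/under-estimates function.

    ``category`` holds per-cell codes: -1 over (richness overestimates,
    D < −ε), 0 match (|D| ≤ ε), +1 under (D > ε); fractions are percentages
    of defined cells and sum to 100.
    """

    epsilon: float
    category: np.ndarray
    pct_over: float
    pct_match: float
    pct_under: float


@dataclass(frozen=True)
class RobustFit:
    """OLS fit with HC3 covariance: slope of functional change on richness change."""

    slope: float
    intercept: float
    r_squared: float
    hc3_se: tuple[float, float]  # (intercept, slope)
    p_values: tuple[float, float]
    n: int


def minmax_normalize(
    values: np.ndarray, domain: np.ndarray | None = None, source_metric: str = ""
) -> NormalizedMap:
    """Min–max rescale to [0, 1] over the domain cells.

    The domain defaults to all finite cells.  If the map is constant over
    the domain the result is all zeros (logged as a warning) rather than an
    error, so a completely uniform landscape still classifies as agreement.
    """
    values = np.asarray(values, dtype=float)
    if domain is None:
        domain = np.isfinite(values)
    domain = np.asarray(domain, dtype=bool) & np.isfinite(values)
    if not domain.any():
        raise ValueError("normalization domain is empty")
    sub = values[domain]
    lo, hi = sub.min(), sub.max()
    out = np.full(values.shape, np.nan)
    if hi == lo:
        log.warning(
            "degenerate min-max normalization (%s): map constant at %g over "
            "%d cells; returning zeros", source_metric or "unnamed", lo, domain.sum()
        )
        out[domain] = 0.0
    else:
        out[domain] = (sub - lo) / (hi - lo)
    return NormalizedMap(out, domain, source_metric)


def decoupling_index(
    func_norm: NormalizedMap, rich_norm: NormalizedMap, metric: str = "", scenario: str = ""
) -> DecouplingMap:
    """D = normalized function − normalized richness, per cell, in [−1, 1]."""
    if func_norm.values.shape != rich_norm.values.shape or not np.array_equal(
        func_norm.domain, rich_norm.domain
    ):
        raise ValueError("function and richness maps must share grid and domain")
    D = np.full(func_norm.values.shape, np.nan)
    dom = func_norm.domain
    D[dom] = func_norm.values[dom] - rich_norm.values[dom]
    return DecouplingMap(D, metric, scenario, dom)


def classify_decoupling(dmap: DecouplingMap, epsilon: float = 0.05) -> DecouplingClassification:
    """Split the domain into over / match / under at half-width ε.

    over: D < −ε (richness overestimates function); match: |D| ≤ ε;
    under: D > ε.  Fractions are percentages of defined cells.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    D = dmap.D
    dom = dmap.domain & np.isfinite(D)
    n = int(dom.sum())
    if n == 0:
        raise ValueError("no defined cells to classify")
    cat = np.full(D.shape, np.nan)
    cat[dom] = 0
    cat[dom & (D < -epsilon)] = -1
    cat[dom & (D > epsilon)] = 1
    pct_over = 100.0 * np.sum(cat[dom] == -1) / n
    pct_match = 100.0 * np.sum(cat[dom] == 0) / n
    pct_under = 100.0 * np.sum(cat[dom] == 1) / n
    return DecouplingClassification(epsilon, cat, pct_over, pct_match, pct_under)


def stable_cells(plant_current: BinaryRangeMap, plant_future: BinaryRangeMap) -> np.ndarray:
    """Boolean mask of cells suitable for the plant under both climates."""
    check_same_grid(plant_current.grid, plant_future.grid)
    return (plant_current.presence == 1) & (plant_future.presence == 1)


def fit_richness_function_model(
    delta_function: np.ndarray, delta_richness: np.ndarray
) -> RobustFit:
    """OLS of per-cell functional change (%) on richness change (%), with
    HC3 heteroskedasticity-consistent standard errors.

    Non-finite pairs are dropped.  The HC3 covariance inflates each squared
    residual by ``(1 − h_ii)^−2`` with ``h_ii`` the hat-matrix leverage;
    p-values are two-sided from the t distribution with n − 2 df.
    """
    y = np.asarray(delta_function, dtype=float).ravel()
    x = np.asarray(delta_richness, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 cells to fit")
    if np.ptp(x) == 0:
        raise ValueError("richness change is constant; slope undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit(cov_type="HC3", use_t=True)
    return RobustFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        hc3_se=(float(fit.bse[0]), float(fit.bse[1])),
        p_values=(float(fit.pvalues[0]), float(fit.pvalues[1])),
        n=int(x.size),
    )


def histogram_frame(dmap: DecouplingMap, grid: GridSpec, bins: int = 40) -> pd.DataFrame:
    """Binned distribution of D over the domain, as cell counts and km²."""
    vals = dmap.D[dmap.domain & np.isfinite(dmap.D)]
    counts, edges = np.histogram(vals, bins=bins, range=(-1.0, 1.0))
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "n_cells": counts,
            "area_km2": counts * grid.cell_area,
        }
    )
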