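"""Model-agnostic interpretation: ICE curves, PDPs, threshold regions.

An individual-conditional-expectation (ICE) curve fixes one feature at each
grid value in turn and records the model's predicted probability for one
patient with every other feature untouched; the partial-dependence (PDP)
curve is the pointwise arithmetic mean of the ICE curves. Curves are
computed on the probability scale.

The grid defaults to 50 equally spaced points between the 1st and 99th
percentile of the observed feature. Therapy-stratified PDPs recompute the
curve inside each therapy-potency stratum, which is how the age and LDL-C
risk regions per treatment level are read off; ``threshold_summary``
reports, at grid resolution, where a PDP exceeds a probability cutoff
(never an interpolated "exact" threshold).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fhrisk")


@dataclass(frozen=True)
class ICEBundle:
    variable: str
    grid: np.ndarray  # strictly increasing
    curves: np.ndarray  # (n_patients, n_grid) predicted probabilities
    stratum: str = "all"

    def __post_init__(self):
        if self.curves.shape[1] != len(self.grid):
            raise ValueError("each curve needs one value per grid point")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass(frozen=True)
class PDPCurve:
    variable: str
    grid: np.ndarray
    values: np.ndarray  # mean prediction per grid point
    stratum: str = "all"
    n_patients: int = 0


def default_grid(values: Sequence[float], n_points: int = 50,
                 lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    """Equally spaced grid between the 1st and 99th percentile."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.percentile(v, [lo_pct, hi_pct])
    if lo == hi:
        raise ValueError("degenerate feature: percentile range is empty")
    return np.linspace(lo, hi, n_points)


def ice(predict_proba: Callable[[np.ndarray], np.ndarray],
        X: pd.DataFrame, variable: str,
        grid: np.ndarray | None = None, n_points: int = 50,
        max_patients: int | None = None, seed: int = 0,
        stratum: str = "all") -> ICEBundle:
    """ICE curves for one feature of a fitted probability model.

    ``predict_proba`` maps a feature matrix (columns in ``X``'s order) to
    P(high risk). ``max_patients`` optionally subsamples rows (seeded) —
    the usual cost control for expensive models.
    """
    if variable not in X.columns:
        raise KeyError(f"{variable!r} not among the model features")
    if grid is None:
        grid = default_grid(X[variable], n_points)
    grid = np.asarray(grid, dtype=float)
    obs_lo, obs_hi = X[variable].min(), X[variable].max()
    if grid[0] < obs_lo or grid[-1] > obs_hi:
        warnings.warn(f"{variable}: grid extends outside the observed range "
                      f"[{obs_lo}, {obs_hi}]; curves computed anyway")
    rows = X
    if max_patients is not None and len(X) > max_patients:
        rng = np.random.default_rng(seed)
        rows = X.iloc[np.sort(rng.choice(len(X), max_patients, replace=False))]
    base = rows.to_numpy(dtype=float)
    col = list(X.columns).index(variable)
    n, g = len(base), len(grid)
    # one big batch: patient-major blocks, grid-minor
    tiled = np.repeat(base, g, axis=0)
    tiled[:, col] = np.tile(grid, n)
    preds = np.asarray(predict_proba(tiled), dtype=float).reshape(n, g)
    return ICEBundle(variable=variable, grid=grid, curves=preds, stratum=stratum)


def pdp(bundle: ICEBundle) -> PDPCurve:
    """Pointwise mean of the ICE curves."""
    if bundle.curves.shape[0] == 0:
        raise ValueError("empty ICE bundle")
    return PDPCurve(variable=bundle.variable, grid=bundle.grid,
                    values=bundle.curves.mean(axis=0), stratum=bundle.stratum,
                    n_patients=bundle.curves.shape[0])


def stratified_pdp(predict_proba: Callable[[np.ndarray], np.ndarray],
                   X: pd.DataFrame, variable: str,
                   strata: Sequence, grid: np.ndarray | None = None,
                   n_points: int = 50, max_patients: int | None = None,
                   seed: int = 0) -> dict[str, PDPCurve]:
    """One PDP per stratum (e.g. therapy level), on a shared grid."""
    strata = np.asarray(strata)
    if len(strata) != len(X):
        raise ValueError("stratifier length differs from the cohort")
    if grid is None:
        grid = default_grid(X[variable], n_points)
    curves: dict[str, PDPCurve] = {}
    for value in pd.unique(strata):
        mask = strata == value
        if not mask.any():
            warnings.warn(f"empty stratum {value!r} omitted")
            continue
        bundle = ice(predict_proba, X.loc[mask], variable, grid=grid,
                     max_patients=max_patients, seed=seed, stratum=str(value))
        curves[str(value)] = pdp(bundle)
        logger.info("stratum %s: %d patients", value, int(mask.sum()))
    return curves


@dataclass(frozen=True)
class ThresholdRegion:
    """Grid interval on which a PDP exceeds the probability cutoff."""

    stratum: str
    variable: str
    cutoff: float
    first_above: float | None  # lowest grid value with PDP > cutoff
    last_above: float | None   # highest grid value with PDP > cutoff
    empty: bool


def threshold_summary(curves: dict[str, PDPCurve],
                      probability_cutoff: float) -> dict[str, ThresholdRegion]:
    """Where each stratum's PDP exceeds the cutoff, at grid resolution."""
    out = {}
    for stratum, curve in curves.items():
        above = np.flatnonzero(curve.values > probability_cutoff)
        if above.size == 0:
            out[stratum] = ThresholdRegion(stratum, curve.variable,
                                           probability_cutoff, None, None, True)
        else:
            out[stratum] = ThresholdRegion(
                stratum, curve.variable, probability_cutoff,
                float(curve.grid[above[0]]), float(curve.grid[above[-1]]), False)
    return out


def curves_to_frame(objects: Sequence[ICEBundle | PDPCurve]) -> pd.DataFrame:
    """Tidy export: variable, stratum, curve id (patient index or PDP), grid, value."""
    rows = []
    for obj in objects:
        if isinstance(obj, PDPCurve):
            for gval, pval in zip(obj.grid, obj.values):
                rows.append((obj.variable, obj.stratum, "PDP", float(gval), float(pval)))
        else:
            for i, curve in enumerate(obj.curves):
                for gval, pval in zip(obj.grid, curve):
                    rows.append((obj.variable, obj.stratum, str(i), float(gval), float(pval)))
    return pd.DataFrame(rows, columns=["variable", "stratum", "curve",
                                       "grid_value", "prediction"])
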