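"""Post-fit inference and management-scenario simulation.

All quantities derive from a fitted weighted model of sqrt(% bleached) on
standardized drivers.  Predictions are squared back to the percent scale
and clipped to [0, 100]; sub-zero sqrt-scale predictions clip to 0 and are
logged, since they indicate extrapolation outside the fitted range.

* **Partial regression** — the marginal curve of one driver with all other
  drivers at their means, relative to the intercept of the reduced model
  refit without the driver and its interactions; residuals of the reduced
  model (back-transformed, weight-carrying) are the points.
* **Perturbation** — mean predicted bleaching when each driver in turn is
  moved ±1 SD with everything else at its mean.
* **Management scenario** — per analysis cell, acute thermal stress is
  pinned at a high quantile (default the 95th percentile of the fitted
  event) while each manageable driver in turn is reduced by 1 SD from its
  observed value; the best action per cell is the largest predicted
  bleaching reduction, ties resolving alphabetically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import INTERCEPT, FittedModel, fit_terms, term_parents

logger = logging.getLogger(__name__)

#: Drivers a manager could plausibly act on.
DEFAULT_MANAGEABLE_DRIVERS = (
    "bs_score",
    "par",
    "sewage_effluent",
    "tourism",
    "urban_runoff",
)
SCENARIO_DHW_QUANTILE = 0.95


def model_drivers(model: FittedModel) -> "list[str]":
    """Distinct driver columns the model's terms reference."""
    out: set[str] = set()
    for t in model.terms:
        if t == INTERCEPT:
            continue
        parents = term_parents(t)
        out.update(parents if parents else (t,))
    return sorted(out)


def predict_bleached(model: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Back-transformed percent-bleached prediction, clipped to [0, 100]."""
    sqrt_pred = model.predict_sqrt(rows)
    n_neg = int((sqrt_pred < 0).sum())
    if n_neg:
        logger.info("%d sqrt-scale predictions below 0 clipped (extrapolation)", n_neg)
    return np.clip(np.clip(sqrt_pred, 0.0, None) ** 2, 0.0, 100.0)


def _mean_rows(model: FittedModel, n: int = 1) -> pd.DataFrame:
    """Rows with every driver at its (standardized) mean of zero."""
    return pd.DataFrame(0.0, index=range(n), columns=model_drivers(model))


@dataclass
class PartialRegression:
    driver: str
    grid: np.ndarray            # driver values (standardized scale)
    curve: np.ndarray           # back-transformed partial prediction
    residual_x: np.ndarray      # observed driver values
    residual_y: np.ndarray      # back-transformed reduced-model residuals
    residual_weight: np.ndarray


def reduced_terms(model: FittedModel, driver: str) -> "list[str]":
    """Model terms with ``driver`` and every interaction involving it removed."""
    return [
        t for t in model.terms
        if t != driver and driver not in term_parents(t)
    ]


def partial_regression(
    model: FittedModel,
    data: pd.DataFrame,
    driver: str,
    response: str = "sqrt_pct_bleached",
    weight_col: str = "weight",
    grid_n: int = 100,
) -> PartialRegression:
    """Partial-regression curve and residual points for one selected driver.

    The reduced model refits the selected terms without the driver and its
    interactions.  The curve is the full model's back-transformed prediction
    across the driver's observed range (other drivers at their means) minus
    the reduced model's back-transformed intercept; the points are the
    reduced model's residuals, back-transformed with sign preserved, at the
    observed driver values, carrying the observation weights.
    """
    if driver not in model.terms:
        raise ValueError(f"driver {driver!r} is not a term of the selected model")
    red = fit_terms(data, reduced_terms(model, driver), response, weight_col)
    x_obs = data[driver].to_numpy(dtype=float)
    grid = np.linspace(x_obs.min(), x_obs.max(), grid_n)
    rows = _mean_rows(model, n=grid_n)
    rows[driver] = grid
    curve = predict_bleached(model, rows) - float(red.params[INTERCEPT]) ** 2
    resid = red.resid
    resid_back = np.sign(resid) * resid**2
    return PartialRegression(
        driver=driver,
        grid=grid,
        curve=curve,
        residual_x=x_obs,
        residual_y=resid_back,
        residual_weight=data[weight_col].to_numpy(dtype=float),
    )


@dataclass
class InteractionSurface:
    driver_a: str
    driver_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    surface: np.ndarray  # shape (len(grid_a), len(grid_b)), percent bleached
    points: pd.DataFrame  # observed (a, b) pairs


def interaction_surface(
    model: FittedModel,
    data: pd.DataFrame,
    driver_a: str,
    driver_b: str,
    grid_n: int = 25,
) -> InteractionSurface:
    """Predicted bleaching over the joint range of two interacting drivers.

    All other drivers are held at their mean (zero on the standardized
    scale).  Requires the a x b interaction in the selected model.
    """
    from .model import interaction_name

    if interaction_name(driver_a, driver_b) not in model.terms:
        raise ValueError(f"no {driver_a} x {driver_b} interaction in the model")
    a_obs = data[driver_a].to_numpy(dtype=float)
    b_obs = data[driver_b].to_numpy(dtype=float)
    grid_a = np.linspace(a_obs.min(), a_obs.max(), grid_n)
    grid_b = np.linspace(b_obs.min(), b_obs.max(), grid_n)
    ga, gb = np.meshgrid(grid_a, grid_b, indexing="ij")
    rows = _mean_rows(model, n=ga.size)
    rows[driver_a] = ga.ravel()
    rows[driver_b] = gb.ravel()
    surface = predict_bleached(model, rows).reshape(ga.shape)
    return InteractionSurface(
        driver_a=driver_a,
        driver_b=driver_b,
        grid_a=grid_a,
        grid_b=grid_b,
        surface=surface,
        points=pd.DataFrame({driver_a: a_obs, driver_b: b_obs}),
    )


def perturb_model(model: FittedModel, drivers: "list[str] | None" = None) -> pd.DataFrame:
    """±1 SD single-driver perturbations about the all-at-means baseline.

    With centered predictors every interaction vanishes at the baseline row,
    so the baseline equals the squared intercept exactly.  Returns one row
    per driver x direction with the back-transformed predicted percent.
    """
    drivers = list(drivers) if drivers is not None else model_drivers(model)
    baseline = float(predict_bleached(model, _mean_rows(model))[0])
    rows = []
    for d in sorted(drivers):
        for direction in (+1.0, -1.0):
            r = _mean_rows(model)
            if d in r.columns:
                r[d] = direction
            pred = float(predict_bleached(model, r)[0])
            rows.append(
                {
                    "driver": d,
                    "direction": "+1sd" if direction > 0 else "-1sd",
                    "predicted_pct_bleached": pred,
                    "baseline_pct_bleached": baseline,
                }
            )
    return pd.DataFrame(rows)


def management_scenario(
    model: FittedModel,
    data: pd.DataFrame,
    manageable: "tuple[str, ...]" = DEFAULT_MANAGEABLE_DRIVERS,
    dhw_quantile: float = SCENARIO_DHW_QUANTILE,
    delta_sd: float = -1.0,
    dhw_col: str = "acute_dhw",
    cell_cols: "tuple[str, ...]" = ("cluster_id", "depth_bin"),
) -> pd.DataFrame:
    """Rank manageable drivers per cell under a simulated heating event.

    Acute thermal stress is pinned at the ``dhw_quantile`` of the analysis
    set for every cell; all other drivers keep their observed values
    (baseline).  Each manageable driver is then shifted by ``delta_sd``
    standardized units in turn and bleaching re-predicted; best_action is
    the largest reduction from the baseline, ties alphabetical.
    """
    manageable = tuple(sorted(manageable))
    if not manageable:
        raise ValueError("manageable driver list is empty")
    drivers = model_drivers(model)
    base = data[[c for c in drivers if c in data.columns]].copy()
    missing = [c for c in drivers if c not in base.columns]
    if missing:
        raise KeyError(f"data lacks model drivers: {missing}")
    dhw_fixed = float(np.quantile(data[dhw_col].to_numpy(dtype=float), dhw_quantile))
    base[dhw_col] = dhw_fixed
    baseline_pred = predict_bleached(model, base)

    out = pd.DataFrame({c: data[c].to_numpy() for c in cell_cols if c in data.columns})
    out["dhw_fixed"] = dhw_fixed
    out["baseline_pct_bleached"] = baseline_pred
    for action in manageable:
        shifted = base.copy()
        if action in shifted.columns:
            shifted[action] = shifted[action] + delta_sd
        out[f"pred_{action}"] = predict_bleached(model, shifted)

    preds = out[[f"pred_{a}" for a in manageable]].to_numpy()
    # manageable is sorted: the first prediction within tolerance of the
    # minimum resolves exact ties alphabetically, robust to float jitter
    best = preds.min(axis=1)
    best_idx = np.argmax(preds <= best[:, None] + 1e-9, axis=1)
    out["best_action"] = [manageable[i] for i in best_idx]
    out["best_reduction"] = out["baseline_pct_bleached"] - best
    return out
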