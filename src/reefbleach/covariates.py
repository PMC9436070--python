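"""Driver covariates for the bleaching model.

Matches environmental and anthropogenic driver values to cluster cells:

* quality masking of ocean-colour rasters where the pixel footprint is
  substantially shallow (bathymetry overlay, > 5 % of area at <= 30 m);
* nearest-pixel extraction with an expanding search radius — if the
  containing pixel is missing, the radius grows until the first valid
  pixel is reached and the mean of all valid pixels within that radius
  is returned (per-variable maximum radius, e.g. 750 m for wave action);
* per-variable monotone transforms (identity / log1p / sqrt) chosen to
  tame right skew, then centring and scaling so every retained column has
  mean 0 and SD 1 over the analysis cells.

Rasters are plain ``xarray.DataArray`` objects with ``lat``/``lon``
coordinate vectors; NaN encodes missing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .spatial import haversine_km

logger = logging.getLogger(__name__)

#: Canonical driver columns of the analysis matrix.
DRIVER_COLUMNS = [
    "acute_dhw",
    "historical_dhw",
    "historical_bleached",
    "bs_score",
    "urban_runoff",
    "sewage_effluent",
    "tourism",
    "par",
    "kd_par",
    "depth",
    "sst_variability",
    "wave_action",
]

DEFAULT_MAX_RADIUS_KM = 8.0
#: Wave-action products are only trusted very near shore.
WAVE_MAX_RADIUS_KM = 0.75
SHALLOW_FRACTION_LIMIT = 0.05
SHALLOW_DEPTH_LIMIT_M = 30.0
MIN_ANALYSIS_CELLS = 30
SKEWNESS_LOG1P_CUTOFF = 1.0

_TRANSFORMS = {
    "identity": (lambda x: x, lambda y: y),
    "log1p": (np.log1p, np.expm1),
    "sqrt": (np.sqrt, np.square),
}


def mask_shallow_pixels(
    ocean_color: xr.DataArray,
    bathymetry: xr.DataArray,
    frac: float = SHALLOW_FRACTION_LIMIT,
    depth_limit_m: float = SHALLOW_DEPTH_LIMIT_M,
) -> xr.DataArray:
    """Mask ocean-colour pixels whose footprint is more than ``frac`` shallow.

    ``bathymetry`` holds positive depths in metres on either the same grid
    (footprint fraction is then 0 or 1) or an integer-factor finer grid, in
    which case the shallow fraction is counted over the block of bathymetry
    sub-pixels under each ocean-colour pixel.  Grids must be co-registered;
    resampling is the caller's job.
    """
    ny, nx = ocean_color.shape
    by, bx = bathymetry.shape
    if by % ny or bx % nx:
        raise ValueError(
            f"bathymetry grid {by}x{bx} is not an integer refinement of {ny}x{nx}"
        )
    fy, fx = by // ny, bx // nx
    shallow = (bathymetry.values <= depth_limit_m).astype(float)
    block = shallow.reshape(ny, fy, nx, fx).mean(axis=(1, 3))
    out = ocean_color.copy(deep=True)
    out.values[block > frac] = np.nan
    n_masked = int((block > frac).sum())
    if n_masked:
        logger.info("masked %d/%d ocean-colour pixels as shallow", n_masked, ny * nx)
    return out


def extract_nearest(
    raster: xr.DataArray,
    lat: float,
    lon: float,
    max_radius_km: float = DEFAULT_MAX_RADIUS_KM,
) -> float:
    """Value at a point with an expanding search for missing pixels.

    If the containing (nearest-centre) pixel is valid its value is returned
    directly.  Otherwise the search radius expands until the first valid
    pixel is reached, and the mean of all valid pixels within that radius
    is returned.  NaN signals an exhausted search; a point outside the
    raster extent is rejected.
    """
    lats = raster["lat"].values
    lons = raster["lon"].values
    dlat = np.abs(np.diff(lats)).max() if len(lats) > 1 else 0.0
    dlon = np.abs(np.diff(lons)).max() if len(lons) > 1 else 0.0
    if not (
        lats.min() - dlat / 2 <= lat <= lats.max() + dlat / 2
        and lons.min() - dlon / 2 <= lon <= lons.max() + dlon / 2
    ):
        raise ValueError(f"point ({lat}, {lon}) outside raster extent")
    values = raster.values
    i = int(np.argmin(np.abs(lats - lat)))
    j = int(np.argmin(np.abs(lons - lon)))
    if np.isfinite(values[i, j]):
        return float(values[i, j])
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    dist = haversine_km(lat, lon, glat, glon)
    valid = np.isfinite(values) & (dist <= max_radius_km)
    if not valid.any():
        return float("nan")
    first_radius = dist[valid].min()
    within = valid & (dist <= first_radius)
    return float(values[within].mean())


@dataclass
class TransformRegistry:
    """Per-variable monotone transform plus fitted centre/scale.

    Recorded so model predictions on the standardized scale can be mapped
    back to natural driver units and vice versa.
    """

    transforms: "dict[str, str]" = field(default_factory=dict)
    centers: "dict[str, float]" = field(default_factory=dict)
    scales: "dict[str, float]" = field(default_factory=dict)

    def fit(self, frame: pd.DataFrame, overrides: "dict[str, str] | None" = None) -> None:
        """Choose transforms (skewness > 1 -> log1p unless overridden) and
        fit centring/scaling moments on the analysis cells."""
        overrides = overrides or {}
        for col in frame.columns:
            name = overrides.get(col)
            if name is None:
                x = frame[col].to_numpy(dtype=float)
                skew = float(pd.Series(x).skew())
                name = "log1p" if (skew > SKEWNESS_LOG1P_CUTOFF and (x >= 0).all()) else "identity"
            if name not in _TRANSFORMS:
                raise ValueError(f"unknown transform {name!r} for {col}")
            self.transforms[col] = name
            t = _TRANSFORMS[name][0](frame[col].to_numpy(dtype=float))
            self.centers[col] = float(np.mean(t))
            sd = float(np.std(t, ddof=1))
            if sd == 0:
                raise ValueError(f"column {col} is constant; cannot standardize")
            self.scales[col] = sd

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in frame.columns:
            if col not in self.transforms:
                raise KeyError(f"column {col} not in registry")
            fwd = _TRANSFORMS[self.transforms[col]][0]
            out[col] = (fwd(frame[col].to_numpy(dtype=float)) - self.centers[col]) / self.scales[col]
        return pd.DataFrame(out, index=frame.index)

    def inverse(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in frame.columns:
            inv = _TRANSFORMS[self.transforms[col]][1]
            out[col] = inv(frame[col].to_numpy(dtype=float) * self.scales[col] + self.centers[col])
        return pd.DataFrame(out, index=frame.index)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"transforms": self.transforms, "centers": self.centers, "scales": self.scales},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "TransformRegistry":
        with open(path) as fh:
            d = json.load(fh)
        return cls(transforms=d["transforms"], centers=d["centers"], scales=d["scales"])


@dataclass
class DriverMatrix:
    """Standardized predictor set per analysis cell plus its registry."""

    cells: pd.DataFrame          # cell metadata (cluster_id, depth_bin, zone, weight, response)
    design: pd.DataFrame         # standardized driver columns, same index
    registry: TransformRegistry
    dropped: pd.DataFrame        # cell key + reason for every exclusion


def build_driver_matrix(
    cells: pd.DataFrame,
    raster_vars: "dict[str, xr.DataArray] | None" = None,
    site_indices: "pd.DataFrame | None" = None,
    transform_overrides: "dict[str, str] | None" = None,
    max_radius_km: "dict[str, float] | None" = None,
    exclude_deep: bool = True,
    driver_columns: "list[str] | None" = None,
) -> DriverMatrix:
    """Assemble, transform and standardize the per-cell driver matrix.

    Deep (> 18 m) cells are excluded up front; raster variables are
    extracted at cell centroids with the expanding-radius rule; site-index
    variables join on ``cluster_id`` (or on (cluster_id, depth_bin) when the
    index table carries a depth_bin column).  Cells with any missing driver
    are dropped with a logged per-variable reason.  Transforms and
    centring/scaling are fitted on the surviving analysis set.
    """
    driver_columns = driver_columns or DRIVER_COLUMNS
    radii = {"wave_action": WAVE_MAX_RADIUS_KM}
    radii.update(max_radius_km or {})
    df = cells.copy()
    dropped: list[dict] = []

    if exclude_deep:
        deep = df["depth_bin"] == "deep"
        for _, row in df[deep].iterrows():
            dropped.append(
                {"cluster_id": row["cluster_id"], "depth_bin": row["depth_bin"],
                 "reason": "depth_bin:deep"}
            )
        df = df[~deep].copy()

    for var, raster in (raster_vars or {}).items():
        r = radii.get(var, DEFAULT_MAX_RADIUS_KM)
        df[var] = [
            extract_nearest(raster, row["lat"], row["lon"], max_radius_km=r)
            for _, row in df.iterrows()
        ]
    if site_indices is not None:
        join_keys = ["cluster_id"]
        if "depth_bin" in site_indices.columns:
            join_keys.append("depth_bin")
        overlap = [c for c in site_indices.columns if c in df.columns and c not in join_keys]
        df = df.merge(site_indices.drop(columns=overlap), on=join_keys, how="left")

    present = [c for c in driver_columns if c in df.columns]
    absent = [c for c in driver_columns if c not in df.columns]
    if absent:
        raise ValueError(f"driver columns never supplied: {absent}")

    missing_any = df[present].isna().any(axis=1)
    for _, row in df[missing_any].iterrows():
        reasons = [f"{c}:missing" for c in present if pd.isna(row[c])]
        dropped.append(
            {"cluster_id": row["cluster_id"], "depth_bin": row["depth_bin"],
             "reason": ";".join(reasons)}
        )
    df = df[~missing_any].reset_index(drop=True)
    if len(df) < MIN_ANALYSIS_CELLS:
        logger.warning(
            "only %d analysis cells survive; model estimates may be unstable", len(df)
        )

    registry = TransformRegistry()
    registry.fit(df[present], overrides=transform_overrides)
    design = registry.transform(df[present])
    meta = df.drop(columns=present)
    return DriverMatrix(
        cells=meta,
        design=design,
        registry=registry,
        dropped=pd.DataFrame(dropped, columns=["cluster_id", "depth_bin", "reason"]),
    )


def raster_from_grid(values: np.ndarray, lats: np.ndarray, lons: np.ndarray) -> xr.DataArray:
    """Convenience constructor for a lat/lon raster."""
    return xr.DataArray(
        np.asarray(values, dtype=float),
        coords={"lat": np.asarray(lats, dtype=float), "lon": np.asarray(lons, dtype=float)},
        dims=("lat", "lon"),
    )


def raster_to_csv(raster: xr.DataArray, path) -> None:
    """Write a raster as a long-format CSV (lat, lon, value)."""
    raster.to_dataframe(name="value").reset_index().to_csv(path, index=False)


def raster_from_csv(path) -> xr.DataArray:
    frame = pd.read_csv(path)
    pivot = frame.pivot(index="lat", columns="lon", values="value")
    return raster_from_grid(pivot.values, pivot.index.values, pivot.columns.values)
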