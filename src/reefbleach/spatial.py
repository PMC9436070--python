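"""Spatial aggregation of bleaching surveys into analysis cells.

Surveys within 1 km of one another (irrespective of depth) form a spatial
cluster; within a cluster, surveys in the same depth bin are combined to a
single mean percent-bleached estimate.  A (zone, depth bin) stratum with
fewer than three such cell estimates is dropped.  Each surviving cell gets
an analysis weight: the inverse standard error of its mean, capped at the
95th percentile of raw weights, rescaled so weights lie in (0, 1], with
single-survey cells (undefined SE) assigned the 5th-percentile raw weight.

Clustering uses complete linkage on great-circle (haversine) distance so
"within 1 km of one another" is honoured as a cluster-diameter constraint;
single linkage would allow chains exceeding 1 km.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius
CLUSTER_THRESHOLD_KM = 1.0
MIN_CELLS_PER_ZONE_DEPTH = 3
WEIGHT_CAP_PERCENTILE = 95.0
MISSING_SE_PERCENTILE = 5.0

#: Depth bins (m): half-open upper-inclusive intervals, 0 belongs to shallow.
DEPTH_BIN_EDGES = {"shallow": (0.0, 6.0), "mid": (6.0, 18.0), "deep": (18.0, 30.0)}
DEPTH_BIN_ORDER = ["shallow", "mid", "deep"]


def assign_depth_bin(depth_m: float) -> str:
    """Map a survey depth in metres to shallow (0-6], mid (6-18] or deep (18-30]."""
    if not np.isfinite(depth_m) or depth_m < 0 or depth_m > 30:
        raise ValueError(f"depth {depth_m} m outside surveyable range [0, 30]")
    if depth_m <= 6.0:
        return "shallow"
    if depth_m <= 18.0:
        return "mid"
    return "deep"


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (vectorised)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Condensed pairwise great-circle distance matrix (scipy pdist order)."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    full = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    # enforce exact symmetry/zero diagonal against floating jitter
    full = (full + full.T) / 2.0
    np.fill_diagonal(full, 0.0)
    return squareform(full, checks=False)


def cluster_surveys(
    surveys: pd.DataFrame, threshold_km: float = CLUSTER_THRESHOLD_KM
) -> pd.Series:
    """Assign cluster ids by complete-linkage clustering cut at ``threshold_km``.

    Every within-cluster pairwise distance is <= the threshold.  Cluster ids
    are relabelled by the lowest survey index they contain, which makes the
    labelling deterministic and permutation-stable up to relabelling.
    """
    lat = surveys["lat"].to_numpy(dtype=float)
    lon = surveys["lon"].to_numpy(dtype=float)
    if not (np.isfinite(lat).all() and np.isfinite(lon).all()):
        raise ValueError("non-finite coordinates")
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise ValueError("latitude/longitude outside valid range")
    if len(surveys) == 1:
        return pd.Series([0], index=surveys.index, name="cluster_id")
    condensed = pairwise_haversine_km(lat, lon)
    tree = linkage(condensed, method="complete")
    raw = fcluster(tree, t=threshold_km, criterion="distance")
    # relabel clusters in order of first appearance (lowest survey index)
    order: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    return pd.Series(labels, index=surveys.index, name="cluster_id")


@dataclass
class ClusterCell:
    cluster_id: int
    island: str
    zone: str
    depth_bin: str
    n: int
    mean_pct_bleached: float
    se_pct_bleached: float  # NaN when n == 1
    mean_bs: float
    lat: float
    lon: float


def aggregate_cells(surveys: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    """Aggregate surveys to cluster x depth-bin cells.

    Returns one row per cell with n, mean and SE of percent bleached
    (SE = sample SD / sqrt(n), missing when n = 1), mean BS where present,
    and the centroid coordinates.
    """
    df = surveys.copy()
    df["cluster_id"] = clusters.to_numpy()
    if "depth_bin" not in df.columns:
        df["depth_bin"] = [assign_depth_bin(d) for d in df["depth_m"]]

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        vals = g["pct_bleached"].to_numpy(dtype=float)
        out = {
            "island": g["island"].iloc[0] if "island" in g.columns else "",
            "zone": g["zone"].iloc[0] if "zone" in g.columns else "",
            "n": n,
            "mean_pct_bleached": float(vals.mean()),
            "se_pct_bleached": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
            "lat": float(g["lat"].mean()),
            "lon": float(g["lon"].mean()),
        }
        if "bs" in g.columns:
            out["mean_bs"] = float(g["bs"].mean())
        return pd.Series(out)

    cells = (
        df.groupby(["cluster_id", "depth_bin"], sort=True)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    cells["n"] = cells["n"].astype(int)
    n_singleton = int((cells["n"] == 1).sum())
    if n_singleton:
        logger.info("%d cells have n=1 (SE undefined)", n_singleton)
    return cells


def filter_zone_depth(
    cells: pd.DataFrame, min_cells: int = MIN_CELLS_PER_ZONE_DEPTH
) -> pd.DataFrame:
    """Drop every (zone, depth_bin) stratum with fewer than ``min_cells`` cells."""
    counts = cells.groupby(["zone", "depth_bin"])["cluster_id"].transform("count")
    kept = cells[counts >= min_cells].reset_index(drop=True)
    dropped = len(cells) - len(kept)
    if dropped:
        logger.info(
            "zone/depth filter dropped %d cells in under-replicated strata", dropped
        )
    return kept


def compute_weights(
    cells: pd.DataFrame,
    cap_percentile: float = WEIGHT_CAP_PERCENTILE,
    missing_percentile: float = MISSING_SE_PERCENTILE,
) -> pd.Series:
    """Inverse-SE analysis weights scaled into (0, 1].

    Raw weight = 1/SE over cells with a defined, positive SE.  Weights above
    the ``cap_percentile`` of raw weights are capped at it; everything is
    then divided by that percentile.  Cells whose SE is missing (n = 1) or
    zero are assigned the ``missing_percentile`` raw weight before scaling.
    Percentiles use linear interpolation between order statistics.
    """
    se = cells["se_pct_bleached"].to_numpy(dtype=float)
    defined = np.isfinite(se) & (se > 0)
    if not defined.any():
        raise ValueError("no cells with a defined positive SE; weights undefined")
    raw_defined = 1.0 / se[defined]
    cap = float(np.percentile(raw_defined, cap_percentile))
    floor = float(np.percentile(raw_defined, missing_percentile))
    raw = np.empty(len(se))
    raw[defined] = raw_defined
    raw[~defined] = floor
    weights = np.minimum(raw, cap) / cap
    out = pd.Series(weights, index=cells.index, name="weight")
    if not ((out > 0) & (out <= 1)).all():
        raise AssertionError("weights escaped (0, 1]")
    return out


def assign_zones(
    cells: pd.DataFrame,
    zone_map: "dict[int, str] | None" = None,
    zone_polygons: "dict[str, object] | None" = None,
) -> pd.DataFrame:
    """Attach zone labels from a cluster_id->zone map or GeoJSON-style polygons.

    Polygon membership uses shapely point-in-polygon on the cell centroid;
    the explicit map wins where both are given.
    """
    out = cells.copy()
    if zone_polygons:
        from shapely.geometry import Point, shape

        shapes = {name: shape(geom) for name, geom in zone_polygons.items()}

        def _locate(row) -> str:
            p = Point(row["lon"], row["lat"])
            for name, geom in shapes.items():
                if geom.contains(p) or geom.touches(p):
                    return name
            return ""

        out["zone"] = out.apply(_locate, axis=1)
    if zone_map:
        mapped = out["cluster_id"].map(zone_map)
        out["zone"] = mapped.fillna(out.get("zone", "")).astype(str)
    return out
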