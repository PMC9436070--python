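"""Synthetic bleaching-survey bundles with a known ground truth.

Generates the three input families the analysis consumes — survey tables,
daily SST series, and environmental/anthropogenic driver fields — from an
explicit linear model on the square-root percent-bleached scale, so every
downstream stage (clustering, weighting, covariate matching, model
selection, scenarios) has a recoverable truth.

Construction, in the order the data are built:

1. Cluster geometry is a deterministic hexagonal layout per zone plus
   jitter, sized so that surveys within a cluster are < 1 km of one
   another and distinct clusters are > 2 km apart — the downstream
   1-km complete-linkage clustering therefore recovers the generating
   clusters exactly.
2. Latent drivers are drawn per cluster x depth-bin cell as correlated
   standard Gaussians, winsorised at |z| = 3.5, then standardized
   empirically over the analysis cells (depth enters structurally from
   the cell's depth bin).  Natural-scale driver values are monotone maps
   of these scores chosen so the covariate stage's transform + empirical
   standardization reproduces the generating design exactly.
3. Expected sqrt-bleaching is the design row dotted with ``true_beta``;
   cell-level noise N(0, noise_sd) is added on the sqrt scale and the cell
   mean percent is the clipped square.  Replicate surveys draw from a Beta
   distribution on [0, 100] whose mean is the cell percent exactly and
   whose spread follows the proportion mean-variance relation
   (sd proportional to sqrt(p(1-p)), equal to ``within_cluster_sd`` at
   50 % bleaching) — heteroskedastic replication that respects the bounded
   response without clamping bias.  Cells whose latent sqrt mean is
   clamped at 0 still carry a (small) boundary bias; that is documented
   rather than removed.
4. Per-taxon covers realize each cell's susceptibility score exactly by
   mixing the two taxa whose scores bracket it; per-taxon bleaching is
   proportional to the taxon score so the cover-weighted survey values
   stay mutually consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial import DEPTH_BIN_EDGES, haversine_km

KM_PER_DEG_LAT = 111.32

#: taxon code, susceptibility score (1 least .. 5 most), mean cover %
DEFAULT_TAXA = [
    ("PLOB", 1.0, 12.0),   # Porites lobata — massive, stress tolerant
    ("PCOM", 2.0, 8.0),    # Porites compressa
    ("MCAP", 3.0, 6.0),    # Montipora capitata
    ("MFLA", 4.0, 3.0),    # Montipora flabellata
    ("PMEA", 5.0, 2.0),    # Pocillopora meandrina — branching, vulnerable
]

#: Ground-truth coefficients on the sqrt-percent scale over standardized
#: drivers.  Signs follow the fitted driver structure of the 2019 Hawai'i
#: event (historical bleaching, susceptibility and acute heat stress
#: positive; sewage and historical heat stress negative) at moderate
#: magnitudes that keep latent means away from the clamping boundaries.
DEFAULT_TRUE_BETA = {
    "Intercept": 4.0,
    "historical_bleached": 0.8,
    "bs_score": 0.7,
    "acute_dhw": 0.6,
    "urban_runoff": 0.45,
    "depth": 0.4,
    "par": 0.3,
    "sewage_effluent": -0.3,
    "historical_dhw": -0.25,
    "tourism": -0.12,
    "acute_dhw:historical_dhw": 0.4,
    "acute_dhw:tourism": 0.25,
    "bs_score:urban_runoff": 0.25,
    "bs_score:historical_bleached": -0.25,
    "bs_score:depth": 0.2,
}

#: Monotone map from standardized score z to the natural driver scale:
#: transform name (as the covariate registry knows it), offset a, slope b;
#: natural = inverse_transform(a + b z).  log1p-mapped drivers come out
#: right-skewed and positive, as their real counterparts are.
DEFAULT_NATURAL_MAPS = {
    "acute_dhw": ("log1p", 1.79, 0.35),        # °C-weeks, ~0.7–20
    "historical_dhw": ("log1p", 2.20, 0.30),   # °C-weeks
    "historical_bleached": ("log1p", 3.00, 0.30),  # %
    "bs_score": ("identity", 3.0, 0.55),       # community susceptibility 1–5
    "urban_runoff": ("log1p", 1.5, 0.5),       # index
    "sewage_effluent": ("log1p", 1.2, 0.5),    # index
    "tourism": ("log1p", 1.8, 0.6),            # index
    "par": ("identity", 45.0, 5.0),            # mol photons m^-2 d^-1
    "kd_par": ("identity", 0.10, 0.02),        # m^-1
    "sst_variability": ("identity", 1.2, 0.25),  # °C
    "wave_action": ("log1p", 1.0, 0.4),        # index
}

GAUSSIAN_DRIVERS = list(DEFAULT_NATURAL_MAPS)  # depth enters structurally
WINSOR_Z = 3.5


@dataclass
class SstParams:
    """Seasonal cycle + heatwave anomaly for the synthetic SST series."""

    base_mean: float = 26.0        # °C annual mean
    amplitude: float = 1.8         # °C seasonal half-range, peak in September
    heatwave_onset_doy: int = 240  # day of year the anomaly starts (final year)
    peak_anomaly: float = 2.5      # °C boxcar anomaly above the seasonal cycle
    duration_days: int = 42
    noise_sd: float = 0.0
    n_years: int = 6
    start_year: int = 2014


@dataclass
class SimulationConfig:
    """Conditions of a synthetic study; the seed fully determines output."""

    seed: int = 0
    n_islands: int = 4
    zones_per_island: int = 3
    clusters_per_zone: int = 8
    surveys_per_cluster: "tuple[int, int]" = (3, 6)
    depth_bins: "tuple[str, ...]" = ("shallow", "mid", "deep")
    taxa: "list[tuple[str, float, float]]" = field(default_factory=lambda: list(DEFAULT_TAXA))
    true_beta: "dict[str, float]" = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    noise_sd: float = 0.5          # sqrt-% units, cell-level
    within_cluster_sd: float = 5.0  # % units, survey replication
    driver_correlation: float = 0.2  # exchangeable correlation of latent drivers
    sst_params: SstParams = field(default_factory=SstParams)
    cluster_spacing_km: float = 3.2
    survey_jitter_km: float = 0.35  # surveys within this radius of cluster centre
    center_jitter_km: float = 0.15
    zone_extent_km: float = 40.0
    mean_total_cover: float = 25.0  # % live coral cover
    exclude_deep_from_truth: bool = True

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.taxa]
        if any(not 1 <= s <= 5 for s in scores):
            raise ValueError("taxon susceptibility scores must lie in [1, 5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if any(c < 0 for _, _, c in self.taxa):
            raise ValueError("taxon mean covers must be >= 0")

    def rng(self, *salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, *salt]))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline should recover."""

    true_beta: "dict[str, float]"
    cells: pd.DataFrame    # natural drivers + latent mu/pct per cell
    design: pd.DataFrame   # standardized design over analysis cells
    natural_maps: "dict[str, tuple]"

    def expected_sqrt(self) -> np.ndarray:
        from .model import build_design

        terms = list(self.true_beta)
        X = build_design(self.design, terms)
        beta = np.array([self.true_beta[t] for t in terms])
        return X.to_numpy() @ beta


# ---------------------------------------------------------------------------
# SST
# ---------------------------------------------------------------------------

def generate_sst(config: SimulationConfig, island_id: str) -> pd.DataFrame:
    """Daily SST for one island: sinusoid + final-year heatwave + noise.

    The seasonal cycle peaks in early September (around the warmest month
    in Hawai'i); the configured boxcar anomaly is added in the final year.
    Returns a frame with island_id, date, sst.
    """
    p = config.sst_params
    if p.n_years < 5:
        raise ValueError("need >= 5 simulated years for an estimable climatology")
    if p.duration_days < 1:
        raise ValueError("heatwave duration must be >= 1 day")
    start = pd.Timestamp(year=p.start_year, month=1, day=1)
    end = pd.Timestamp(year=p.start_year + p.n_years - 1, month=12, day=31)
    dates = pd.date_range(start, end, freq="D")
    if len(dates) < 365:
        raise ValueError("series must cover at least one year")
    island_index = int(island_id.split("_")[-1]) if "_" in island_id else 0
    doy = dates.day_of_year.to_numpy()
    seasonal = p.base_mean + 0.1 * island_index + p.amplitude * np.cos(
        2 * np.pi * (doy - 250) / 365.25
    )
    sst = seasonal.astype(float)
    final_year = dates.year == (p.start_year + p.n_years - 1)
    in_wave = final_year & (doy >= p.heatwave_onset_doy) & (
        doy < p.heatwave_onset_doy + p.duration_days
    )
    sst = sst + np.where(in_wave, p.peak_anomaly, 0.0)
    if p.noise_sd > 0:
        rng = config.rng(1, island_index)
        sst = sst + rng.normal(0.0, p.noise_sd, size=len(sst))
    return pd.DataFrame({"island_id": island_id, "date": dates, "sst": sst})


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _hex_layout(n: int, spacing_km: float) -> np.ndarray:
    """Deterministic hexagonal grid of n points (km offsets from origin)."""
    cols = int(np.ceil(np.sqrt(n)))
    pts = []
    r = 0
    while len(pts) < n:
        for c in range(cols):
            if len(pts) >= n:
                break
            x = c * spacing_km + (spacing_km / 2 if r % 2 else 0.0)
            y = r * spacing_km * np.sqrt(3) / 2
            pts.append((x, y))
        r += 1
    return np.array(pts)


def _cluster_centres(config: SimulationConfig) -> pd.DataFrame:
    """Place cluster centres per island/zone; rejects infeasible geometry."""
    layout = _hex_layout(config.clusters_per_zone, config.cluster_spacing_km)
    extent = layout.max(axis=0)
    if max(extent) > config.zone_extent_km:
        raise ValueError(
            f"{config.clusters_per_zone} clusters at {config.cluster_spacing_km} km "
            f"spacing exceed the {config.zone_extent_km} km zone extent"
        )
    rng = config.rng(2)
    rows = []
    cluster_id = 0
    for isl in range(config.n_islands):
        lat0 = 19.5 + 1.1 * isl
        lon0 = -156.0 + 1.3 * isl
        for z in range(config.zones_per_island):
            # zones sit on well-separated offsets around the island origin
            zone_lat = lat0 + 0.0
            zone_lon = lon0 + z * (config.zone_extent_km + 3 * config.cluster_spacing_km) / (
                KM_PER_DEG_LAT * np.cos(np.radians(lat0))
            )
            jit = rng.uniform(-config.center_jitter_km, config.center_jitter_km, size=layout.shape)
            for k in range(config.clusters_per_zone):
                x_km, y_km = layout[k] + jit[k]
                rows.append(
                    {
                        "cluster_id": cluster_id,
                        "island": f"island_{isl}",
                        "zone": f"island_{isl}_zone_{z}",
                        "lat": zone_lat + y_km / KM_PER_DEG_LAT,
                        "lon": zone_lon + x_km / (KM_PER_DEG_LAT * np.cos(np.radians(zone_lat))),
                    }
                )
                cluster_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Surveys + ground truth
# ---------------------------------------------------------------------------

def _standardize(col: np.ndarray) -> np.ndarray:
    return (col - col.mean()) / col.std(ddof=1)


def _natural_from_z(name: str, z: np.ndarray, maps: "dict[str, tuple]") -> np.ndarray:
    transform, a, b = maps[name]
    lin = a + b * z
    if transform == "identity":
        return lin
    if transform == "log1p":
        return np.expm1(lin)
    if transform == "sqrt":
        return np.square(lin)
    raise ValueError(f"unknown natural map {transform!r}")


def _replicate_pct(cell_pct: float, within_sd: float, rng: np.random.Generator) -> float:
    """One replicate survey's percent bleached around the cell mean.

    Beta-distributed on [0, 100] with mean exactly ``cell_pct`` and standard
    deviation ``within_sd * sqrt(p(1-p))/0.5`` (the proportion mean-variance
    relation, so spread shrinks toward the 0 and 100 boundaries).  Degenerate
    at the boundaries and when ``within_sd`` is 0.
    """
    m = cell_pct / 100.0
    if within_sd <= 0 or m <= 0.0 or m >= 1.0:
        return float(cell_pct)
    s = (within_sd / 100.0) * np.sqrt(m * (1.0 - m)) / 0.5
    s = min(s, 0.95 * np.sqrt(m * (1.0 - m)))
    nu = m * (1.0 - m) / (s * s) - 1.0
    return float(100.0 * rng.beta(m * nu, (1.0 - m) * nu))


def generate_surveys(config: SimulationConfig) -> "tuple[pd.DataFrame, GroundTruth]":
    """Survey table (one row per survey x taxon) plus the generating truth.

    Cells are cluster x depth-bin units; the ground-truth design is built
    over the analysis cells (deep excluded when configured) so the
    downstream transform/standardize path reproduces it exactly.
    """
    centres = _cluster_centres(config)
    bins = [b for b in ("shallow", "mid", "deep") if b in config.depth_bins]
    cells = centres.loc[centres.index.repeat(len(bins))].reset_index(drop=True)
    cells["depth_bin"] = bins * len(centres)

    rng = config.rng(3)
    # representative cell depth drawn uniformly within the bin
    lo_hi = np.array([DEPTH_BIN_EDGES[b] for b in cells["depth_bin"]])
    cells["depth"] = rng.uniform(lo_hi[:, 0] + 0.5, lo_hi[:, 1])

    if config.exclude_deep_from_truth:
        analysis = (cells["depth_bin"] != "deep").to_numpy()
    else:
        analysis = np.ones(len(cells), dtype=bool)
    n_cells = int(analysis.sum())
    if n_cells < 3:
        raise ValueError("too few analysis cells; increase clusters or zones")

    # correlated latent drivers, winsorised then standardized over analysis cells
    k = len(GAUSSIAN_DRIVERS)
    corr = np.full((k, k), config.driver_correlation)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z_raw = rng.standard_normal((len(cells), k)) @ chol.T
    z_raw = np.clip(z_raw, -WINSOR_Z, WINSOR_Z)

    design = pd.DataFrame(index=cells.index[analysis])
    natural = pd.DataFrame(index=cells.index)
    for j, name in enumerate(GAUSSIAN_DRIVERS):
        z_std = np.empty(len(cells))
        z_std[analysis] = _standardize(z_raw[analysis, j])
        # non-analysis (deep) cells reuse the analysis moments
        mu, sd = (
            z_raw[analysis, j].mean(),
            z_raw[analysis, j].std(ddof=1),
        )
        z_std[~analysis] = (z_raw[~analysis, j] - mu) / sd
        natural[name] = _natural_from_z(name, z_std, DEFAULT_NATURAL_MAPS)
        design[name] = z_std[analysis]
    # depth is structural: standardized representative depth
    depth_all = cells["depth"].to_numpy()
    dmu, dsd = depth_all[analysis].mean(), depth_all[analysis].std(ddof=1)
    natural["depth"] = depth_all
    design["depth"] = (depth_all[analysis] - dmu) / dsd

    truth_cells = pd.concat([cells[["cluster_id", "island", "zone", "depth_bin", "lat", "lon"]],
                             natural.drop(columns="depth"), ], axis=1)
    truth_cells["depth"] = natural["depth"]

    truth = GroundTruth(
        true_beta=dict(config.true_beta),
        cells=truth_cells,
        design=design.reset_index(drop=True),
        natural_maps=dict(DEFAULT_NATURAL_MAPS),
    )

    # latent response per cell
    mu = np.full(len(cells), np.nan)
    mu[analysis] = truth.expected_sqrt()
    # deep cells: reuse the same coefficients on their (off-sample) scores
    if (~analysis).any():
        from .model import build_design

        deep_design = pd.DataFrame(index=cells.index[~analysis])
        for j, name in enumerate(GAUSSIAN_DRIVERS):
            m, s = z_raw[analysis, j].mean(), z_raw[analysis, j].std(ddof=1)
            deep_design[name] = (z_raw[~analysis, j] - m) / s
        deep_design["depth"] = (depth_all[~analysis] - dmu) / dsd
        terms = list(config.true_beta)
        Xd = build_design(deep_design, terms).to_numpy()
        beta = np.array([config.true_beta[t] for t in terms])
        mu[~analysis] = Xd @ beta

    cell_sqrt = mu + rng.normal(0.0, config.noise_sd, size=len(cells))
    cell_pct = np.clip(cell_sqrt, 0.0, 10.0) ** 2
    truth_cells["mu_sqrt"] = mu
    truth_cells["cell_sqrt"] = cell_sqrt
    truth_cells["cell_pct"] = cell_pct
    truth_cells["is_analysis"] = analysis

    # replicate surveys
    taxa_codes = [t for t, _, _ in config.taxa]
    taxa_scores = {t: s for t, s, _ in config.taxa}
    sorted_taxa = sorted(config.taxa, key=lambda x: x[1])
    lo_s, hi_s = config.surveys_per_cluster
    survey_rows = []
    survey_id = 0
    for i, cell in truth_cells.iterrows():
        n_surv = int(rng.integers(lo_s, hi_s + 1))
        bs_target = float(cell["bs_score"])
        # two taxa whose scores bracket the target realize it exactly
        lower = [t for t in sorted_taxa if t[1] <= bs_target]
        upper = [t for t in sorted_taxa if t[1] >= bs_target]
        t_lo = lower[-1] if lower else sorted_taxa[0]
        t_hi = upper[0] if upper else sorted_taxa[-1]
        if t_hi[1] == t_lo[1]:
            f_hi = 1.0
        else:
            f_hi = (bs_target - t_lo[1]) / (t_hi[1] - t_lo[1])
        for _ in range(n_surv):
            theta = rng.uniform(0, 2 * np.pi)
            radius = config.survey_jitter_km * np.sqrt(rng.uniform())
            lat = cell["lat"] + radius * np.sin(theta) / KM_PER_DEG_LAT
            lon = cell["lon"] + radius * np.cos(theta) / (
                KM_PER_DEG_LAT * np.cos(np.radians(cell["lat"]))
            )
            pct = _replicate_pct(float(cell["cell_pct"]), config.within_cluster_sd, rng)
            total_cover = float(np.clip(rng.normal(config.mean_total_cover, 6.0), 3.0, 95.0))
            date = pd.Timestamp("2019-08-20") + pd.Timedelta(days=int(rng.integers(0, 110)))
            depth_m = float(cell["depth"])
            bs = bs_target
            taxa_rows = [
                (t_hi[0], total_cover * f_hi),
                (t_lo[0], total_cover * (1.0 - f_hi)),
            ]
            for taxon, cover in taxa_rows:
                if cover <= 0:
                    continue
                taxon_bleach = float(np.clip(pct * taxa_scores[taxon] / bs, 0.0, 100.0)) if bs > 0 else 0.0
                survey_rows.append(
                    {
                        "survey_id": f"s{survey_id:05d}",
                        "island": cell["island"],
                        "zone": cell["zone"],
                        "cluster_true": int(cell["cluster_id"]),
                        "lat": lat,
                        "lon": lon,
                        "date": date,
                        "depth_m": depth_m,
                        "method": ["visual", "photoquad", "transect"][survey_id % 3],
                        "total_cover": total_cover,
                        "pct_bleached": pct,
                        "taxon": taxon,
                        "cover": cover,
                        "taxon_pct_bleached": taxon_bleach,
                    }
                )
            survey_id += 1
    surveys = pd.DataFrame(survey_rows)
    return surveys, truth


# ---------------------------------------------------------------------------
# Driver fields (rasters + correlated site indices)
# ---------------------------------------------------------------------------

def generate_driver_fields(
    config: SimulationConfig,
    grid_n: int = 40,
    na_fraction: float = 0.1,
    index_correlation: "float | None" = None,
    n_sites: int = 200,
):
    """Gridded driver rasters and correlated per-site anthropogenic indices.

    Rasters (PAR, kdPAR, bathymetry, wave action) are smooth low-order
    fields over the survey domain with rectangular NA blocks occupying
    roughly ``na_fraction`` of pixels (exercising the expanding-radius
    search).  Site indices (urban run-off, sewage, tourism) are drawn with
    the configured pairwise correlation.
    """
    import xarray as xr

    from .covariates import raster_from_grid

    rng = config.rng(4)
    lats = np.linspace(19.0, 19.0 + 5.0, grid_n)
    lons = np.linspace(-157.0, -157.0 + 6.0, grid_n)
    gy, gx = np.meshgrid(np.arange(grid_n), np.arange(grid_n), indexing="ij")

    def _field(base: float, slope: float, noise: float) -> np.ndarray:
        f = base + slope * (gy + gx) / (2 * grid_n) + rng.normal(0, noise, size=gy.shape)
        if na_fraction > 0:
            n_blocks = max(1, int(na_fraction * grid_n * grid_n / 16))
            for _ in range(n_blocks):
                r0 = int(rng.integers(0, grid_n - 4))
                c0 = int(rng.integers(0, grid_n - 4))
                f[r0:r0 + 4, c0:c0 + 4] = np.nan
        return f

    rasters = {
        "par": raster_from_grid(_field(45.0, 8.0, 1.0), lats, lons),
        "kd_par": raster_from_grid(_field(0.10, 0.05, 0.005), lats, lons),
        "bathymetry": raster_from_grid(_field(60.0, 40.0, 5.0), lats, lons),
        "wave_action": raster_from_grid(_field(2.0, 1.5, 0.2), lats, lons),
    }

    rho = config.driver_correlation if index_correlation is None else index_correlation
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    z = rng.standard_normal((n_sites, 3)) @ np.linalg.cholesky(corr).T
    site_indices = pd.DataFrame(
        {
            "site_id": [f"site_{i:04d}" for i in range(n_sites)],
            "urban_runoff": np.expm1(1.5 + 0.5 * z[:, 0]),
            "sewage_effluent": np.expm1(1.2 + 0.5 * z[:, 1]),
            "tourism": np.expm1(1.8 + 0.6 * z[:, 2]),
            "z_urban_runoff": z[:, 0],
            "z_sewage_effluent": z[:, 1],
            "z_tourism": z[:, 2],
        }
    )
    return rasters, site_indices


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def cell_site_indices(truth: GroundTruth) -> pd.DataFrame:
    """Per-cell driver table keyed by (cluster_id, depth_bin), natural scale."""
    cols = ["cluster_id", "depth_bin"] + list(DEFAULT_NATURAL_MAPS) + ["depth"]
    out = truth.cells[cols].copy()
    out = out.drop(columns=["bs_score"])  # BS comes from the survey taxa themselves
    return out


def score_table(config: SimulationConfig) -> pd.DataFrame:
    return pd.DataFrame(
        [(t, s) for t, s, _ in config.taxa], columns=["taxon", "score"]
    )


def write_bundle(config: SimulationConfig, outdir) -> "dict[str, str]":
    """Write the full synthetic input bundle (CSV/JSON) and return its paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    surveys, truth = generate_surveys(config)
    paths = {}

    paths["surveys"] = str(outdir / "surveys.csv")
    surveys.to_csv(paths["surveys"], index=False)

    sst = pd.concat(
        [generate_sst(config, f"island_{i}") for i in range(config.n_islands)],
        ignore_index=True,
    )
    paths["sst"] = str(outdir / "sst.csv")
    sst.to_csv(paths["sst"], index=False)

    paths["site_indices"] = str(outdir / "site_indices.csv")
    cell_site_indices(truth).to_csv(paths["site_indices"], index=False)

    paths["score_table"] = str(outdir / "score_table.csv")
    score_table(config).to_csv(paths["score_table"], index=False)

    paths["synonyms"] = str(outdir / "synonyms.csv")
    pd.DataFrame([("PEVE", "PLUT")], columns=["from", "to"]).to_csv(
        paths["synonyms"], index=False
    )

    zones = truth.cells[["cluster_id", "zone"]].drop_duplicates()
    paths["zones"] = str(outdir / "zones.csv")
    zones.to_csv(paths["zones"], index=False)

    paths["ground_truth"] = str(outdir / "ground_truth.json")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "true_beta": truth.true_beta,
                "natural_maps": {k: list(v) for k, v in truth.natural_maps.items()},
                "seed": config.seed,
            },
            fh,
            indent=2,
        )
    return paths


def recovery_config(seed: int, n_analysis_cells: int = 312, **overrides) -> SimulationConfig:
    """A configuration sized for parameter-recovery runs (~300 analysis cells).

    Uses shallow+mid bins only (the analysis range) across 4 islands x 3
    zones; clusters per zone are chosen to reach the requested cell count.
    """
    per_zone = max(3, int(np.ceil(n_analysis_cells / (4 * 3 * 2))))
    defaults = dict(
        seed=seed,
        n_islands=4,
        zones_per_island=3,
        clusters_per_zone=per_zone,
        depth_bins=("shallow", "mid"),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
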