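# reefbleach

Drivers of coral bleaching across an archipelago, from daily sea-surface
temperature and benthic bleaching surveys to a weighted regression model
and site-level management scenarios.

Mass coral bleaching is triggered by accumulated heat stress, but the
response on any given reef is modulated by the susceptibility of the coral
assemblage present and by local environmental and anthropogenic conditions
(light, depth, turbidity, run-off, sewage, tourism pressure, wave action,
historical stress).  `reefbleach` implements the full analysis chain used
to disentangle those drivers for event-scale bleaching survey campaigns,
and ships a synthetic-data generator with a known ground truth so that
every stage is testable against a recoverable answer.

## The analysis

**Thermal stress.**  From a daily SST series, the climatological Maximum of
the Monthly Mean (MMM) is the warmest calendar-month mean; the bleaching
threshold is MMM + 1 °C.  Daily HotSpots are HS_d = max(0, SST_d − MMM),
and Degree Heating Weeks accumulate qualifying HotSpots over a trailing
12-week window:

    DHW_d = (1/7) Σ_{i=d−83..d} HS_i · 1[HS_i ≥ 1 °C]   (°C-weeks)

**Taxonomic susceptibility.**  Each taxon carries a rank S_t from 1 (least)
to 5 (most susceptible).  A survey's community score is the cover-weighted
mean over its taxa, diluted by unscored live cover:

    BS = ( Σ_t P_st · S_t ) / P_s

with P_st the percent cover of taxon t and P_s total live coral cover.

**Spatial aggregation and weights.**  Surveys within 1 km of one another
(complete-linkage clustering on great-circle distance, so 1 km bounds the
cluster *diameter*) form clusters; surveys are averaged per cluster ×
depth bin (shallow 0–6 m, mid >6–18 m, deep >18–30 m).  Zone × depth-bin
strata with fewer than three cells are dropped.  Each cell's analysis
weight is the inverse standard error of its mean percent bleached, capped
at the 95th percentile of raw weights and rescaled into (0, 1]; cells with
a single survey receive the 5th-percentile raw weight.

**Drivers model.**  The response is √(% bleached) per cell.  Predictors
(acute and historical DHW, historical bleaching, community susceptibility,
depth, PAR, kdPAR, SST variability, wave action, urban run-off, sewage
effluent, tourism) are transformed toward normality (log1p for
right-skewed variables), centred and scaled.  Candidate terms are all main
effects plus two interaction families — acute stress × driver and
susceptibility × driver.  The fitted model is weighted least squares,

    minimise Σ_i w_i (y_i − x_iᵀβ)² ,

selected by backward stepwise elimination under
BIC = n·log(RSS_w/n) + k·log(n), with marginality enforced (a main effect
never leaves while one of its interactions is retained).  Weighted one-way
ANOVA + Tukey HSD compares locations; temporal change is tested with a
weighted random-intercept mixed model (likelihood-ratio tests) and a
weighted two-way ANOVA.

**Inference and scenarios.**  Predictions square the fitted √-scale value
back to percent (clipped to [0, 100]).  The package produces
partial-regression curves, interaction prediction surfaces, ±1 SD
single-driver perturbations about the all-at-means baseline, and a
management scenario that pins acute DHW at a high quantile (default the
95th percentile of the event) and ranks, per cell, which manageable driver
(PAR, sewage, run-off, susceptibility, tourism) yields the largest
predicted bleaching reduction when lowered by 1 SD.

## Worked example

Generate a synthetic bundle with known truth and run the pipeline:

```python
import reefbleach as rb
from reefbleach.synthetic import DEFAULT_NATURAL_MAPS, SimulationConfig

cfg = SimulationConfig(seed=42, n_islands=2, zones_per_island=2, clusters_per_zone=10)
paths = rb.write_bundle(cfg, "bundle")
overrides = {k: v[0] for k, v in DEFAULT_NATURAL_MAPS.items()} | {"depth": "identity"}
run = rb.RunConfig(
    surveys=paths["surveys"], sst=paths["sst"], site_indices=paths["site_indices"],
    score_table=paths["score_table"], synonyms=paths["synonyms"], zones=paths["zones"],
    out_dir="run", transform_overrides=overrides,
)
rb.run_pipeline(run)
```

The run directory then contains per-stage CSV/JSON outputs.  For this seed
the selected model has n = 80 cells, adjusted R² = 0.93, and the
coefficient table starts:

```
                    term  estimate    se      t
               Intercept     3.879 0.074 52.436
               bs_score      1.021 0.074 13.848
     historical_bleached     0.917 0.077 11.890
               acute_dhw     0.575 0.076  7.580
            urban_runoff     0.490 0.080  6.121
```

Estimates are on the √-percent scale per standardized driver unit: the
intercept back-transforms to a baseline of 3.879² ≈ 15.0 % bleached at
mean conditions, and raising community susceptibility by one standard
deviation lifts the mean prediction from 15.0 % to 24.0 % (lowering it
drops the prediction to 8.2 %), as reported in `perturbations.csv`.  In
`management_scenario.csv`, with acute DHW pinned at its 95th percentile,
reducing susceptibility is the best action at 69 of 80 cells, reducing
surface light at 8, and reducing urban run-off at 3 — the same shape of
site-specific ranking the method produces on real campaigns.

The same pipeline is scriptable from a shell:

```bash
reefbleach simulate --seed 42 --out bundle
reefbleach validate --config cfg.yaml
reefbleach run --config cfg.yaml
```

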