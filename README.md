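# locustlens

Desert locust (*Schistocerca gregaria*) swarms devastate crops across dozens
of countries, and outbreak risk is driven by a handful of environmental
variables — soil moisture, precipitation and maximum temperature — whose
effect on breeding differs from country to country.  `locustlens` is a
pipeline for predicting locust **presence/absence** at region-month
resolution from fused swarm-sighting records and monthly gridded climate,
built for researchers and analysts who work with point-event pest data and
TerraClimate-style netCDF products.

The package covers the full workflow:

1. **Fusion** — reverse geocode each reported swarm sighting
   (latitude/longitude → country, region) against a rectangular-cell atlas,
   and attach the nearest-grid-cell climate values for the sighting's exact
   year and month.  Sightings only ever document *presence*, so every fused
   row is labelled `yes`.
2. **Pseudo-absence augmentation** — for every region of every country with
   at least one reported attack, each study-span month with *no* recorded
   attack becomes one `no` row (covariates sampled at the region centroid).
   Per region the construction is an exact calendar complement:
   `absence months + attacked months = span months`.
3. **Classification** — a from-scratch K-nearest-neighbour classifier,
   partitioned by country: each test sample is classified by a K-NN fitted
   only on training rows from its own country.  The pooled "global" K-NN is
   available as a baseline.
4. **Evaluation** — accuracy, precision, recall, F1, rank-based AUC,
   per-country breakdowns, mean fit/predict times.
5. **Carbon ledger** — operational energy and gCO₂eq accounting for each
   pipeline phase from a constant power model and a regional grid-intensity
   table.

A seeded synthetic-data module generates all three inputs (atlas, seasonal
climate grid, events) with a *planted* country-specific logistic
climate→attack structure, so every stage is testable offline and the central
claim — that per-country fitting beats pooled fitting when climate responses
differ between countries — is a checkable property.

## The model

For a test sample $x$ from country $c$, let $S_c$ be the training rows of
country $c$, z-scored with statistics of the fitted subset.  The $k$ nearest
neighbours are taken under the weighted Manhattan distance

$$d(x, z) = \sum_{r=1}^{d} w_r\,|x_r - z_r|, \qquad w_r = 1,$$

over the feature vector (start year, start month, precipitation, maximum
temperature, soil moisture), and the predicted class is the majority vote

$$C(x) = \arg\max_{C} \sum_{i=1}^{k} \mathbb{I}(y_i = C),$$

with the fraction of presence-labelled neighbours serving as the positive
score for AUC.  Tuned hyperparameters: $k = 7$, uniform vote weights,
Manhattan metric.  Ties are deterministic (equal distances rank by training
index; tied votes go to the nearest neighbour's class).  Emissions follow
`energy (kWh) × regional carbon intensity (gCO₂eq/kWh)` with a 42.5 W CPU /
12.678 GB RAM power model.

## Worked example

Build a two-country synthetic system in which the attack response to
maximum temperature has *opposite sign* in the two countries, fuse and
augment it, and compare the country-partitioned model with the pooled
baseline:

```python
import locustlens as ll
from locustlens.simulate import (two_country_config, make_atlas,
                                 make_climate, simulate_events)
from locustlens.fusion import build_positive_rows
from locustlens.augment import (attack_calendar, generate_negatives,
                                assemble_dataset)

cfg = two_country_config(seed=42)
atlas = make_atlas(cfg)
grid = make_climate(cfg, atlas)
events = simulate_events(cfg, atlas, grid)

pos = build_positive_rows(events, grid, atlas)
neg = generate_negatives(attack_calendar(pos), atlas, grid, cfg.year_span)
dataset = assemble_dataset(pos, neg)

results = ll.LocustLens(dataset, seed=42).fit()   # 5-fold stratified CV
print(results.summary())
```

```
LocustLens (country-partitioned K-NN)
=====================================
rows: 653   folds: 5   seed: 42
k=7  weights=uniform  metric=manhattan

accuracy : 0.8943
precision: 0.9117
recall   : 0.9344
F1-score : 0.9229
AUC      : 0.9165
mean fit time    : 0.000097 s
mean predict time: 0.000041 s

per-country accuracy:
  C01: acc=0.896  recall=0.950  AUC=0.919  (n=326)
  C02: acc=0.893  recall=0.919  AUC=0.911  (n=327)
```

The 653 rows are 442 presences (sightings) and 211 calendar-complement
absences.  Because the planted temperature coefficients are +3 in C01 and −3
in C02, a *pooled* K-NN sees the two signals partially cancel: the same
protocol with `mode="global"` scores 0.8606 accuracy, about 3 points below
the partitioned model — the planted structure is recovered.

The same pipeline runs from the shell:

```bash
locustlens all --out-dir runs/demo --seed 42
locustlens run --data runs/demo/glad42.csv --k 7 --metric manhattan \
    --folds 5 --seed 42 --out preds.csv
locustlens evaluate --preds preds.csv --out report.json --per-country
```

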