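# kelptrack

Spatial-ecology analysis of passive acoustic telemetry from coastal
receiver arrays, built around the kind of study that tracks large,
site-attached reef fish — e.g. Giant Sea Bass (*Stereolepis gigas*) in a
southern California kelp forest — across an array that straddles marine
protected areas (MPAs) and heavily fished grounds. It is aimed at
movement ecologists who have detection logs, receiver metadata, and
management polygons, and want a tested, scriptable route from raw
decodings to residency, home-range, and movement-rate inference.

## What it computes

* **Detection filtering** — tagging-day removal and a code-collision
  filter (drop detections closer than the tag's minimum transmission
  delay, default 30 s, to the last retained detection of the same tag on
  the same receiver).
* **Residency** — per-fish days at liberty and residency indices:
  `study residency = days detected / days release→study end`,
  `array residency = days detected / days first→last detection`.
* **Centers of activity (COA)** — interval-binned detection-count-
  weighted mean receiver positions (30 min bins for space use, 10 min
  for movement rates).
* **Detection range** — a logistic mixed model of per-ping detection
  against distance with a per-receiver random slope,
  `logit p_ij = β₀ + (β₁ + b_j)·d_ij`, `b_j ~ N(0, σ_b²)`, fit by
  Laplace maximum likelihood; the detection range is the 50% distance
  `d50 = −β₀/(β₁ + b_j)`.
* **Space use** — kernel utilization distributions from COAs with the
  ad-hoc bandwidth `h = ½(sd_x + sd_y)·n^(−1/6)`, 50% (core use area)
  and 95% (home range) volume contours, land clipping, MPA-overlap
  fractions, spawning (May–Oct) vs non-spawning splits.
* **Hurdle movement model** — hourly movement rates (sum of inter-COA
  distances over six consecutive 10-min COAs), then
  `logit P(rate>0) ~ diel + lunar + month + (1|fish)` (binomial GLMM)
  and `rate | rate>0 ~ same` (REML linear mixed model), with
  delta-method marginal/conditional pseudo-R².
* **Synthetic data** — an Ornstein–Uhlenbeck track simulator with
  diel/monthly activity modulation, uniform-gap tag transmissions,
  distance-dependent Bernoulli detections, and range-test drifts, so the
  whole chain is verifiable end to end.

## Worked example

Simulate a three-fish, ten-day scenario on a 29-receiver array and run
the full pipeline:

```python
from kelptrack import pipeline, range_model, synthetic

scenario = synthetic.make_scenario(seed=7, n_fish=3, days=10,
                                   n_range_receivers=4)
paths = synthetic.write_scenario(scenario, "demo")
cfg = pipeline.RunConfig(
    detections=str(paths["detections"]), receivers=str(paths["receivers"]),
    deployments=str(paths["deployments"]), rangetest=str(paths["rangetest"]),
    polygons=str(paths["polygons"]), study_end=str(scenario["study_end"]))
results = pipeline.run_pipeline(cfg, "demo/out")

print(results["residency"])
fit = results["range_fit"]
print(f"d50 = {range_model.d50(fit):.1f} m")
print(results["kud_overlap"])
```

prints (abridged):

```
tag_id  station_count  study_days  array_days  days_detected  study_res  array_res
   T01              6          11           9              9      0.818        1.0
   T02              7          11           9              9      0.818        1.0
   T03              5          11           9              9      0.818        1.0

d50 = 208.1 m

tag_id       season  level  n_coas  bandwidth_m  area_km2  mpa_fraction
   T01 non_spawning   0.50     431       42.683     0.019         1.000
   T01 non_spawning   0.95     431       42.683     0.187         1.000
   T02 non_spawning   0.95     424       35.676     0.095         0.671
   T03 non_spawning   0.95     418       33.122     0.108         0.000
```

Each fish was detected on every day after release (array residency 1.0;
study residency is lower because the study window starts at release).
The recovered 50% detection range, 208 m, sits near the simulator's true
218 m. The 95% KUD areas (~0.1–0.2 km²) are tight home ranges around
each fish's activity centre, and the MPA fraction is the share of that
home range inside the no-take polygon — fish T01 sits fully inside,
T03 fully outside.

The hurdle model on the same run (`results["hurdle"]`) reports, among
other terms, a positive day contrast in the binary part
(`diel[day] = 0.971` logit units: the fish are more likely to log
non-zero movement in daytime, as simulated) and pseudo-R² values
(marginal 0.041, conditional 0.317) whose gap reflects between-fish
variability absorbed by the random intercept.

The same stages are exposed on the command line:

```sh
kelptrack simulate --outdir demo --seed 7 --n-fish 3 --days 10
kelptrack filter --detections demo/detections.csv --deployments demo/deployments.csv --out demo/filtered.csv
kelptrack residency --detections demo/filtered.csv --deployments demo/deployments.csv --study-end 2021-03-11 --out demo/residency.csv
kelptrack range-fit --rangetest demo/rangetest.csv --receivers demo/receivers.csv --out demo/range.json
kelptrack run --config run.yml --outdir demo/out
```

## Layout

```
src/kelptrack/
  io.py          readers/writers, detection filters, polygon handling
  geo.py         local equirectangular projection, great-circle distance
  synthetic.py   array/track/transmission/detection/range-test simulators
  range_model.py distance-detection GLMM and d50
  glmm.py        Laplace logistic mixed-model estimator (shared)
  coa.py         centers of activity, days at liberty, residency
  space_use.py   kernel UDs, volume contours, clipping, MPA overlap
  solar.py       NOAA sunrise/sunset/civil twilight
  movement.py    hourly rates, diel/lunar covariates, hurdle model
  pipeline.py    config-driven orchestration
  cli.py         `kelptrack` command group
  datasets.py    published tagging-summary inputs
```
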