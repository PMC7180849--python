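# odormap

Two-level SOM / k-means analysis of multi-month electronic-nose (e-nose)
monitoring campaigns: pattern recognition of recurrent "air types" near an
industrial odor source, fusion with TVOC and wind data, and detection of a
loss of sensor dynamic response.

## Who this is for

Environmental monitoring groups running a ten-channel MOS e-nose (plus a
photoionization TVOC detector and a weather station) continuously at a
receptor site collect on the order of 10⁵ per-minute response vectors per
season. Supervised calibration against source samples is usually impossible
for fugitive emissions, so the analysis must be unsupervised; and multi-month
deployments expose the instrument to failures that routine field calibrations
miss. `odormap` packages the "odor control map" workflow for this setting,
together with a synthetic campaign generator that reproduces the statistical
structure of such data (recurrent air types, wind/TVOC covariation,
power-failure gaps, sensor freeze) so every stage is testable end to end.

## The method

1. **Compression by a self-organizing map (SOM).** Per-minute vectors
   x ∈ ℝ¹⁰ (conductance ratios, re-oriented so larger = stronger response,
   then z-scored) are summarized by a hexagonal-lattice map of prototype
   vectors m_u. Map size follows the classic heuristics: ⌈5√n⌉ units,
   quartered for a "small" map, with side-length ratio √(λ₁/λ₂) from the two
   leading covariance eigenvalues. Initialization spans the leading principal
   plane; training is the deterministic batch rule — each unit becomes the
   neighborhood-kernel-weighted mean of the data whose best matching unit
   (BMU) lies nearby — with a Gaussian kernel shrinking over two epochs.
2. **Two-level clustering.** The few hundred prototypes are clustered by
   k-means, and K is selected by minimizing the Davies–Bouldin index
   DB = (1/K) Σᵢ maxⱼ≠ᵢ (dᵢ + dⱼ)/d(cᵢ, cⱼ),
   with dᵢ the mean member-to-centroid distance and d(cᵢ, cⱼ) the centroid
   separation. Cluster membership flows from BMUs back to timestamps, which
   also labels every simultaneous TVOC/wind record (data fusion).
3. **Temporal analysis and anomaly detection.** The per-day percentage share
   of minutes per cluster is the monitoring statistic. A sudden, persistent
   collapse onto a single cluster, *together with* a collapse of within-day
   signal variability, flags a loss of dynamic response (sensor freeze);
   rebuilding the model on the pre-onset data and projecting the suspect
   minutes onto it confirms the anomaly when they concentrate on a handful
   of prototypes of one cluster.

## Worked example

Simulate a 16-day campaign with a sensor freeze at the start of day 11, then
run the full two-stage pipeline:

```sh
odormap simulate --days 16 --seed 5 --failure-day 11 --out data
odormap run-all --sensors data/sensors.csv --ancillary data/ancillary.csv \
    --seed 0 --out run
```

which prints

```
stage 1: best k = 4; anomaly flagged = True
  onset 2017-04-18, dominant cluster 2
stage 2: built on 15840 minutes up to 2017-04-17; best k = 4
  external projection: 7200 minutes on 2 distinct BMU(s)
manifest: run/manifest.json
```

Reading the output: the exploratory map over all 23,040 minutes partitions
best into four clusters (Davies–Bouldin 0.199 at k = 4 against 0.803 at
k = 2), and the detector flags 2017-04-18 — day 11 of the campaign, exactly
the injected freeze onset — because cluster 2 holds ≥ 95% of every later
day's minutes while within-day variability drops to 0.002 against a campaign
median of 0.49. Stage 2 rebuilds on the 15,840 pre-onset minutes, again
finds four air types, and the 7,200 frozen "external" minutes project onto
just 2 prototypes of a single cluster — the loss-of-responsivity signature.
The fused summaries in `run/` show the plant-impact analogue (here cluster
2): TVOC median 0.14 ppm vs 0.03–0.06 ppm elsewhere, wind-speed median
0.61 m/s (campaign's calmest), and a wind-sector table dominated by the
configured NE/E source sectors.

Artifacts written per run: SOM model files, per-k DB tables, per-minute
membership, daily share tables, anomaly report (JSON), per-cluster
TVOC/wind summaries, and figures (component planes, cluster maps, daily
share bars, sector roses, hit maps).

## Layout

| module | contents |
| --- | --- |
| `odormap.synthetic` | campaign generator with ground truth (air-type Markov chain, wind/TVOC models, gaps, sensor freeze) |
| `odormap.frames`, `odormap.ingest` | containers, CSV IO, signal orientation, minute alignment |
| `odormap.som` | sizing heuristics, linear init, batch training, BMU/QE/TE, component planes, model files |
| `odormap.clustering` | k-means on prototypes, Davies–Bouldin, k selection, cluster variance |
| `odormap.fusion` | membership transfer, daily shares, wind sectors, ancillary summaries, anomaly detector, projection |
| `odormap.pipeline`, `odormap.cli`, `odormap.plots` | two-stage orchestration, manifests, CLI, figures |

See `docs/methods.md` for the model, parameter defaults, and limitations.
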