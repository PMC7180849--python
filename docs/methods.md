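# Methods

This note records the models, conventions and numerical choices behind
`odormap`, the reasoning where the design was genuinely open, and what the
synthetic-data tests do and do not establish about real campaigns.

## Signal model and orientation

A MOS channel reports a dimensionless conductance ratio; instrument presets
mix two conventions (some channels log G/G0, others G0/G — sample over
baseline conductance and its reciprocal). Before modeling, G0/G channels are
inverted (x → 1/x) so that on every channel a larger value means a stronger
response to detectable compounds. The transform is analytic and exactly
invertible; a raw-convention mode (`orient: false`) is available because
mixed-convention modeling is also defensible — group structure is preserved
either way, only the sign of the correlation between channel groups changes.
Orientation state is tracked on the frame and re-orienting is an error, so a
double inversion cannot happen silently.

Malformed or out-of-range rows in ingest are quarantined and counted rather
than fatal: multi-month field data is dirty, and a hard failure on row
ten thousand of an 80,000-minute file helps nobody. Structural problems
(missing columns, duplicate timestamps) remain hard errors.

## SOM

* **Sizing.** Target unit count ⌈5·√n⌉ for n input vectors; a "small" map
  divides this by 4 (rounded half away from zero), a "big" one multiplies by
  4. Side lengths: ydim = round(√(units/ratio)), xdim = round(units/ydim),
  ratio = √(λ₁/λ₂) of the two leading covariance eigenvalues, rounding half
  away from zero. With these conventions a campaign of 80,017 vectors at
  ratio ≈ 2.5 yields a 30×12 (360-unit) map and 45,503 vectors at ratio
  ≈ 1.85 yield 22×12 (264 units); both grids are stable across a window of
  ratios (2.3–2.6 and 1.75–1.95 respectively), so the result does not hinge
  on the third decimal of an eigenvalue.
* **Lattice.** Hexagonal by default (offset rows at √3/2 spacing, unit
  distance between neighbors); rectangular available. Neighborhood distances
  and the topographic-error neighbor test both use the lattice embedding.
* **Normalization.** Per-channel z-score, fitted on the building data only
  and reused verbatim for any external projection. Zero-variance channels
  get an epsilon scale with a warning instead of an error, so a dead channel
  degrades gracefully.
* **Initialization.** Deterministic: unit (row, col) = mean + a·σ₁·PC1 +
  b·σ₂·PC2 with a, b linearly spaced over ±1 SD along the long/short grid
  sides. Rank-1 data zeroes the second axis with a warning. This init is
  only guaranteed to beat a random codebook when the cluster structure lies
  near the leading principal plane — which is the situation the heuristic
  targets; for structure spanning 3+ dimensions at equal scale the initial
  advantage can vanish (training recovers either way).
* **Batch training.** Per pass: BMU assignment for all rows, then every unit
  moves to the Gaussian-kernel-weighted mean of rows by BMU,
  h = exp(−d²/2σ²) on lattice distance. σ shrinks linearly from
  max(1, longest-side/4) to 1 across the passes; "two learning epochs" is
  interpreted as two full batch passes (an optional rough+finetune phases
  mode exists, off by default). Units with zero kernel mass keep their
  prototypes. The batch path contains no randomness: training is
  bit-reproducible, and each update is a convex combination of data rows, so
  prototypes never leave the data envelope. With σ = 0 the kernel is the BMU
  indicator and one pass is exactly one Lloyd k-means step with k = units —
  the equivalence the test suite checks against an independent Lloyd
  implementation.
* **BMU ties** break to the lowest unit index, for determinism.

## Two-level clustering

k-means runs on the codebook in the same normalized space used for training
(consistency with BMU assignment; weights are denormalized only for
reporting). All units participate, including zero-hit units — the object
being partitioned is the map. Restarts seed from k distinct prototypes;
empty clusters are repaired by reseeding at the point farthest from its
center; the lowest-SSE restart wins and the per-restart trace is kept.
A hit-weighted variant was considered and rejected for the default: the map
is already a density-aware summary, and unweighted clustering keeps the
partition a property of the map alone.

K is chosen over 2–8 by Davies–Bouldin argmin (ties to smaller K). DB uses
mean member-to-centroid Euclidean distance as the within-cluster dispersion
and centroid distance as separation; coincident centroids are an error, not
a silent infinity. Per-cluster "total variance" is reported as the trace of
the member covariance (population convention, denormalized weights) — one
explicit convention among several the quantity's name could mean.

## Fusion and temporal statistics

Cluster membership transfers from BMUs to timestamps and then to any
ancillary record at the same minute. Summaries per cluster: TVOC and
wind-speed quartiles (linear interpolation), and wind-sector frequencies
over 8 sectors centered on the cardinal/intercardinal directions
(N = [337.5°, 22.5°), half-open, clockwise; 16-sector mode available).
Minutes calmer than 0.5 m/s keep their speed in the quartiles but are
excluded from sector tables, where direction is ill-defined.

Daily cluster shares are percentages of each day's *recorded* minutes; a day
with fewer than 60 recorded minutes is "ND" (not recorded). The threshold is
a declared default, not an inference about any particular study.

## Anomaly detector

A freeze is flagged by a conjunction designed so that one genuinely
odor-dominated 100% day does not trigger it:

1. **Persistent dominance** — the earliest run of ≥ 3 non-ND days on which
   one cluster holds ≥ 95% of each day's minutes and continues to do so on
   every later non-ND day to campaign end;
2. **Variability collapse** — the mean within-day per-channel standard
   deviation over the run is ≤ 0.1× the campaign median of that statistic.

Two refinements matter in practice, both caused by natural full-day
single-state episodes that can sit immediately before a freeze in the same
cluster: run starts are scanned forward until the collapse condition holds
(otherwise a healthy leading day dilutes the run mean and the freeze is
missed), and the reported onset is the first day of the accepted run whose
own variability is collapsed (otherwise the onset lands a day early). All
thresholds are configurable.

The campaign median in (2) assumes healthy days form at least roughly half
of the campaign; a freeze covering most of a record would depress the median
and can mask detection. This is a known limitation, shared with any
self-referenced baseline.

Stage 2 rebuilds the model — including the normalization — on data up to the
day before the onset, and projects the rest ("external" data) onto it as a
pure query. Frozen minutes concentrating on very few prototypes of a single
cluster confirm the instrumental origin of the collapse.

## Synthetic campaigns

The generator emulates what the analysis assumes about a receptor site near
an industrial VOC source, with ground truth:

* **Air types.** A first-order Markov chain at minute resolution over four
  states. The default transition matrix is 0.995·I + 0.005·1πᵀ with
  π = (0.15, 0.25, 0.40, 0.20), giving ~200-minute episodes and exactly π as
  the stationary occupancy. Episode persistence is a stated default, not a
  fitted quantity. Note the statistical consequence: occupancy over 50,000
  minutes fluctuates with SD ≈ 4% per state at this stickiness, so tight
  occupancy checks are run on a faster-mixing variant where a 2% tolerance
  is meaningful.
* **Response profiles.** Oriented means per state: background near baseline,
  a sulphur-tinged episode (S7/S9 elevated), an aromatic episode
  (S1/S3/S5), and a broad plant-impact profile elevated on all channels.
  The four profiles are roughly equidistant (pairwise separations 1.8–3.9
  ratio units against per-channel noise SD 0.08) rather than nested —
  distinct odor sources have distinct fingerprints, and a purely nested
  gradient would make the cluster count ill-defined for any validity index.
  A shared diurnal sinusoid (amplitude 0.05) and Gaussian noise complete the
  signal; values are clipped positive.
* **Ancillary covariation.** Per state: von Mises wind direction, lognormal
  speed and lognormal TVOC. The plant state draws wind from the NE/E sectors
  at low speed (median 0.6 m/s) with TVOC median 0.14 ppm; the other states
  blow mostly from westerly sectors at 1.8–2.5 m/s with TVOC medians
  0.03–0.06 ppm.
* **Gaps** are absent records, not sentinels: one 10-day outage plus a lost
  day and scattered multi-hour gaps in the default 83-day layout.
* **Sensor freeze.** From the onset minute, every channel holds the last
  *observed* vector plus tiny noise (SD 0.002). Freezing at the state mean
  instead would be degenerate: trained prototypes arrange symmetrically
  around a state's mean, so that point sits where several prototype cells
  meet and the projected BMU count becomes an artifact of tie geometry
  rather than of the freeze. A stuck instrument holds whatever value it last
  produced. Freeze-to-constant (not drift) is the failure mode modeled; the
  detector is not a drift detector.

What passing tests on this generator shows: the pipeline recovers planted
cluster structure, attributes the plant profile through fused ancillary
data, and detects freezes under realistic gap patterns. What it does not
show: robustness to sensor drift, humidity/temperature response, baseline
wander, or air types without Markovian persistence — none of which the
generator emulates.

## Problem sizes in tests

Unit tests use 1–20-day campaigns; recovery checks use 10 seeds of 14-day
(20,160-minute) campaigns; freeze-detection checks use 10 freeze and 10
clean 60-day campaigns with a 5-day gap, freeze at day 34 (the same ~0.57
campaign fraction as an 83-day record failing after day 47). These sizes
keep the full suite around a minute while leaving every statistical margin
wide (label agreement in recovery runs is ~100% against a 90% requirement).
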