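# Methods

## The problem and the data model

One acquisition is a 500 s, 1 Hz recording from a six-channel gas-sensor
array (Temperature °C, Humidity %rh, CO₂ ppm, C₂H₄ ppm, O₂ %VOL, VOC
ppm). Acquisitions are flattened sensor-major into a length-3000 feature
vector: variables 1–500 are the Temperature trace in time order,
501–1000 Humidity, 1001–1500 CO₂, 1501–2000 C₂H₄, 2001–2500 O₂,
2501–3000 VOC. Index spaces are 1-based throughout because sparse
warning models cite variables by number (e.g. 228, 2001). Two boundary
conventions are fixed deliberately: tiles are inclusive 1-based
intervals (so variable 2001 *starts* the O₂ tile), and time within a
tile is chronological.

Detection ranges enforced everywhere (generator clipping, channel
metadata): C₂H₄ 0–100 ppm, O₂ 0–30 %VOL, VOC 0–50 ppm, CO₂ 0–5000 ppm,
Temperature −20–80 °C, Humidity 0–100 %rh.

## Synthetic warehouse generator

The generator emulates the study design the analysis assumes: 9
warehouses × 8 consecutive daily acquisitions (days 1–2 fresh, 3–8 after
fungal inoculation), 72 samples in total. Within an acquisition each gas
channel follows a first-order saturating approach from an ambient
baseline (CO₂ 400 ppm, O₂ 21 %VOL, C₂H₄ and VOC 0 ppm) toward a
day-dependent equilibrium level with time constant τ = 60 s — the
simplest defensible response model for electrochemical/IR gas sensors,
which approach equilibrium monotonically. Per-timepoint i.i.d. Gaussian
noise with sd = 1% of full scale (matching the ±2% FS precision class of
the sensors) is added, then traces are clipped to the detection range.
Temperature and Humidity are held at the incubation conditions, 25 °C
and 60 %rh.

Only the *ordering* of mean responses across days is empirically
constrained (VOC 7>8>4>6>5>1>3>2; CO₂ ascending 1<4<3<2<7<5<6<8; O₂
8>5>6>7>3>4>2>1; C₂H₄ 7>6>8>5>4>3>2>1). Absolute levels are not
reported, so the defaults place the eight day levels evenly inside a
plausible sub-range of each channel (VOC 5–40 ppm, CO₂ 400–3200 ppm, O₂
5–19 %VOL, C₂H₄ 10–80 ppm), spaced widely enough that the orderings
survive the default noise. The reported CO₂ narrative is internally
inconsistent (rising response vs. "release decreased gradually"); the
generator encodes the printed response ordering only. The inoculation
event itself is not modelled mechanistically; the day levels absorb it.

For parameter-recovery studies the generator can embed a known sparse
linear signal: 10 variables (default) drawn from the late, plateau
portion of the gas tiles, Gaussian coefficients affinely rescaled so the
noiseless response spans the day-like range 1–8, plus label noise with
sd 0.3. The construction (indices, coefficients, intercept) is returned
as a `GroundTruth` sidecar so tests can compare recovered models against
truth.

What the generator does **not** emulate: sensor drift and hysteresis,
cross-sensitivity between channels, warehouse-to-warehouse heterogeneity
beyond noise, and transport dynamics of the sampling pump. Passing tests
therefore demonstrate correctness of the algorithms under a clean,
known-signal regime, not field performance on real warehouse data.

## PLS engine

Single-response PLS (PLS1) by NIPALS with deflation. Features and labels
are autoscaled internally (mean-centred, unit variance; constant columns
get scale 1) because the channels carry incommensurate units;
coefficients are folded back to original units so prediction is a plain
affine map. One NIPALS pass yields the coefficient path for every
component count up to K, so k-fold RMSECV across component counts costs
one decomposition per fold. With full components on a full-rank matrix
PLS1 equals OLS, which the tests exploit as a closed-form oracle
(agreement to 1e-8), alongside a cross-check against an independent PLS
implementation at reduced component counts.

Conventions: RMSE uses divisor n; Pearson correlation raises on
zero-variance input rather than returning NaN; CV folds are a seeded
permutation split into contiguous blocks; the component count for final
models minimizes RMSECV, capped at 12 components for SA-derived models
and 15 otherwise. The calibration/prediction split is a seeded random
2:1 split stratified by day, so both sets span all eight days; the
alternative (leaving whole warehouses out) is available through the same
function by splitting upstream.

## Variable selection

All four selectors minimize k-fold RMSECV of PLS restricted to the
candidate subset, share a memoized fitness, and are deterministic given
their seed. Defaults are the reference settings: GA (30 chromosomes,
deletion group 5, mutation 0.01, crossover 0.5, 100 generations), SA
(T₀ = 10, T_end = 1, Markov chain 10, cooling 0.95, window widths 10–20
step 1, 2-point exchanges, ≤ 12 components), ACO (50 ants, 10 cycles ×
50 iterations, P = 0.3, Q = 0.01), CARS (≤ 15 components, 5 folds, 2000
Monte-Carlo runs). Where the procedure descriptions leave details open,
this package resolves them as follows:

* **GA** — "deletion group 5" is read as steady-state replacement: each
  generation five offspring (tournament-of-2 parents, uniform crossover,
  bitwise mutation) replace the five worst chromosomes, the elite
  remainder surviving. Chromosomes initialize sparsely
  (`init_inclusion_probability`, default 0.1), as is standard for
  wavelength-selection GAs — dense initializations leave the final
  frequency-threshold step uninformative at realistic budgets. Final
  selection keeps variables at or above a cumulative population
  frequency of 0.5 (configurable; the fittest chromosome is the fallback
  if none qualify).
* **SA** — the largest interpretive choice in the module: the "window
  width" schedule sets the *size* of the selected set for one annealing
  pass (initialized as a contiguous index window at a random position),
  while moves exchange `swap_count_per_step` selected variables for
  unselected ones under the Metropolis criterion with geometric cooling.
  The best state ever visited across all widths is returned. Note that
  when the window width equals the swap count a move replaces the whole
  subset and the search degenerates to random sampling; small-subset
  experiments should set `swap_count_per_step = 1`.
* **ACO** — pheromone is uniform initially; each ant includes variable i
  with probability `clip(τᵢ/Στ · target_subset_size, 0, 1)` — the plain
  normalized share would give an expected subset of one variable at
  p = 3000, so the share is rescaled to a target expected size (default
  30) and saturates toward 1 as pheromone concentrates. Evaporation rate
  0.1; each ant deposits Q/RMSECV on its variables. The threshold
  P = 0.3 applies to the same normalized inclusion probability; if no
  variable qualifies, the top-k by pheromone are returned with a warning
  (k = mean ant subset size).
* **CARS** — run i of N keeps the ⌈rᵢ·p⌉ variables of largest absolute
  autoscaled coefficient, where the exponential-decay ratio
  rᵢ = a·e^(−k·i) satisfies r₁ = 1 and r_N = 2/p
  (a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1)), followed by adaptive
  reweighted sampling (coefficient-weighted resampling with
  replacement). Each run fits on a random 80% Monte-Carlo calibration
  subsample (the fraction is unreported in the source procedure; 0.8 is
  the standard choice in the CARS literature). Each run's live set is
  scored by full-sample RMSECV and the best-scoring set wins. A small
  numerical tolerance in the ceiling guards the analytic boundary
  r_N·p = 2 against floating-point noise.

## Problem sizes used in tests and drivers

Unit and acceptance tests run the selectors at reduced search budgets
(`test_scale_selector_configs`): GA 15 generations × 20 chromosomes, SA
windows 10–12 with cooling 0.85 and chain length 5, ACO 2 × 10
iterations × 20 ants, CARS 50 Monte-Carlo runs — chosen as desk-scale
budgets that preserve each algorithm's behaviour on the 72 × 3000 study;
the config defaults remain the full reference settings. Oracle
comparisons use exhaustive subset enumeration at p ≤ 10 (all subsets) or
fixed subset size 2 at p ≤ 12. Stochastic claims aggregate over seeds:
20 replicates for signal recovery (Rp ≥ 0.9 in ≥ 90%), 10 seeds for
selector-vs-random comparisons (majority wins), 10⁴ trials for the
Metropolis acceptance law (within 3 standard errors).

## The reference warning model

The published 20-variable SA-PLS model ships verbatim as a JSON fixture:
coefficients in equation order X1–X20 over variables 228…2965 and
intercept 38.9899. In the source table the two value columns are
printed under swapped headers; the fixture follows the equation text,
which disambiguates (X1 is the value at variable 228 with weight
0.3264). Whether those coefficients apply to raw or autoscaled sensor
values is unstated — the intercept magnitude suggests raw-scale inputs —
so the model is stored verbatim and scoring is scale-agnostic; no claim
is made that scoring raw synthetic data with it reproduces the original
study's statistics (the original samples are unavailable).

Grade bands: the nominal ranges 1–2 / 3–4 / 5–6 / 7–8 leave gaps, so
classification uses midpoint boundaries — fresh Y < 2.5, mild [2.5,
4.5), medium [4.5, 6.5), severe ≥ 6.5 — with the nominal ranges kept as
metadata. Scores outside [1, 8] are assigned the nearest band with an
out-of-range flag, which is how the all-zero diagnostic input (Y =
38.9899) reports.

## Known limitations

* The synthetic study is easier than real warehouse data (clean day
  structure, no drift, no confounders); reported correlations on it run
  near 1 and should not be read as field performance.
* The original calibration/prediction partition and per-set sample
  counts were never published, so the original model-comparison
  statistics cannot be recomputed from any input; the pipeline instead
  demonstrates the same comparison *layout* and sound statistics on
  synthetic data.
* ACO's cycle/iteration distinction is under-specified in the source
  description; both loops are implemented as nested with the printed
  counts, with pheromone persisting across cycles.
* CARS's "2000 Monte-Carlo sampling runs" is read as 2000 schedule
  iterations and is configurable; drivers and tests use 50.
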