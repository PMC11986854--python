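# Methods

## Model

The package implements the two-step floating catchment area (2SFCA) family
for prehospital EMS accessibility. Both steps operate on a demand × station
distance matrix (km; great-circle with Earth radius 6371.0088 km for
geographic coordinates, Euclidean for planar ones) and a zone-dependent
catchment threshold: 5 km for main-urban entities, 15 km for non-main-urban
ones, following Chinese EMS planning guidance. The boundary is inclusive
(d = d₀ is inside the catchment) for every variant.

Step 1 computes each station's supply–demand ratio
R_j = S_j / Σ_k w(d_kj)·D_k over its in-catchment demand; Step 2 sums
w(d_ij)·R_j over each demand point's reachable stations. The weight w is:
binary (`cumr`), Epanechnikov kernel ¾(1 − (d/d₀)²) (`kd`), a truncated
Gaussian rescaled to 1 at d = 0 and 0 at d = d₀ (`gauss`), or the Gaussian
multiplied by a Huff-type selection probability
P_ij(λ) = d_ij^(−λ)/Σ_j d_ij^(−λ) (`gp`). Both steps always use the same
weight; mixing variants between steps is not supported.

Assumptions inherited from the model family: uniform station capacity
S_j = 1 unless a supply column says otherwise; demand measured as case
counts at community/village centroids; straight-line (or great-circle)
distance as the impedance — no road network or travel time.

## Parameters

- **λ (trip friction)** — exponent of the inverse-distance choice term;
  larger values concentrate choice on nearer stations. Default 2.0 (the
  gravity-model convention), grid sweep default {2.0, 2.2, 2.4, 2.6, 2.8,
  3.0}, dimensionless.
- **d₀ (catchment threshold)** — 5 km main urban / 15 km non-main urban by
  default. `attribution` chooses whose zone governs a demand–station pair;
  the default is the demand point's zone (the patient's area determines the
  acceptable distance). The same attribution applies in both steps so
  catchments are symmetric and the conservation identity below holds.
- **Probability scope** — the denominator of P_ij sums over in-catchment
  stations by default (`within_threshold`); `all_stations` normalizes over
  every station instead. The within-threshold default keeps the choice
  distribution consistent with the catchment sums.
- **ε (distance floor)** — 0.001 km; distances are clamped to ε inside
  d^(−λ) only, so a demand centroid coincident with a station receives
  essentially all choice probability without non-finite arithmetic.
  Catchment membership always uses the unclamped distance.

## Numerical conventions

- d^(−λ) is evaluated in log space with a row-max shift, so extreme λ or
  tiny distances cannot overflow; probabilities sum to 1 to machine
  precision.
- Stations with zero weighted in-catchment demand get R_j = 0 (not NaN) and
  are reported as idle; demand points with empty catchments get A_i = 0 and
  are reported as unreachable. This keeps the pipeline total and surfaces
  data problems explicitly.
- Pearson r is undefined (NaN) for constant vectors; MAPE averages only
  stations with positive observed counts and reports how many were
  excluded; min-max normalization of a constant vector returns zeros with a
  warning.
- Nearest-neighbor expected distance is 0.5/√(n/A) with standard error
  0.26136/√(n²/A); the study area defaults to the convex-hull area of the
  points (computed in a local equirectangular km frame for geographic
  input) and the result records whether the area was supplied or derived —
  silent area defaults are the main source of divergence between
  implementations of this index.
- Ties in dispatch-to-centroid assignment go to the lexicographically
  smallest demand id; duplicates are defined as an identical record id or
  an identical (station, timestamp, coordinates) triple.

## Conservation identity

Because both steps use the same weight matrix, Σ_i D_i·A_i = Σ_j S_j holds
exactly (to rounding) on every instance where no station is idle and no
demand point unreachable, for all four variants and both probability
scopes. The test suite verifies this on hundreds of random instances, and a
double-loop naive implementation of both steps serves as an independent
oracle for the vectorized engine (agreement to 1e−12).

## Synthetic scenarios

`generate_scenario` draws a planar (km-unit) scenario intended to mimic a
prefecture-level city: by default 37 stations from a parent–offspring
cluster process (6 parents, 4.5 km offspring dispersion — giving a station
nearest-neighbor ratio around 0.45–0.5, i.e. significantly clustered), 240
demand centroids, and Poisson case counts with mean 250 (~60 000 cases). A
negative-binomial `dispersion` parameter is available to emulate heavily
concentrated urban demand. The cluster parents double as population
centers: 75% of demand centroids scatter around them (8 km dispersion), the
rest are uniform background — emergency stations are sited where people
live, so demand and supply share geography. Zones are geometric: points
inside a 15 km central disk are main-urban; 16 of 37 station parents-worth
of mass sits in that disk, mirroring a realistic main-urban share. Each
stage draws from its own seed-derived substream, so enlarging one stage
never perturbs another, and a spec plus seed reproduces a scenario exactly.

Observed dispatch counts are sampled per case: each case at demand point k
picks a station with probability proportional to G(d, d₀)·d^(−λ_true) over
the in-threshold stations (λ_true = 2.4 by default); cases at demand points
with no in-threshold station are recorded as uncaptured (~20% under the
defaults). The generator does **not** emulate road networks, travel times,
temporal dynamics, geocoding noise, or station capacity differences — so
passing tests demonstrate internal consistency and statistical
recoverability of the model, not real-world predictive validity.

## λ recovery

`recover_lambda` grid-searches λ by correlating observed per-station counts
with the model's **expected observed counts** — the row-normalized
G·P allocation of each demand point's captured cases
(`expected_observed_demand`). At the generating λ this allocation equals
E[observed] exactly, which makes the grid search consistent: on default
study-scale scenarios it recovers λ within one grid step in effectively all
seeds. Correlating against the *unnormalized* Step-1 predicted demand
instead is biased here: predicted and expected-observed differ by a
per-demand-point captured fraction, and in experiments with the sampling
noise removed the r-maximizing λ wandered over [1.2, 4.0] depending on the
point pattern. The unnormalized Step-1 sum remains what the accessibility
computation and the Table-style model comparison use, since it is the
model's demand estimate for capacity planning.

## MMAD λ-sensitivity: a known divergence from field expectations

MMAD is the elementwise difference of two min-max normalized accessibility
vectors; it is antisymmetric, bounded in [−1, 1], and invariant to positive
affine transformations of either input. Empirical studies on real city data
have reported that low λ settings understate accessibility relative to a
mid-grid reference (mean MMAD < 0) and high λ overstate it. On this
package's synthetic scenarios the mean has the **opposite** sign, and the
mechanism is structural: conservation pins the demand-weighted mean of A at
every λ, and with near-homogeneous case counts the unweighted mean is
effectively pinned too; raising λ concentrates choice probability and
inflates max(A) — the best-placed demand point sitting next to a station —
so after division by the max the bulk of normalized values *falls*. The
sign observed on real data therefore reflects the shape of that dataset's
accessibility distribution (strongly heterogeneous demand and a stable
maximum), not a general property of the model; the corresponding acceptance
test asserts the field-reported pattern and fails on synthetic data by
design rather than being weakened. Negative-binomial demand heterogeneity
and the all-stations probability scope were both checked and do not flip
the synthetic sign.

## Known limitations

- Straight-line/great-circle distances; fixed thresholds ignore the road
  network and travel times.
- Uniform default capacity; no capacity measure tailored to EMS operations.
- No competition scheme beyond the choice probability (no 3SFCA-style
  weighting).
- Free-text address geocoding is out of scope; dispatch records must carry
  coordinates. Aggregation to demand points uses nearest-centroid
  assignment unless boundary polygons are supplied.
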