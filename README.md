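# ems2sfca

Floating-catchment spatial accessibility models for prehospital emergency
medical services (EMS), built for health-services researchers and planners
who need to score how easily communities can reach ambulance stations and to
validate competing distance-decay assumptions against observed dispatch
volumes.

## The models

The two-step floating catchment area (2SFCA) family measures accessibility
in two passes over a bipartite demand–supply system. For stations *j* with
capacity *S<sub>j</sub>* and demand centroids *k* with case counts
*D<sub>k</sub>*, within a catchment radius *d₀* (5 km in the main urban
zone, 15 km elsewhere):

**Step 1** — each station's supply–demand ratio

> R_j = S_j / Σ_{k : d_kj ≤ d0} w(d_kj) · D_k

**Step 2** — each demand point's accessibility

> A_i = Σ_{j : d_ij ≤ d0} w(d_ij) · R_j

The packages differ in the pair weight *w*:

| variant | weight `w(d)` |
|---------|----------------|
| `cumr`  | 1 inside the threshold, 0 beyond (classic binary 2SFCA) |
| `kd`    | Epanechnikov kernel ¾(1 − (d/d₀)²) |
| `gauss` | truncated Gaussian (e^(−(d/d₀)²/2) − e^(−1/2)) / (1 − e^(−1/2)) |
| `gp`    | Gaussian decay × Huff-type choice probability P_ij(λ) = d_ij^(−λ) / Σ_j d_ij^(−λ) |

The `gp` variant (GP2SFCA) is the interesting one: when several stations'
service areas overlap, patients do not split evenly — the inverse-power
selection probability, governed by the trip-friction exponent λ (typically
2.0–3.0), models which station a case actually goes to. That makes the
Step-1 predicted station loads comparable with real dispatch counts, which
is how the package scores models (Pearson *r*, MSE/RMSE/MAE/MAPE) and
recovers λ by grid search.

Also included: the min-max normalized accessibility difference (MMAD) for
comparing accessibility surfaces across parameter settings, the average
nearest-neighbor clustering index for station patterns, a dispatch-record
cleaning pipeline (deduplication, empty-return exclusion, aggregation to
demand centroids), and a synthetic scenario generator whose dispatch counts
come from a known threshold-censored Gaussian × inverse-power choice
process, so every claim is testable end to end without any private data.

## Worked example

Generate a study-scale synthetic scenario (37 stations, 240 demand
centroids, ~60 000 annual cases, λ = 2.4 generating process), check the
station clustering, and score all models against the observed counts:

```sh
$ ems2sfca simulate --seed 7 --out scenario/
wrote scenario to scenario/: 37 stations, 240 demand points, 49302 observed cases, 10761 uncaptured

$ ems2sfca nn-index --points scenario/stations.csv --area-km2 9025
n=37 area=9025.0 km2 (supplied)
observed mean NN = 3.5278 km
expected mean NN = 7.8090 km
ratio = 0.452  z = -6.380
pattern is clustered (ratio < 1)

$ ems2sfca evaluate --scenario scenario/ --lambdas 2.0:3.0:0.2 --out metrics.csv
     model  lambda  pearson_r      p_value          mse        rmse         mae       mape
      cumr     NaN   0.156150 3.560579e-01 2.268195e+07 4762.557557 4399.027027 446.127028
        kd     NaN   0.237659 1.566608e-01 2.044051e+06 1429.703237 1192.653436 128.613427
     gauss     NaN   0.242235 1.485989e-01 3.877639e+06 1969.172181 1635.703647 171.903617
     gp2.0     2.0   0.856331 1.397445e-11 4.894744e+05  699.624437  583.041600  41.079244
     ...
     gp3.0     3.0   0.887851 2.377861e-13 4.098279e+05  640.178049  543.852569  39.660681
gp_average     NaN   0.874155 3.708779e-12 4.470895e+05  668.338530  562.486956  40.321722
```

Reading this: the stations are significantly clustered (NN ratio 0.452,
z < −2.58); the binary and plain-decay baselines barely correlate with the
observed station loads (r ≈ 0.16–0.24, p > 0.05), while every GP row is far
stronger (r ≈ 0.86–0.89, p < 10⁻¹⁰) because the choice probability routes
overlapping demand realistically. MAPE drops from 446% (`cumr`) to ~40%.

Accessibility surfaces and their λ-sensitivity:

```sh
$ ems2sfca accessibility --stations scenario/stations.csv --demand scenario/demand.csv \
    --model gp --lambda 2.4 --out a24.csv
INFO ems2sfca: 43 unreachable demand points, 0 idle stations
wrote a24.csv (gp, lambda=2.4)

$ ems2sfca compare --a a20.csv --b a24.csv --out mmad.csv
mean MMAD = +0.0109 (n=240)
```

`A` in the output CSV is the accessibility score (supply units per case —
its demand-weighted sum equals total station capacity); demand points with
no station within their zone's threshold are flagged unreachable with A = 0.
Library use mirrors the CLI: see `ems2sfca.accessibility`,
`ems2sfca.lambda_sweep`, `ems2sfca.recover_lambda`,
`ems2sfca.generate_scenario`.

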