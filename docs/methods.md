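# Methods

## Problem and model

The package sites a mobile stroke unit (MSU) base among a fixed set of
endovascular-clot-retrieval (ECR) capable hospitals. The underlying model is
a maximum-coverage variant with *fixed* facilities: rather than opening new
sites, it scores how well each suburb is already served and directs the new
mobile resource toward the least-served demand.

Formally, with travel time `t(h, s)` (minutes, hospital → suburb centroid,
peak traffic) and threshold `T`:

* membership `m(s) = |{h in class : t(h, s) ≤ T}|`, inclusive boundary;
* least-served set `L = {s : m(s) = min m}`;
* hub score `score(h) = agg_{s in L} t(h, s)` for ECR hubs `h`;
* selected base `argmin_h (score(h), h)` (lexicographic tie-break).

Annual stroke cases per suburb are `Σ_b pop_b · rate_b / 10^5` over 5-year
age bands `b`; a hub's catchment caseload at threshold `T` (minutes or km)
sums suburb cases over suburbs within `T`. Hubs are evaluated independently;
their catchments overlap deliberately, since the question is "how much could
each candidate base service", not a partition of demand.

### Assumptions

- Each suburb's demand is concentrated at its centroid; travel times to the
  centroid stand in for the suburb average.
- Travel is directional hospital → suburb. (Routing sources can be
  asymmetric; the matrix container is explicitly directional, and a
  suburb → hospital matrix can be built by swapping the point sets.)
- Peak traffic is a uniform multiplicative slowdown (default 1.4×) on
  free-flow times. No time-of-day edge profiles, one-way streets, or
  stochastic congestion.
- Coverage is binary at the threshold: no capacity limits and no
  distance-decay weighting.

## Key parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `threshold_minutes` | 30 | min | coverage membership threshold; inclusive |
| minute catchments | 30, 45, 60 | min | caseload sensitivity analysis |
| km catchments | 20, 30, 50 | km | route-distance analog |
| `congestion_factor` | 1.4 | – | peak/free-flow time ratio |
| `fallback_speed_kmh` | 60 | km/h | haversine-provider road speed |
| `aggregator` | mean | – | hub score over the least-served set |
| `hospital_class` | all | – | membership counts all hospitals; "ecr" restricts to hubs |

"Closest hub to a set of suburbs" is genuinely ambiguous; the mean matches
the equity intent, the max gives a worst-case guarantee, the median is
robust to stragglers. All three are computed and reported; an optional
population-weighted mean reflects where the people at risk live. The
boundary convention (≤, not <) matters only on exact ties and is applied
uniformly to membership and catchments.

## Synthetic cities

`generate_city` emulates a large Australian metropolis at desk scale:

- 250 suburbs uniform over a 60 km square (WGS84 coordinates around a fixed
  origin; a small-region equirectangular mapping converts km to degrees);
- suburb sizes log-normal (σ = 0.8), age structure an 18-band census-style
  profile; a single joint multinomial draw allocates exactly
  `total_population` persons (default 5.1 M), so conservation is exact by
  construction, not by rounding;
- 5 ECR hubs + 8 thrombolysis-only hospitals co-located with distinct
  suburbs; placement probability decays as
  `exp(-bias · d_centre / extent)` with default biases 6 (ECR) and 3
  (spokes), mirroring the inner-city clustering of tertiary hospitals;
- a jittered m×m grid road network (connected by construction), edge speeds
  uniform in 40–70 km/h; suburbs and hospitals attach to their nearest node,
  attachment adds no time.

One integer seed per operation feeds `numpy.random.default_rng`; no global
RNG state.

What the generator does **not** emulate: real street topology and detour
patterns, population density gradients (suburbs are uniform in space),
correlated age structure (age mix is identical across suburbs up to
multinomial noise), coastline/harbour geography, and empirically calibrated
travel times. Passing tests therefore demonstrate correctness and the
structural behaviour of the method — monotone catchments, equity targeting,
recovery of planted deprivation — not a validated forecast for any real
city.

### Incidence schedules

Published age-specific stroke incidence tables are licensed tables, not
shipped here. The synthetic `high` profile follows an exponential age
gradient `rate_i = 2.2·e^{0.42 i}` (band index i = 0 … 17), ranging ~2 to
~2,800 cases per 100,000 person-years — the steep age dependence
characteristic of stroke. The `low` profile is 0.58× the high one, the
contrast observed between two Australian incidence studies run 13 years
apart. Real tables load from `band_lower,band_upper,rate_per_100k` CSVs.

### Planted underserved corner

`plant_underserved_region` clears all hospitals from the south-west corner
(fraction f of the bounding box per axis) and re-draws populations so the
corner holds exactly `round(share · total)` persons, totals conserved. It is
the ground truth for parameter recovery: the selected hub should be the ECR
hub nearest the corner.

Recovery is only identifiable when the corner is the *unique* deprived
region. The recovery experiments therefore use a harness city with 40
uniformly placed spoke hospitals (so every non-corner suburb keeps
membership ≥ 1 at 30 min) and strongly centre-clustered ECR hubs (bias 18,
so no hub sits beside the corner), 1 M people, corner fraction 0.35, corner
population share 0.3, and the population-weighted mean aggregator. Under
these conditions the pipeline recovers the corner-nearest hub (unweighted
mean network time to corner suburbs, exhaustively enumerated) in 97 of 100
simulated cities; the residual disagreements are sub-minute near-ties
between similarly placed central hubs.

## Numerical choices

- Haversine uses Earth radius 6371.0088 km; the argument of `asin` is
  clamped to 1 to guard floating-point overshoot on antipodal points.
- Network km is measured along the minimal-**time** path (ambulances
  optimize time); with a uniform congestion factor the minimal-time path is
  invariant between peak and off-peak, so peak minutes are exactly off-peak
  × factor, elementwise.
- Exactly co-located origin/destination pairs are forced to 0 min / 0 km.
  Under nearest-node attachment, two distinct points can share a node and
  also get 0; the "zero implies co-located" direction is therefore not
  enforced for the network provider.
- Case projections stay real-valued end to end; rounding happens only in
  formatters. CSV floats are written with 6 decimals, which (with fixed
  seeds) makes pipeline outputs byte-reproducible.
- Ties in hub scores break lexicographically by hospital id; least-served
  sets are processed in sorted order, making every result independent of
  input ordering.
- Degenerate inputs fail loudly: empty hospital classes, empty least-served
  sets, missing (hospital, suburb) pairs, duplicated CSV rows, negative
  times, disconnected network components (offending ids are named).

## Problem sizes

Tests and the acceptance script run the default 250-suburb city (Dijkstra
from 13 sources over a ~300-node grid, < 1 s), 500 random coverage
instances, 200 random selection instances, 100 random ≤ 8-node graphs
against all-simple-paths enumeration, and 20 planted-corner cities at 1 M
population. The whole suite completes in well under a minute.

## Known limitations

- A single MSU, no fleet allocation, no operating-hours rostering, no
  dispatch/cancellation modelling, no cost-effectiveness analysis.
- Coverage is unweighted by demand by default; the population-weighted mean
  is available for hub scoring but membership itself is purely binary
  reachability.
- The "least-served" definition (minimum of the membership distribution) is
  sensitive to single outlier suburbs; on real data one may prefer a
  quantile-based cutoff.
- Whether km catchments should use route or straight-line distance depends
  on the data source; both are available (network vs haversine provider) and
  the choice is recorded in the matrix provenance.
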