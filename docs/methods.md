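# Methods

## The null model

The package asks whether observed counts of established nonindigenous
species (NIS) per donor region are compatible with a null model in which
invasion success depends only on (1) the donor's available species pool,
(2) shipping-mediated propagule pressure, and (3) environmental match
between donor and recipient ports. Species traits play no role under the
null; systematic departures therefore point at trait-level differences
between donor faunas.

### Donor species pools

A donor region's pool enters as its *average* derived species richness per
equal-area coastal grid cell — averaging rather than summing avoids
double-counting species shared by neighbouring cells. Non-coastal cells are
ignored. Regions missing from the gridded source are placed on the same
scale by a cross-source correction factor: the ratio of per-grid average to
registry-style total richness in a reference region covered by both sources,
multiplied onto the other regions' totals. The factor is always computed
from the supplied reference numbers and logged, never hard-coded; for
realistic inputs it is on the order of 0.1 (regional totals run roughly ten
times higher than per-cell averages).

### Invasion probabilities

Per ballast-water route *r* from donor port *i* to recipient port *j*:

* nonindigenous: `P_ij(Non) = 1 / (1 + gamma * d_ij**(-beta))`, a sigmoid in
  port-to-port distance with midpoint `gamma**(1/beta)`;
* introduction: `P_r(Intro) = (1 - exp(-lambda*B_r)) * exp(-mu*dt_r)`;
* establishment: `P_ij(Estab) = alpha * exp(-0.5*((dT/sigma_T)**2 +
  (dS/sigma_S)**2))` on signed differences of annual mean temperature and
  salinity.

`P_r(Inv)` is their product; routes of a port pair and port pairs of a
region pair aggregate as complement products of independent events,
`P = 1 - prod(1 - p)`. The port-pair-level complement product is not forced
by the region-level formula but mirrors it one level down, which is the
consistent reading when routes are treated as independent colonization
chances.

Ballast provenance uses a well-mixed tank: the tank starts full of
first-port water at the start of the observation window (earlier history is
censored and the truncation logged), and at each later call a fraction `f`
of the tank volume is discharged — one parcel per origin currently in the
tank, proportional to its share, so discharged volume is exactly `f * V`
per call — then replaced by local water. A parcel's travel time runs from
departure at its origin to arrival at the discharging port.

### Comparison

Expected count `E = richness_A * P_AB`; observed `O` is the integer number
of checklist species native to the donor (a multi-origin species counts
fully toward each of its native regions here, unlike the fractional
composition tallies). Per pair, the one-cell goodness-of-fit statistic
`chi2 = (O - E)**2 / E` with df = 1; per recipient (or pooled over both),
the sum over donors with df = k − 1. No continuity correction and no
multiple-testing adjustment are applied.

**Display-value convention.** Report tables round expected counts half-up
to integers at or above 1 and to one significant figure below 1; chi-square
statistics to two decimals below 100 and to integers above; p-values below
.001 display as `<.001`. Chi-square statistics and their p-values are
computed *from the displayed expected value* (and the p from the displayed
chi-square): the reported statistics are exactly reproducible from the
numbers a reader of the table sees. Full-precision expected values are
retained on every result row. Expected values below ~0.005 are permitted
with a logged caveat that the chi-square approximation is unreliable there.

## Parameters

| symbol  | meaning                         | units  | placeholder default |
|---------|---------------------------------|--------|---------------------|
| alpha   | establishment base rate         | —      | 2e-4                |
| beta    | distance-sigmoid steepness      | —      | 4                   |
| gamma   | distance scale (midpoint^beta)  | km^β   | 1000^4              |
| lambda  | per-volume inoculation rate     | 1/m³   | 3e-5                |
| mu      | en-route mortality rate         | 1/day  | 0.02                |
| sigma_T | temperature niche width         | °C     | 2                   |
| sigma_S | salinity niche width            | ppt    | 10                  |

These defaults are NON-CANONICAL placeholders: the model family they belong
to is calibrated against global traffic and invasion records, and no such
calibration is attempted here. Every run using them logs a warning and the
pipeline report flags them; no shipped result depends on their values.
Units throughout: days, °C, ppt, m³, km. Distance is the haversine
great-circle distance (R = 6371 km); a `distance_fn` hook accepts a
precomputed port-to-port matrix (e.g. actual sea routes) where available.

## Fractional origin attribution

For composition summaries a species native to k regions contributes 1/k to
each (exact `fractions.Fraction` arithmetic, so region tallies sum to the
species count with no tolerance). `unknown` is a first-class donor group.
The flow-matrix operation also offers the flow-count convention (one unit
flow per native region, double-counting multi-origin species) used by
chord-diagram style visualisations. Name matching normalises case and
whitespace and strips inline bracketed synonyms
(`Genus (=Synonym) species`), the convention in curated tables. Exclusion
of vascular plants (Tracheophyta) is a generic `exclude_phyla` parameter —
the composition results are meaningful both ways.

## Synthetic worlds

The generator (`invexpect.synthetic`) emulates the statistical structure of
the pipeline's data sources: ports scattered around regional centroids with
per-region temperature/salinity regimes; ship voyages as biased random walks
(configurable intra-region affinity, travel time = distance/speed);
lognormal tank volumes with a fixed per-call discharge fraction; per-region
richness grid cells (normal around a regional mean, cv 0.15, plus
non-coastal decoys that averaging must ignore); and a species pool per
region sized as round(realized per-cell average richness) — pool size and
the analysed richness therefore agree by construction, which is what makes
the self-consistency experiment a clean test of the statistics rather than
of a pool/richness mismatch. Observed checklists are realized by independent
Bernoulli draws at the model's own region probabilities.

Default study conditions: 4 regions (two marine, two brackish; temperature
means 9–15 °C, salinity means 11–33 ppt), 4 ports per region, 30 ships ×
10 calls, richness means 45–75 species per cell, and synthetic constants
alpha 0.3, beta 2, gamma 1e6 km² (midpoint 1000 km), lambda 2e-3 /m³,
mu 0.05 /day, sigma_T 4 °C, sigma_S 8 ppt. These were chosen once so that
region-pair probabilities spread over roughly 0.03–0.6 and expected counts
over a few to a few tens of species — large enough for the chi-square
approximation, small enough that probabilities do not all saturate.

Randomness is organised as named substreams spawned in fixed order from one
`SeedSequence` (ports, environment, ships, voyages, grid, species,
realization), so a fixed seed yields byte-identical serialized worlds and
adding a generator cannot silently reshuffle existing draws.

What passing on synthetic worlds shows: the probability algebra,
provenance bookkeeping, aggregation, and chi-square machinery are mutually
consistent, the null model accepts its own data, and a 10-fold-odds donor
anomaly is reliably flagged. What it does not show: fidelity to real
coastline geometry, seasonal traffic or environmental cycles, reporting
biases in real checklists, or the calibration of the seven constants.

## Experiment design and problem sizes

* Monte-Carlo consistency: one default world, 10,000 route-level Bernoulli
  replicates per region pair, agreement within 3 binomial standard errors.
* Null self-consistency: 200 worlds; per world the pooled overall
  chi-square across all connected pairs; non-significance (p > .05)
  expected in ≥ 90% of worlds. The binomial variance E(1−p) is smaller than
  the Poisson variance the chi-square assumes, so the test errs
  conservative — observed non-significance runs ~98–99%.
* Misspecification sensitivity: 200 worlds; the connected donor with the
  smallest invasion probability toward the first region gets 10× odds
  (p' = 10p/(1+9p)); its pair chi-square should be the recipient's maximum
  in ≥ 95% of worlds (observed: essentially always).

These sizes keep the whole suite and the reproduction script each within a
couple of minutes on one core while leaving comfortable statistical margin.

## Numerical choices and degenerate inputs

* Exact rational arithmetic for origin tallies; float elsewhere.
* `P(Non)` at d = 0 is defined as 0 (same-port water is never
  nonindigenous; the raw sigmoid diverges there), and underflow of
  `d**(-beta)` for denormal distances maps to the same limit.
* Decimal round-half-up for all display rounding (not banker's rounding).
* Region pairs with no shipping connection yield probability 0 with a
  warning and are skipped by the comparison assembly (no defined
  chi-square at E = 0).
* A recipient with fewer than two connected donors has no overall test
  (df would be 0) and is reported as an error.
* Duplicate checklist rows merge by normalized name with unioned presence
  and native ranges, logged as warnings.

## Known limitations

* The distance metric defaults to great-circle; real ballast routes follow
  sea lanes, which lengthens most distances (hence the `distance_fn` hook).
* Annual-mean environmental matching ignores seasonality and within-port
  gradients; signed mean differences, not distribution distances.
* The tank model assumes perfect mixing and a constant discharge fraction;
  real ballast management is episodic and regulated.
* One-cell chi-square with very small expected values (the model produces
  some well below 1) is a rough instrument; the qualitative conclusions
  rest on discrepancies of orders of magnitude, not on marginal p-values.
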