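# Methods

## Model overview

`spchub` scores communities as candidate sites for rural secondary
palliative care hubs. The pipeline is: build a drive-time road graph →
select candidate communities (population and isolation filters) →
compute four component scores per candidate → combine into a weighted
mean → flag eligibility against a cut-point and rank.

The model is summative and deliberately simple: each component is a
[0, 1] score with a direct planning interpretation, and the final score
is their weighted mean so that component weaknesses and strengths stay
legible to decision makers. The package treats the weights as a
first-class parameter because local stakeholders are expected to
recalibrate them.

## Travel-time engine

The road network is an undirected graph. Edge cost is
`60 × length_km / speed_kmh` minutes; endpoints matching within 1 mm
merge into one node. All queries (point-to-point times, service areas,
nearest facility) are Dijkstra shortest paths over edge minutes.

Assumptions and their consequences:

* **Undirected travel.** One-way streets, turn restrictions,
  congestion and ferries are not modelled. In the rural regional
  setting the model targets, road attribute data rarely carries
  directionality; in coastal or urban applications this understates
  some travel times.
* **Free off-network access.** Communities, blocks and facilities
  attach to the nearest graph node at zero cost. With network nodes
  spaced kilometres apart, snap distances are small relative to
  60-minute catchments; with a sparse network this can mis-assign
  blocks near catchment boundaries.
* **Centroid representation.** A community is a point (its centroid),
  not a polygon; catchments and isolation times are measured from that
  point.
* **Unreachable is a value, not an error.** A community with no route
  to any palliative-care centre receives infinite minutes, which the
  isolation component maps to the maximal score of 1 and the selection
  filter treats as "more than an hour away". This is the only
  defensible reading: disconnection is extreme isolation.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `catchment_minutes` | 60 | min | population catchment and the selection drive-time filter |
| `isolation_cap_minutes` | 240 | min | drive time at which isolation saturates at 1 |
| `cutpoint` | 0.6 | score | eligibility lower bound (strict >) |
| `min_population` | 5000 | persons | selection filter (strict >) |
| `hospital_min_beds` | 500 | beds | palliative-centre definition (strict >) |
| `hospice_min_beds` | 3 | beds | palliative-centre definition (strict >) |
| `physician_ratio_max` | 1307 | persons/physician | adequate-supply benchmark (inclusive ≤) |
| `weights` | (1, 1, 1, 1) | — | component weights; normalized by their sum |
| `pcix_scaling_mode` | `max` | — | how vulnerability variables are scaled (`max`, `minmax`, `none`) |
| `display_decimals` | 2 | — | rounding at the serialization boundary only |

Boundary semantics are intentional and tested: a 500-bed hospital is
*not* a palliative-care centre, a community exactly at the cut-point is
*not* eligible, and a ratio of exactly 1307 persons per physician *is*
adequate supply.

## Vulnerability (PCIX) scaling

Each of the four PCIX variables is scaled across a reference set of
communities. Two conventions are defensible: scale by the maximum
(`x / max`, the community with the highest value scores 1) or by the
range (`(x − min) / (max − min)`). Published descriptions of the index
use "relative to the community with the highest value" language while
the printed sub-scores in the provincial demonstration (e.g. the female
share scoring ≈ 0.42–0.51) look like raw proportions rather than
max-scaled values. Rather than silently resolving the ambiguity, the
scaling mode is a visible configuration knob (`max` by default, with
`minmax` and `none` available), and the reference set is likewise
configurable: pass a province-wide community table to `run_ssm` via
`pcix_reference`, or let the candidate set itself be the reference (the
default).

The deprivation composite is the unweighted mean of seven
dissemination-area indicators, each scaled per the same mode. Three of
the conventional indicators — average income, home ownership,
employment ratio — are *protective*: a high raw value means less
deprivation, so their scaled values are complemented (1 − scaled)
before averaging. The direction vector is an explicit, overridable
parameter (`vandix_directions`) rather than a hidden convention.
Published lists of the composite name seven indicators but enumerate
six; the seventh position here is a user-defined slot with a
non-protective default direction, not a hard-coded guess.

Three rows of the demonstration's printed vulnerability table
(Haileybury, Hawkesbury, Parry Sound) disagree with the mean of their
own printed sub-scores by 0.01–0.02 at two decimals — consistent with
the published sub-scores having been rounded before the overall score
was computed upstream. The regression tests assert exact reproduction
on the nine self-consistent rows and a ±0.02 band on those three.

## Aggregation and numerics

All internal arithmetic runs at full precision; rounding happens only
at the display/serialization boundary. Two numerical choices matter:

* **Decimal aggregation.** `combine_components` converts scores and
  weights to `decimal.Decimal` (via their shortest string form) before
  forming the weighted mean. Component tables are quoted at two
  decimals, and binary-float accumulation can land imperceptibly below
  a rounding boundary (0.26 + 0.16 + 0.28 + 0.60 summing to
  1.3000000000000003, or worse, a sum landing at 0.40499…); decimal
  arithmetic makes 1.62/4 exactly 0.405 so that display rounding
  behaves predictably. With equal weights the result is the arithmetic
  mean of the four components to < 1e−12.
* **Half-away-from-zero display rounding.** `round_display` quantizes
  the decimal value of the float's shortest representation with
  `ROUND_HALF_UP`, so 0.325 prints as "0.33" and 0.405 as "0.41" —
  matching how the demonstration tables were evidently rounded —
  rather than Python's banker's rounding.

Ranking ties (identical full-precision scores) break by descending
population component, then ascending community identifier. This is a
serialization convention, not model substance: the model reports
identical scores as identical, and the tie-break only fixes row order.
Note that two communities printing the same two-decimal score (e.g.
0.41) are usually not tied at full precision; ranking always uses full
precision.

Degenerate inputs are defined, not exceptional: an all-zero catchment
map scores all communities 0; a degenerate min–max spread scores 0; an
empty candidate set yields an empty result with a warning; a dataset
with no qualifying palliative-care centre retains every
population-qualified community (with a warning) and scores their
isolation as maximal.

## Synthetic regions

Real inputs (census population centres and blocks, licensed road
networks, facility directories) cannot be redistributed, so testing
runs on generated regions.

`generate_region` emulates the *structure* the model assumes: a
connected perturbed-grid road lattice (8×8 nodes, 20 km spacing, 15% of
links removed where removal preserves connectivity, speeds uniform in
50–100 km/h, road lengths 5–35% over straight-line), communities placed
on nodes with log-normal populations straddling the 5000 selection
threshold (median ≈ 6000), blocks scattered near nodes with log-normal
populations (median ≈ 400), Beta-distributed demographic proportions
(over-75 and living-alone shares centred near 10%, female share tightly
near 50%), physician counts Poisson in population, Bernoulli(0.5)
readiness flags, and facilities of both kinds with bed counts — the
first always a qualifying hospital so every region has at least one
palliative-care centre. One seed sequence drives four independent
sub-streams (network, centres, blocks, facilities) so changing one
layer's count does not perturb the others, and output is
byte-reproducible for a fixed seed.

What the generator does *not* emulate: real spatial autocorrelation of
deprivation, settlement-size geography (population centres are placed
uniformly, not along corridors), realistic facility siting, or any
correlation between readiness and community size. Passing tests
therefore demonstrate that the *mechanics* — filtering, travel-time
computation, scaling, aggregation, ranking — are correct, not that the
model's scores are externally valid for any real region.

`generate_line_region` is a fixed six-community line network with
hand-chosen edge minutes (50/45/50/55/70) and a single qualifying
hospital at one end. Every intermediate quantity — which three
communities survive selection, each 60-minute catchment sum, isolation
minutes, all four components (as exact fractions), final scores and
ranking — was traced by hand and frozen in `LINE_EXPECTATION`, giving
an end-to-end oracle that is independent of the implementation.

The travel-time engine is additionally checked against an independent
Floyd–Warshall triple-loop oracle on ~100 random graphs of ≤ 12 nodes,
and model-level properties (score bounds, population scale-invariance,
isolation monotonicity and cap, service-area nesting, rank permutation
invariance, weight-degeneracy orderings, facility-placement
monotonicity over 50 seeded trials) are asserted on random inputs.
These problem sizes keep the whole suite and the acceptance script
within seconds while still exercising every code path at a scale where
the oracles are exhaustive.

## Known limitations

* No reprojection: inputs must share one planar metric CRS, and the
  package trusts them to.
* Point-based communities and free snapping (above).
* The candidate funnel of a real province (hundreds of centres
  filtering to a dozen) depends on licensed census and road data and is
  exercised here only on synthetic fixtures; the bundled Ontario
  demonstration covers the aggregation stages, not selection or travel
  times.
* Readiness indicators are binary and equally weighted; partial
  readiness (e.g. a college at 65 minutes) is invisible to the score.
* The 0.6 cut-point is advisory and context-dependent; the model makes
  it configurable but offers no calibration procedure.
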