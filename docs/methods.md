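# Methods

`mangroveshift` models poleward range expansion of mangroves into temperate
salt marsh from three coupled angles: climatic habitat suitability
(an ensemble of presence/absence models), dispersal opportunity (Lagrangian
drift of buoyant propagules in surface currents, with stranding and
source–sink accounting), and episodic storm-driven transport (direction and
intensity statistics of historical storm tracks during the propagule-release
season). This note describes the models, their assumptions, the synthetic
data generator that stands in for the real inputs, and the numerical choices
that matter.

## Habitat suitability ensemble

Presence/absence records (mangrove = 1, salt marsh = 0; marsh sites are
treated as potential but unoccupied mangrove habitat) are related to climate
covariates: extreme minimum air temperature (EMT, °C), mean annual
precipitation (MAP, mm/yr) and coldest-month sea-surface temperature
(SST, °C).

**Collinearity screening.** Candidate predictors are screened pairwise with
Spearman rank correlation; for any pair with |ρ| > 0.5 the lower-priority
member is dropped (priority EMT > MAP > SST). Applied transitively this
keeps exactly the top-priority member of a mutually collinear group. SST is
nearly a linear function of EMT by construction in the generator (and in the
region the generator emulates), so it is routinely excluded.

**Missing covariates.** Records inside enclosed waterbodies (lagoons) lack
SST because the gridded SST product does not resolve them; they take the SST
of the nearest non-missing cell at their waterbody's ocean inlet. Any other
gap takes the nearest non-missing raster cell to the record itself.
"Nearest" is great-circle distance on a sphere of radius R = 6371 km — the
one Earth constant used everywhere in the package — with exact distance ties
broken toward the lowest (lat, lon) cell index for determinism. Every fill
is tagged (`inlet` / `nearest-cell`), and the operation is idempotent.

**Model families.** Six families are fit behind one probabilistic-classifier
contract (fit on a covariate frame, return P(presence)):

| family | implementation | frozen hyperparameters |
|---|---|---|
| GLM | maximum-likelihood logistic regression | — |
| GAM | logistic regression on cubic-spline bases | 5 knots, degree 3, ridge C=1000 |
| CTA | single classification tree | min leaf 10 |
| FDA | linear discriminant on degree-2 polynomial basis | degree 2 |
| GBM | gradient-boosted shallow trees | 100 trees, depth 3, lr 0.1 |
| RF | random forest | 100 trees, min leaf 5 |

Backends are sklearn estimators; nothing downstream depends on that, so the
families are pluggable.

**Evaluation.** Repeated split-sample cross-validation: 10 random 70/30
partitions (both classes required in every subset; deterministic under the
run seed). Per repetition and family: the rank-based (Mann–Whitney) AUC on
the raw probabilities; TSS = sensitivity + specificity − 1 maximised over an
exhaustive threshold scan of the validation probabilities — the customary
reporting convention for this statistic — and ACC at that same threshold.
Family scores are arithmetic means over the ten repetitions (the choice of
mean over median was open; means are simpler and match the ensemble
weighting below).

**Ensemble.** Families with mean cross-validated TSS > 0.8 enter a
weighted-average ensemble, weight_i = TSS_i / Σ TSS_j. The ensemble
probability is therefore a convex combination and always lies within the
envelope of member probabilities.

**Threshold selection.** Candidate thresholds come from an exhaustive scan
of the ensemble probabilities on the full dataset (sorted unique values plus
midpoints; ties toward the lower cut) under six criteria: maximum TSS,
maximum kappa, sensitivity = specificity, predicted prevalence = observed
prevalence, minimum ROC-distance to (0, 1), and a fixed 0.5. Which criteria
the threshold toolbox of record computes, and whether on ensemble or
per-model probabilities, was an open design point; this package uses these
six on the ensemble output. The mean, median and most-conservative (max)
summaries of the candidates are then compared on sensitivity, specificity,
TSS, kappa, ACC and the binary-predictor AUC = (sens + spec)/2; the summary
that wins the most of {sensitivity, TSS, kappa, AUC} becomes the suitability
threshold (ties: higher TSS, then lower threshold). A location is suitable
iff its ensemble probability ≥ threshold (closed on the suitable side, so a
threshold of 1 is attainable only by probability 1).

**Scenario projections.** Future climate is represented by additive EMT
offsets and multiplicative MAP factors per CMIP6 scenario
(SSP1-2.6 … SSP5-8.5). Per scenario the package reports the binary
suitability of every scored point, the northernmost suitable latitude, and
percentage-suitable per named latitude region.

## Lagrangian drift and stranding

Propagules are passive surface floats: vertical motion, windage and
diffusion are neglected; transport is by the 2-D surface velocity field
only.

* **Fields.** Hourly u,v snapshots (m/s) on the cell-corner (node) lattice
  of a regular lat-lon grid. Queries are bilinear in space and linear in
  time between the two bracketing snapshots. Nodes surrounded entirely by
  land carry no velocity; if a queried cell has invalid corners, the nearest
  valid corner of that cell substitutes before the bilinear blend, so land
  values are never dragged into ocean queries.
* **Integration.** First-order Euler with dt = 1 h, matching the field
  cadence (hourly fields carry no finer information):
  Δlat = v·dt/(πR/180), Δlon = u·dt/((πR/180)·cos lat), guarded to
  |lat| < 89°. Euler is exact for constant fields, which makes the
  uniform-flow oracle exact to machine precision; for the steady double-gyre
  test flow the error decreases linearly as dt is halved.
* **Releases.** Source points map to ocean coastal cells; points inside a
  lagoon are reassigned to the lagoon's inlet cell, and duplicate cells are
  collapsed. Releases are hourly over a half-open window.
* **Stranding.** A particle strands at the first hourly position lying in a
  coastal ocean cell (an ocean cell with a land 8-neighbour) with its
  minimum floating period elapsed. The minimum float is drawn per particle
  from a continuous Uniform[1, 5] days; before it elapses, stranding is
  suppressed (not deferred with memory): a particle sitting in a coastal
  cell strands at the first eligible step. A step that would land on a land
  cell holds the particle in place for that hour. Leaving the domain
  terminates the particle (`out_of_domain`); reaching the maximum floating
  period terminates it (`expired`). Maximum floats are expressed in months
  of 30.44 days, calendar-free. Every particle ends in exactly one of the
  three states, which is what makes the conservation audit exact.
* **Density.** Trajectory density counts *distinct trajectories* per cell
  (a trajectory contributes at most once per cell, however many hourly
  positions fall there); counting positions instead would weight slow water.

Water connectivity (lagoon ↔ ocean) is 4-connected so corner-touching water
does not leak; coastal adjacency is 8-connected, the permissive reading of
"adjacent to land".

## Connectivity and destination suitability

Stranded particles are tallied by (release subregion × destination latitude
bin). Subregions are configurable half-open latitude bands with the coastal
codes SFL/CFL1/CFL2/NFL/GA (defaults 24.5–26.5–28.0–29.0–30.7–32.0° N — the
published band boundaries are in supplementary material not available here,
so these are set to respect the band ordering and the state-border landmark);
destination bins default to 0.1° of latitude, fine enough to resolve the
ecotone. Strandings on urban beaches or unclassified coast are excluded from
the matrix but tallied, so

    released = counted + excluded + expired + out_of_domain

holds on every run and is asserted by the pipeline. Each destination bin is
classified from the scored wetland points it contains: present-suitable,
future-suitable under the least-severe scenario crossing the threshold, or —
conservatively, including bins with no scored point — unsuitable. The
"northernmost reached suitable" latitude is the maximum bin centre with
strandings and a qualifying class under the queried scenario.

## Storm-track statistics

HURDAT2 second-generation text (six-hourly best-track fixes, winds in
integer knots) is parsed with per-track error isolation. For each pair of
consecutive non-coincident fixes, the initial great-circle bearing of motion
is reversed by 180° to give the meteorological direction the storm comes
from; the segment inherits the month and intensity of its from-fix. Tracks
are retained if any fix falls in a configurable region polygon (default box:
77°W–82°W ordering as lon −82…−79, lat 24–31 — the published retention
polygon is not defined, so the box is explicit configuration); segments are
filtered to the propagule-release season (August–October by default), with
an optional year-range filter for the satellite-era caveat. Directions are
binned into 16 equal sectors centred on north, half-open on the clockwise
edge, stratified by intensity class; frequencies normalise by total segment
count, and per-month tables sum to the seasonal pool.

Intensity classes: the Saffir–Simpson scale is defined in knots
(64/83/96/113/137 kt), and HURDAT2 winds are classified directly on that
scale. A km/h classifier with the conventional printed bounds
(119/154/178/209/252) is provided for presentation in km/h; the two agree at
the printed boundary equivalents but not under a blind 1.852 kt→km/h
conversion of every integer knot (the printed km/h bounds are independently
rounded — e.g. 64 kt = 118.5 km/h and 136 kt = 251.9 km/h straddle their
printed bounds), which is why the knots scale is authoritative for knots
input.

## The synthetic world

All inputs are generated with known truth, so estimates can be compared to
what was put in:

* **Coastline.** A meridional mainland edge (land to the west), at least one
  lagoon strip sealed by a barrier island with configurable inlet cells and
  land end-caps (the lagoon communicates with open ocean only through its
  inlets — verified by 4-connected flood fill), and urban beach segments on
  the open coast. Coastal habitat is mangrove south of a configurable
  ecotone latitude and salt marsh north of it.
* **Velocity fields.** `uniform` (closed-form trajectories), `double_gyre`
  (steady two-cell flow, zero normal velocity on every boundary, used for
  convergence and stream-function-conservation checks on a near-equatorial
  domain where the degree metric is nearly isotropic), and
  `coastal_jet_tidal` (spatially uniform alongshore jet with an optional
  seasonal sign reversal plus a zero-mean tidal sinusoid on the zonal
  component — hourly samples over whole tidal periods average exactly to the
  jet).
* **Occurrences.** EMT falls linearly with latitude (6 °C at the southern
  edge, lapse 1.2 °C per degree — a compressed analog of the subtropical-to-
  temperate gradient); MAP is Uniform(900, 1600) mm; SST = 0.8·EMT + 22 +
  N(0, 0.5), which makes Spearman(SST, EMT) ≥ 0.98 and exercises the
  screening path. Presence is Bernoulli with logit = −6 + 3.0·EMT +
  0.001·MAP. The slope is calibrated so the six families reach
  cross-validated TSS in the high-skill regime where all are
  ensemble-admissible, matching the discriminability of the wetland mapping
  problem this generator emulates; at n = 5000 a logistic refit recovers the
  EMT coefficient within ±25%. A 15% share of records sits inside lagoons
  with SST withheld and a waterbody id attached. Scenario truth: EMT offsets
  (+1.5, +2.5, +3.5, +5.0 °C) and MAP factors (1.00–1.05), non-decreasing in
  severity by contract.
* **Storm tracks.** Six-hourly fixes advanced along a mean heading with
  uniform jitter by great-circle destination steps; winds random-walk inside
  a stated knot range; serialisation follows the HURDAT2 v2 dialect and
  round-trips byte-identically through the parser.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mesoscale eddies, the Gulf Stream's structure and
seasonal variability (the jet is spatially uniform); bathymetry and
wave/wind effects; the spatial clustering and detection biases of mapped
occurrence points (synthetic points are uniform over coastal cells); spatial
autocorrelation between training and validation records (random CV splits
are optimistic for spatially structured data); and real storm climatology
(synthetic headings are stationary).

## Problem sizes and reproducibility

The default configuration is desk-scale: a 1/8° grid over 24–35° N,
n = 2000 occurrence records, ten CV repetitions, ~200 particles released
hourly over 24 h from 8 source cells with a 1-month maximum float, and 12
synthetic storms; a full run takes seconds on one CPU, and the native 1/24°
resolution is exercised in targeted tests. All randomness flows from a
single integer seed fanned out into named substreams per module (adding
draws in one stage never shifts another); two runs with the same
configuration and seed are byte-identical, which is why the run manifest
records stages, content hashes, seeds and the conservation audit but no
wall-clock timestamps.

## Known limitations

* Random (non-spatial) cross-validation; spatial-block CV is out of scope.
* The tree-based families are not pointwise monotone in EMT, so scenario
  monotonicity is a property of the ensemble on this data, asserted
  empirically, not a theorem.
* First-order Euler at dt = 1 h is the method of record here; it is
  diffusive on curved trajectories (quantified by the double-gyre
  convergence test) and no higher-order integrator is provided.
* The hold-at-previous-position rule for beaching steps is a modelling
  choice where the physical literature offers several (reflect, slip,
  absorb).
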