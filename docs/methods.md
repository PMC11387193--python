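# Methods

`borealfire` re-implements, as a tested library, the analysis chain that
turns sub-daily satellite active-fire detections into a gridded
description of high-latitude fire regimes and their drivers: event
tracking, non-wildfire filtering, 100-km regime mapping, Gaussian-
mixture pyroregion classification, and partial-correlation driver
attribution. Because the real inputs (a decade of 375-m active-fire
detections plus reanalysis, lightning, biomass and human-footprint
rasters) are far beyond desk scale, the package ships a synthetic world
generator with known ground truth; every stage is validated against
that truth or against closed-form oracles.

## Coordinate frame

All synthetic data live in a planar frame in kilometres, origin at the
domain's lower-left corner, y northward. The analysis the package
mirrors operates in an equal-area polar projection, so planar
kilometres preserve every geometric quantity used (areas, distances,
intersections) without geodesy. `io.read_detections` accepts the
generic `lat_or_y / lon_or_x` column pair; projecting real lon/lat into
an equal-area frame is the caller's responsibility.

## Synthetic world

The generator's defaults are the study conditions the analysis assumes,
chosen once:

- **Domain** 2400 x 2400 km (576 analysis cells of 100 km), ten annual
  fire seasons (May-September ignitions), detection lattice at
  0.375 km sampled at two fixed daily overpasses (01:30/13:30 UTC).
- **Land cover** (12-km raster): smooth seeded random fields plus a
  latitudinal zonation produce contiguous patches of ten classes -
  tundra and barren in the north, needle-leaf belts in the middle,
  broadleaf forest, grassland, cropland and urban spots in a southern
  band, lakes and peatlands throughout. Burnable = not water/barren.
- **Climate**: monthly temperature with a seasonal cycle (-30 degC
  January to ~+6 degC July baseline), a 10 degC south-north gradient,
  smooth spatial noise and smooth interannual anomalies. VPD is planted
  directly - a south-minus-north max-month gradient of
  `vpd_gradient_kpa` (default 0.5 kPa) plus spatial (0.2 kPa) and
  interannual (0.15 kPa) anomalies - and the dewpoint is recovered by
  inverting the Tetens curve. This keeps the gradient knob acting on
  VPD alone (the temperature field's own gradient cannot leak in
  through the convexity of the saturation curve) and guarantees
  dewpoint < temperature everywhere.
- **Other drivers**: log-normal lightning climatology peaking in the
  mid-south; biomass from class levels (forest 55-90 Mg/ha, tundra 12)
  modulated by smooth noise; cropland+pasture fraction by smoothing
  class indicators; wilderness anti-correlated with agriculture and
  urban influence; opaque fire-weather indices as monotone transforms
  of summer dryness; tree-type fractions from smoothed class masks.
- **Fires**: ignitions are an inhomogeneous Poisson process with
  log-intensity linear in each year's standardized max-month VPD
  (beta = 0.6 per SD) and log lightning density (0.5), restricted to
  forest/shrub/peat fuels and calibrated to 1.5 ignitions per
  10^4 km2 per year. Each fire grows as a nested discrete-step ellipse
  whose per-overpass area increment is 2 km2 x exp(0.8 x z_VPD) with
  lognormal noise; durations are gamma-distributed around 10 half-day
  steps. In pixels with wilderness fraction below 0.2 a fire is
  truncated to at most 2 steps with probability 0.85 (suppression).
  Because the VPD covariate is the ignition year's max-month value,
  both the spatial couplings and the interannual climate sensitivity
  are genuinely planted.
- **Detections**: every overpass, lattice points in the step's newly
  burning ring are emitted with probability 0.95; FRP is lognormal
  (sigma 0.7) with median equal to the fire's intensity level (itself
  biomass-modulated). Gas flares (0.2 sites per 10^4 km2, clustered in
  flaring districts) emit near-daily jittered detections year-round;
  agricultural burns emit 1-4-detection single-step clusters in
  cropland. Truth labels live in a sidecar table, never in the columns
  the tracker reads.

What the generator does **not** emulate: orbital geometry and swath
overlap, cloud/smoke obscuration, day/night FRP biases, smouldering or
holdover behaviour, and real landscape anisotropy. Passing tests
therefore demonstrate the correctness of the algorithms and the
recoverability of planted statistical structure, not the climatology of
any real region.

### Problem sizes

Tests and the acceptance script use a desk-scale preset
(`WorldConfig.desk()`): the full 2400-km domain but a 1-km lattice over
4 seasons (~50k detections per world, tracker linkage rescaled to six
pixel widths). This is a problem-size choice only; all couplings,
rates and thresholds are the defaults above. Replicate loops
(planted-effect recovery, mixture recovery) use 10-20 seeds.

## Event tracking

Detections are binned into half-open 12-hour UTC bins (epoch half-day
arithmetic). Steps are processed in order; a detection joins an active
event if it lies within the linkage distance (default 2.25 km = six
375-m pixels; bridges adjacent-scan gaps) of one of the event's
detections from the last `timeout` (default 10) steps; detections
touching two events merge them - the survivor is the event with the
earliest ignition (ties to the smaller id), and ignition lists and
lineage concatenate, so a complex always reports every constituent
start; leftover detections seed new events by single-linkage clustering
within the step; events silent for `timeout` steps are finalized.

Restricting association to the most recent `timeout` steps makes the
finalized partition *exactly* the connected components of the graph
joining detections within the linkage distance and within `timeout`
steps - the brute-force oracle the tests compare against (ARI = 1 on
every seeded world). Processing is order-independent: inputs are
canonically sorted, new-event ids are assigned in sorted component
order, so shuffling rows cannot change the atlas.

Perimeters are dissolved unions of square pixel footprints (half-width
default 187.5 m, so footprints tile the 375-m lattice exactly). Areas
are therefore exact, and when all detections sit on the lattice they
are maintained as pixel counts with the polygon built at finalization
(bit-identical areas, much cheaper). The active fire line is the part
of the cumulative boundary within the linkage distance of the step's
new detections. Event duration is the inclusive calendar-day count
from first to last detection (a single-step event lasts 1 day). FRP95
is the 95th percentile (linear interpolation) of member-detection FRP
divided by the pixel footprint area: 1 MW per 0.140625 km2 pixel =
7.1111 W m-2. The final fire type is the modal land-cover class under
the final perimeter with ties resolved Cropland > Urban > Grassland >
forest classes; events outside the raster are typed "Other".

## Filter cascade

Six rules, in order, each recorded as the first matching rule:
non-wildfire fuel types (R1, any size - the source text carries no size
cap and none is applied), winter starts (R2, applied to all fires),
the gas-flare size cutoff (R3), long-duration/low-spread events (R4:
>100 days and <1 km2/day, below 20 km2), footprints overlapping
co-located small events in more than two calendar years (R5; overlap =
positive intersection area, an event's year is its start year), and
final size below 1 km2 (R6).

The flare cutoff is the upper bound of the observation prediction
interval (default level 95%, the conventional choice where the source
states only "upper prediction interval") of an OLS regression of final
size on flare-overlap count over calibration events (<20 km2, >=1
overlapping flare site, site-in-perimeter test). The cutoff is
monotonized over the integer grid and capped at 20 km2. Fewer than ten
calibration events is an error at the API level; the pipeline then
falls back to a fixed 2.5 km2 cutoff (the low end of the reported
cutoff range) with a logged warning. Re-applying the cascade is
idempotent when the fitted cutoff model is carried along (re-fitting on
survivors is a different calibration set by construction).

## Regime mapping

A 100-km axis-aligned grid clipped to the domain. Per-cell burnable
area is the exact rectangle-overlap integral of the land-cover
burnable mask. Fire statistics use one of two membership modes:
centroid within a 250-km radius of the cell centroid (maps and
clustering) or >=30% of the fire's area inside the cell (driver
models). Burned area always sums each fire's intersection area with
the cell or disc, independent of the membership threshold, which makes
the overlap-mode cell sums conserve total burned area to geometric
precision. Annual % burned divides by burnable area (radius mode: the
burnable area within the disc, by the pixel-centre rule - the source
is silent here and the disc baseline is the consistent choice); fire
number density counts initial ignitions of member fires (complexes
contribute all their starts) per unit reference area and year;
size/duration/FRP95/start-day are unweighted means over member fires
(membership is by centroid, so no area weighting). The fire return
interval is 100 / (annual % burned), infinite for fire-free cells.
Start-day means need no year-boundary wraparound because the cascade
already removed November-February starts.

Driver rasters are aggregated to cells as the plain average of the
pixels whose centres fall in the cell, so cell mean x pixel count
conserves the raster total exactly.

## Pyroregion classification

Cells with at least one fire enter the feature matrix of the six
regime properties, z-scored per column (the scaling is recorded;
full-covariance assignments are scale-invariant, but standardization
keeps BIC comparisons across covariance families meaningful).
Gaussian mixtures are fitted by EM with k-means++ seeding, n_init
restarts (default 10) and a covariance ridge of 1e-6 x the mean
feature variance, for k = 1..9 and three covariance families
(scikit-learn's spherical, diagonal and full; "full" is the
variable-volume/shape/orientation family that model selection favours
on elongated regime clusters - note scikit-learn's spherical family
has per-component rather than shared volume). BIC is reported in the
maximized convention 2 ln L - p ln n. Degenerate or non-converged
fits stay in the table flagged unusable and are never selected.

k-selection rules: `max` (argmax), `elbow(eps)` (stop before the first
k whose gain over k-1 falls below eps x the BIC range - the flat part
of the curve adds no structure), or `fixed(k)` for replication runs
that pin k = 7. Hard labels are posterior argmaxes; the per-cell
uncertainty is 1 - max posterior (in [0, 1 - 1/k], invariant under
component relabelling).

Naming: letter 1 is C(ommon) if the cluster-mean fire return interval
is under 500 years, else R(are); letter 2 is L(arge) above 40 km2 mean
size, else S(mall); letter 3 is I(ntense) at mean FRP95 >= 100 W m-2,
otherwise E(arly) for mean start on or before day 181 (30 June,
non-leap; leap years are not special-cased) else C(ool). The intensity
test precedes the timing test - the only precedence consistent with
all seven published code rows, which the test suite reproduces
exactly.

## Driver analysis

VPD = SVP(T) - SVP(Td) with the Tetens form SVP = 0.61078 x
exp(17.27 T / (237.15 + T)) (kPa, degC). Supersaturated inputs return
negative values with a warning, or zero under the clamped variant.
The climatological fire-danger proxy picks each pixel's maximum-VPD
month on the multi-year monthly climatology (ties to the earliest
month) and reports that month's multi-year mean; the interannual
series takes each single year's VPD in that same month. Lightning
climatologies average March-October only; wilderness fractions count
only exactly-zero human-footprint pixels.

Partial Spearman correlations rank-transform all variables (average
ranks on ties) and correlate the residuals of ranked x and ranked y
after least-squares regression on the ranked covariates; every driver
is controlled for all other drivers simultaneously. Two-sided
p-values use the t approximation with n - 2 - |Z| degrees of freedom:
the rank-permutation algorithm used for plain Spearman p-values has no
published extension to the partial case, so the t approximation is
used and its type-I calibration is verified by simulation (rejection
rate at alpha = 0.05 within [0.035, 0.065] over 1000 null replicates).

Linear regime models regress log10(y + eps) on the driver set, with
eps set data-adaptively to one tenth of the smallest positive response
so zero cells stay in the fit. Group contrasts use the studentized-
range (Tukey-Kramer) procedure via scipy. Interannual climate
sensitivity correlates each qualifying cell's annual burned area, fire
number and mean size with annual max-month VPD (cells need >=5 fires
total and >=3 years with fire data) and reports per-pyroregion means
and standard deviations. Annual trends are OLS slopes on calendar year
with t-based two-sided p-values.

## Numerical and design choices

- All randomness flows from one seed through named CRC-32-tagged
  substreams, so each stage is independently reproducible and
  re-runnable from serialized artifacts.
- Geometry via shapely 2 throughout; atlas export is GeoJSON, grids
  and tables are CSV, world rasters are .npy files (deterministic
  bytes, unlike zipped containers).
- Ellipse footprints use 64-segment polygon approximations only where
  a polygon is required; point-in-ellipse tests are analytic.
- EM initialization is k-means++ with seeded restarts rather than a
  hierarchical initialization; acceptance is planted-partition
  recovery, not bitwise parity with any particular fit.
- Merged events keep the survivor's snapshot chain (monotone
  cumulative area by construction) and retain absorbed events'
  pre-merge chains under `merged_snapshots`.

## Known limitations

- The tracker's association radius is isotropic; elongated scan
  geometries or bow-tie effects are not modelled.
- R5 (repeat-burn removal) is quadratic in co-located small events via
  an STRtree; pathological stacks of thousands of identical footprints
  would be slow.
- The synthetic world cannot validate absolute regime magnitudes
  against any real region; only relative structure and algorithmic
  correctness are testable.
- Radius-mode aggregation recomputes disc intersections per cell;
  at continental cell counts this is the slowest stage.
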