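# Methods

## The mechanistic CPDI model

The model treats the water column as a flat waveguide: uniform depth *D*,
constant sound speed *c* (straight-line rays; no refraction), perfectly flat
surface and seafloor. Reflected propagation paths between a tag at depth
*z*ₜ and a receiver at depth *z*ᵣ separated by horizontal range *r* are
generated by the image-source construction: images sit at signed depths
*z* = 2*mD* + *z*ₜ and *z* = 2*mD* − *z*ₜ over the integers *m*, each with
path length *L* = √(*r*² + (*z* − *z*ᵣ)²). The (*m* = 0, +) image is the tag
itself (the direct path). Bounce counts follow from the image branch, and
the delay of each multipath relative to the direct arrival is
Δ*t* = (*L* − *L*₀)/*c*.

Each multipath is assessed against the receiver's two operating constants:
the blanking interval BI (dead time after each registered ping; 260 ms is
the longest the modelled receiver offers and the package default) and the
average maximum detection radius AMDR (the farthest distance at which
transmissions are still detected, estimated from range testing; it absorbs
source level, noise level and detection threshold, so the sonar equation
never needs explicit terms). A path with Δ*t* ≤ BI and *L* ≤ AMDR is
harmless (category 1); Δ*t* > BI and *L* ≤ AMDR is detectable-and-late and
produces CPDI (category 2); *L* > AMDR is too attenuated to matter
(category 3). Both boundary comparisons are inclusive. A tag position is
flagged when it has at least one category-2 path; the CPDI extent at a tag
depth is the maximum flagged range on the grid (contiguity from the
receiver is not required, so the definition stays meaningful if the flagged
region ever fragments).

Model assumptions worth keeping in mind: no reflection or scattering losses
are applied (amplitude depends only on path length, 1/*L* spherical
spreading), so the model deliberately over-counts detectable multipaths and
errs toward predicting CPDI — a worst-case screen for array design. Sloping
bathymetry and depth-dependent sound speed are out of scope.

Two closed forms fall out of the category-2 condition. CPDI requires a
path-length excess of at least *X* = *c*·BI (397.8 m at the defaults), so an
AMDR below *X* provably forbids CPDI everywhere — the shallow-site (25 m)
predictions are zero for every geometry for this reason, not merely
numerically. For a colocated equal-depth pair the first surface bounce
exceeds the blanking once 2*d* > *X*, giving the critical depth
*d*\* = *c*·BI/2 = 198.9 m; with the surface bounce only, the flagged region
ends at *r* = (*v*² − *X*²)/2*X* with *v* = *z*ₜ + *z*ᵣ (also capped by
√(AMDR² − *v*²)), which the gridded model reproduces exactly in
surface-only mode.

### Enumeration completeness and truncation

By default the enumerator is complete: image orders are expanded until the
smallest achievable vertical offset exceeds the requested path-length cap,
and a property test checks that raising the cap never reveals a missed
path below it. `max_arrivals` optionally keeps only the earliest arrivals.
Both modes are exposed because they make different predictions in one
regime: for a colocated pair on a 50 m seafloor, high-order paths (vertical
offsets just above 397.8 m) are late yet still inside an 843 m AMDR, so
complete enumeration flags CPDI while any reasonable truncation (the
first ~4–20 arrivals) does not — and field observations at such sites show
no CPDI. The truncated reading reflects the physical reality that a path
with many reflections loses energy at each bounce, which the 1/*L*
amplitude law ignores. Maps default to complete (conservative);
the tank-style transmission simulator defaults to the 20 earliest arrivals.

### Numerical choices

Grid nodes run 0, res, 2·res, … inclusive of the maximum range; a tag at
range 0 is legal (validation experiments moor tag and receiver on one
line, where delays reduce to *v*/*c* − |*z*ₜ − *z*ᵣ|/*c*). Arrivals are
sorted by length with ties broken by ascending (surface, bottom) bounce
counts, so outputs are deterministic; tests compare lengths at 1e-9 m.

## Receiver decoding simulator

A transmission is a train of `pings_per_train` (default 8) pings; the first
inter-ping interval is the synchronization interval, the last the checksum,
the middle ones the ID code. Real code tables are proprietary, so code
intervals are seeded uniform draws on [0.3, 0.7) s — long enough to exceed
the blanking interval (a shorter interval would self-blank), short enough
that a full train lasts the realistic 3–5 s; only the positional roles
matter here. The channel impulse response is (0, 1/*L*₀) followed by
(Δ*t*, 1/*L*) per multipath; convolving with the train gives the arrival
stream. The decoder registers an arrival iff its amplitude clears the
detection threshold and it lands at or after the end of the current
blanking interval; by default a blanked arrival does *not* restart the
blanking clock (the receiver "does not detect" blanked pings rather than
re-arming; a switch enables the re-arming variant). Detection requires
exactly the expected number of registered pings with the expected interval
pattern within a tolerance (default 5 ms — larger than the zero timing
jitter simulated, far smaller than any code interval); failures are
diagnosed as spurious ping, interval mismatch, or missing ping. Expressing
the detection threshold as the amplitude of a path of length AMDR (1/AMDR)
makes the decoder and the category criterion share one detectability
notion; across randomized geometries the two verdicts agree essentially
always, diverging only at boundary ties.

Collisions: each tag's trains start at uniform 30–90 s spacings (60 s
nominal), and two overlapping trains from different tags are both rejected.
For two tags the loss probability has an exact form — the 7 s overlap
window is shorter than the 30 s minimum spacing, so at most one competing
train can interfere and the surviving fraction is 1 − 2·3.5/60 ≈ 0.883 —
used as the Monte-Carlo reference. Partial-overlap salvage is not modelled.

## Range-test analysis

Hourly detection counts per tag/receiver pair (zero-filled over the
deployment window, UTC hour bins) are modelled as a Poisson penalized
regression spline in distance — basis dimension 6, cubic B-splines, a mild
ridge penalty (α = 1 by default; with only six basis functions the basis
dimension, not the penalty, does the smoothing) — via statsmodels' GLMGam.
Optional covariates (wind, tide, diurnal period, …) enter linearly; every
covariate subset is fitted, fits within 2 AIC units of the best form the
candidate set, and the headline curve is the pointwise median across
candidates, with candidate covariates held at their observed medians for
prediction. Predictions and standard errors are evaluated on a 1 m grid
(delta method on the log link: se(μ) = μ·se(η)).

**AMDR** is read off the curve as the first grid distance — searching
outward from the curve's maximum — at which predicted detections fall below
5% of transmissions sent (3/hour at a 60 s nominal interval); the ±1 SE
curves crossing the same threshold give the band, and a curve that never
crosses is reported censored at the grid edge. Starting at the maximum
rather than at zero range is deliberate: inside a strong CPDI hole the
prediction can dip below the threshold at the receiver itself, and the
quantity of interest is the *outer* detection limit. **CPDI extent** is the
first distance at which the prediction ±1 SE band overlaps the band around
the curve's maximum (zero when the maximum sits at the origin). The ±1 SE
width is configurable; 1 SE is the literal reading of the band-overlap
rule this estimator operationalises.

Meta-log metrics: CDE = detections/syncs and RC = checksum rejects/syncs;
the adjusted variants divide instead by pings/`pings_per_train`, a better
proxy for transmissions sent when CPDI corrupts the synchronization
intervals themselves. Zero-denominator days are reported missing and
excluded from medians, never imputed. The metrics are scale-free in the
counts.

## Synthetic data generator

The generator emulates a single-receiver mooring-line range test: tags at
fixed distances, trains of 3.5 s at uniform 30–90 s spacings, detection
thinned by a distance curve and by collisions. The detection curve is a
logistic decay (the field gives no parametric form; logistic is smooth with
a controllable crossing) times, optionally, a CPDI hole factor
1 − suppression·σ((extent − d)/width − ln 19): the offset places 95%
recovery of the suppression exactly at the stated extent, so the curve's
maximum — and therefore the band-overlap estimator's target — sits at the
hole edge rather than half a transition width beyond it.

Calibration makes recovery tests honest: the logistic midpoint is solved so
that the *expected observed* hourly count — detection probability ×
transmission rate × the analytic collision-survival factor
exp(−(n−1)·2·duration/interval) — crosses the 3/hour threshold exactly at
`amdr_true`. Collision susceptibility is distance-independent (every tag
can collide with every other); event-level overlap resolution is used up to
10 tags and independent thinning at the same probability beyond, and the
two agree to a few percent. All randomness flows from one explicit seed.

Default study conditions: distances 0–300 m every 50 m then 400, 500, 600,
800, 1,000 m (a CPDI-focused design samples the near field densely — with
uniform ~200 m spacing a basis-dimension-6 spline cannot localise a 250 m
hole edge), one tag per distance, 200 hours, plateau 40 detections/hour,
decay width 300 m, hole-edge width 40 m. What passing recovery tests shows,
and what it does not: the estimator chain recovers AMDR and hole extent to
better than 10% *under these conditions* — smooth truth curves, Poisson
noise, stationary behaviour, no environmental covariate structure, no tag
output variation, no reflection-loss physics. Real range tests add
overdispersion, weather-driven nonstationarity and sparser designs, so
field uncertainty will be larger than the synthetic bands suggest.

## Problem sizes

The deliverable's checks use 1 m grids over 0–1,000/1,200 m for the
mechanistic extents, 1,000 random geometries for the enumeration oracle
comparison, 500 random scenarios for decoder/criterion agreement, and 20
seeded range-test replicates (4 truth configurations × 5 seeds) for
parameter recovery; the whole suite runs in well under a minute.

## Known limitations

* The waveguide is ideal: no refraction, slope, or reflection loss; CPDI
  predictions are conservative (over-flagging), and the complete-enumeration
  reading over-flags most at shallow sites with large AMDRs.
* AMDR enters as a single isotropic constant; time-varying noise moves the
  real detection radius and hence the CPDI extent.
* The decoder abstracts the real receiver's code tables and signal
  processing; only blanking logic, interval matching and a scalar threshold
  are modelled.
* Collision modelling treats any overlap as mutual loss; real receivers
  occasionally salvage one of two overlapping trains.
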