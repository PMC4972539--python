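# Methods

This note documents the models implemented in `aggtrap`, the parameter
choices that matter, the synthetic-data generator's scope, and the
numerical decisions taken where the design was genuinely open.

## 1. Target-search simulation (`aggtrap.search`)

### Model

The nucleus is a sphere of diameter 400 spatial units.  `n_targets`
(default 5,000) target sites of diameter 2 represent cognate binding loci;
`n_aggregates` obstacle spheres of diameter `D` represent stable protein
aggregates.  Obstacles are placed uniformly at random, mutually
non-overlapping and fully interior (rejection sampling with a bounded
attempt budget; an impossible packing raises `PackingError`).  Targets are
then placed uniformly in the remaining space: fully interior and outside
every obstacle; targets may overlap one another (at the default density
the probability is negligible).  The aggregate volume ratio is exact:
VR = N·(D/2)³/R³; configurations with VR ≥ 50% are rejected.

A point walker starts uniformly in the obstacle-free space and takes
steps of length 1 in independent uniformly random 3D directions, one step
per tick.  A move that would leave the nucleus is rejected (the walker
stays put; the tick still counts) — rejection rather than reflection is
the simplest boundary contract that keeps the walk inside the sphere.
The walk stops as soon as the walker's position lies within a target
sphere; a walker starting inside a target reports 0 steps.  The
observable is the tick count (first-passage time in step units).

### Slowdown mechanics

Motion inside obstacles is slowed `slowdown_factor`-fold (default 100).
Whether the obstacle is evaluated at the move's origin is fixed:
inside/outside is decided at the current position before the move;
boundary crossings are not sub-resolved (the step is much smaller than
relevant obstacle diameters).  Two mechanics are implemented:

* **accept** (default): a move proposed from inside an obstacle is
  executed with probability `1/slowdown_factor`; otherwise the walker
  stays and the tick counts.  This is a pure time-change of the embedded
  unit-step walk, whose stationary measure stays uniform, so the expected
  dwell-time inflation inside obstacles is exactly the slowdown factor
  and the fold of delay approaches

      fold ≈ 1 + (s − 1)·VR/(1 − VR)

  for slowdown s and small-to-moderate VR.  Measured at the canonical
  condition (N=100, D=32, VR=5.12%, s=100): fold ≈ 6.2 (the asymptote is
  6.3; short walks under-sample deep obstacle interiors slightly).

* **speed**: the step length inside obstacles becomes `1/s` while every
  tick still moves.  The embedded chain itself then creeps inside
  obstacles; its occupancy follows the inverse local diffusivity
  (∝ 1/ℓ² = s²), so

      fold ≈ 1 + c·s²·VR,  c = O(1),

  measured fold ≈ 420–500 at the canonical condition.  Per-walk step
  counts are heavily right-tailed (a single deep excursion into an
  obstacle of radius R_a costs up to ~R_a²·s² ticks), so replicate means
  converge slowly; this mode is retained as the literal "speed divided by
  s" reading and for sensitivity analysis.

In both mechanics the *expected* fold of delay at fixed VR is essentially
independent of how the occupied volume is split into few large or many
small obstacles; apparent obstacle-size effects in small replicate
batches of the speed mechanic are tail-sampling noise.  At volume ratios
above ~10% an additional, strongly geometry-dependent regime appears:
obstacle clusters form pockets that the walker can only leave by slow
traversals, making replicate means seed-sensitive (labyrinth effect).
The package's standard conditions stay at VR ≤ 5.1%.

With `slowdown_factor=1` obstacles are inert and the fold is 1 within
error (they still exclude targets from their interior, which perturbs the
control comparison by far less than a replicate standard error).

### Engine, replication and randomness

The walker kernels are numba-compiled.  Geometry queries use uniform cell
lists storing, per grid cell, every sphere intersecting that cell, so
each tick needs one cell lookup for the target test and one for the
obstacle test; the target test is skipped while inside an obstacle
(targets cannot be reached there by construction).  Randomness is an
inline xorshift64* generator seeded through splitmix64 from the user
seed — deterministic across platforms and cheap enough for the 10⁹-tick
runs the speed mechanic requires.  In accept mode the run of rejected
ticks inside an obstacle is drawn in one shot from the exact geometric
distribution instead of tick-by-tick; this preserves the law of the
process exactly.  Both engines were validated against an independently
written brute-force numpy walker on a small nucleus (agreement of mean
first-passage times within Monte-Carlo error, both mechanics).

`run_condition` distributes `n_simulations` walks (default 2,000) over
`n_geometries` (default 20) independently sampled nucleus realizations;
FPT variance across walks dominates geometry-to-geometry variance at
these densities.  `fold_of_delay` runs a matched control with zero
obstacles under the same seed protocol and reports the ratio of means
with a bootstrap 95% CI (1,000 resamples).  A step cap (default 10⁸)
aborts runaway walks with an error; it does not censor results.

## 2. Decoy-site kinetics (`aggtrap.kinetics`)

Counts-based, spatially implicit model of facilitated search; all
formulas are closed-form (see README for the equation set).  Two
numerical points:

* The trial-sum form of the search time,
  `N_trials·(τ_3D + τ_ns) − τ_ns`, is evaluated with the excess-trial
  count factored out (`N_trials·τ_3D + (N_trials−1)·τ_ns`) so that large
  residence times cannot catastrophically cancel; the equivalence with
  the expanded form is asserted at every call (rtol 1e-12).
* The sampling interval is implemented as
  `(τ_search + τ_s)/N_TF · N_s` — the per-copy cycle time divided among
  `N_TF` parallel searchers and multiplied by the number of cognate
  sites, consistent with "doubling the copy number halves the interval".
  The flattened one-line rendering of this expression is ambiguous in
  isolation; this reading is fixed and documented here.

## 3. Synthetic data (`aggtrap.synthetic`)

The generator produces the study conditions the analyses expect, with
ground truth attached:

* **Three-state streams** (20 ms/frame by default): free molecules
  photoactivate at `activation_rate` per frame, diffuse with
  `d_fast = 3 µm²/s`, and photobleach geometrically (mean ~20 frames).
  Cluster sites host one transient episode each; episode durations are
  exponential with mean `cluster_lifetime_mean = 15 s` (the middle of the
  10–20 s range typical of dynamic clustering) or fixed when
  `cluster_episode_duration` is set.  During an episode the site emits
  molecules that diffuse with `d_cluster = 0.1 µm²/s` confined to a
  100 nm radius and disperse at episode end.  Aggregate regions are
  absorbing — a molecule entering one is immobilized permanently,
  matching the negligible molecular exchange of stable aggregates — and
  can emit their own immobile detections uniformly over the acquisition
  (`aggregate_loc_rate`).  Localization error is Gaussian, 30 nm SD by
  default (typical SMLM precision).  `d_fast`/`d_cluster` defaults are
  plausible nuclear-protein SPT scales chosen for fixture purposes, not
  measured constants.
* **Brownian track tables**: per-axis step variance exactly 2·D·Δt plus
  independent localization error per point.
* **Two-channel aggregate images**: soft-edged bright disks (channel 1)
  on background; channel 2 is a uniform level scaled by `(1+enrichment)`
  inside the disks — negative enrichment models exclusion, positive
  recruitment.  Region annotations span twice the disk radius so the
  rescaled patch contains the surround.
* **FRAP curves**: `I(t) = plateau·(1 − exp(−t/τ)) + noise`.

Not emulated: photophysics (blinking, triplets), 3D axial structure,
camera noise beyond Gaussian, motion blur.  Tests passing on these data
therefore validate the estimators' statistical behaviour, not robustness
to instrument artifacts.

## 4. Trajectory linking (`aggtrap.tracking`)

Greedy globally distance-ordered nearest-neighbour assignment per frame,
with gap closing up to `max_gap_frames` (distance budget scales with the
gap) and a minimum track length.  Input rows are canonically sorted by
(frame, x, y) first, so the result is invariant to row order; equal
distances break ties by canonical order.  This is deliberately minimal —
adequate at sparse photoactivation densities (≥95% of links match
ground-truth molecule identities in the bundled benchmark) and
deterministic; it is not a substitute for multi-hypothesis tracking at
high density.

## 5. SPT analyses (`aggtrap.spt`)

MSD curves are time-averaged over all ordered pairs at each lag; the
diffusion coefficient is the OLS slope of the first 4 lags against lag
time, divided by 4, with a free intercept (absorbing static localization
error), clipped at zero.  Estimates require ≥5 track points and a
regression R² ≥ 0.8 (0.9 available for stricter, figure-grade gating).
Four lags is the usual bias/variance compromise for ~20-frame tracks.
Histograms weight per track.  Jump angles use three consecutive points,
0° = forward persistence, 180° = reversal, with both jumps ≥ 40 nm so the
angle is not localization-noise geometry.  Mask membership uses half-open
pixel intervals; a track is "in aggregate" if any of its localizations
touches the mask.

## 6. Time-counting analysis (`aggtrap.cluster_kinetics`)

Sliding windows pool 1,000 frames and advance by 25 (0.5 s at 20 ms);
window *t* is the trailing window ending at frame (t+1)·25 − 1, so a
single-frame event is visible in exactly window/step = 40 consecutive
maps.  A region "appears"/"disappears" at the first/last window whose
in-region count reaches `visibility_threshold` (default 5 — an explicit,
testable stand-in for by-eye visibility in video reconstructions), and
the lifetime is half the visible span.  The half-span heuristic
compensates the window smearing: a burst of true duration T is visible
for ≈ T + 20 s, giving lifetime estimates of ≈ (T+20)/2 ≈ 17.5 s for
T = 15 s, inside the 15 ± 5 s recovery band, while a stable aggregate
spanning a 120 s acquisition reports ≈ 60 s.  Classification uses a
lifetime threshold of one third of the acquisition.  The density-based
region proposer is a convenience screening tool only; regions are
normally user-supplied disks or polygons.

## 7. Radial intensity analysis (`aggtrap.radial`)

Each annotated region's bounding square is cropped (regions clipped by
the image border are rejected and skipped) and rescaled to 100×100 px by
bilinear interpolation; patches are averaged pixelwise across regions;
the profile bins pixels by integer distance from the patch center
(bin r = [r, r+1) px, r = 0..49), excluding corners beyond the inscribed
disk, with radii reported on [0, 1].  No per-region intensity
normalization is applied before averaging (regions enter with their
native brightness); the exclusion/recruitment classifier is the sign of
the channel-2 center-minus-periphery contrast (innermost vs outermost 20%
of bins) with a small relative tolerance for noise.

## 8. FRAP fitting (`aggtrap.frap`)

Nonlinear least squares of `plateau·(1 − exp(−(t−t0)/τ))` on post-bleach
samples, initialized with plateau = last-quartile mean and τ = time to
half plateau; intensities are normalized (pre-bleach mean → 1,
post-bleach minimum → 0) for robustness unless disabled.  Lifetimes
longer than the observation window are reported but classified "slow":
such fits are lower bounds, not point estimates (a 45-minute lifetime
observed for 400 s is identifiable only as "beyond the window").

## 9. Known limitations

* The search simulator is a lattice-free kinetic walk, not an exact
  continuous-time diffusion; first-passage times are in step units and
  capture efficiency of a unit-step walk differs from the Smoluchowski
  continuum limit by an O(1) factor (identical in both arms of the fold).
* Facilitated diffusion (1D sliding), obstacle absorption, and fitting
  the kinetic model to experimental SPT data are out of scope.
* The speed mechanic's per-walk distributions are heavy-tailed; its
  replicate means at a few hundred walks carry large, skewed errors, and
  obstacle-size comparisons at fixed VR made in that regime are
  unreliable (see §1).
* Test problem sizes (hundreds of walks per condition, 100-replicate
  estimator benchmarks) are chosen for quick desk-scale runs; all scale
  up by configuration.
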