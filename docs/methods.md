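# Methods

## Observation model and units

Tracks are time-ordered 3D positions in micrometres at a uniform frame
interval Δt (default 30 s; movies are 61 frames ≙ 30 min; the imaged volume
is 509 × 509 × 60 µm). Speeds are always reported in µm/min; the single
conversion factor 60/Δt is applied in the metrics layer and never in
storage. Missing detections are treated as gaps: a track is split into
contiguous segments and no velocity sample ever spans a gap — interpolation
would fabricate velocity samples and bias arrest statistics downward.

## Motility metrics

* **Instantaneous velocity**: v_i = ‖p_i − p_{i−1}‖ / Δt.
* **Mean track speed**: path length / duration. At uniform Δt this equals
  the arithmetic mean of interval speeds; both are computed and the identity
  asserted, so the two conventions used by commercial software cannot
  silently diverge (they differ only with gaps, which split tracks here).
* **Track displacement length**: ‖p_n − p_0‖, a measure of directedness.
* **Pausing phase**: a maximal run of consecutive intervals with
  v_i < threshold (strict), lasting ≥ 30 s. The run rule is
  *every-interval-below*, not run-average-below: for runs of one interval
  (the 30 s minimum at 30 s sampling) the two are identical, for longer
  runs every-interval is stricter; it is local, deterministic, and
  insensitive to how a long run is windowed.
* **Arrest coefficient**: fraction of a track's intervals below the
  threshold, in [0, 1]; undefined (NaN, reported as missing, never 0) for
  tracks without intervals.

The threshold is configuration, not a constant: 4 µm/min for the in vivo
window-chamber data and 2 µm/min for spheroid cocultures, where cells move
more slowly overall.

Cohort summaries exclude tracks with fewer than 4 intervals (2 min) by
default: a 1–2 interval track yields a degenerate arrest coefficient
(only values 0, ½, 1). The filter is a parameter (`min_intervals`) and can
be disabled.

### Measurement-noise bias

Positional noise σ per coordinate inflates observed speeds: a stationary
cell shows an apparent speed of 2σ√2 · √(2/π) / Δt·60 ≈ 1.35 µm/min at
σ = 0.3 µm, Δt = 30 s. No de-noising correction is applied, matching common
practice with commercial tracking exports; instead the synthetic generator
exposes σ and its calibration accounts for the bias exactly (below), so
recovery tests are unbiased.

## Compartment classification

The tumor/spheroid boundary is a signed-distance surface (negative inside):
an analytic sphere, or a watertight triangle mesh (exact point–triangle
distance, sign by ray-crossing parity; watertightness is checked by edge
pairing). Per-spot labels: infiltrating d ≤ 0, approaching 0 < d < 10 µm,
peripheral d ≥ 10 µm. Boundary conventions are deterministic: on-surface
counts as infiltrating, exactly-at-band counts as peripheral ("closer than
10 µm" is strict).

A track's label is the time-majority of its per-frame labels, ties broken
infiltrating > approaching > peripheral; majority is stable under brief
noise-driven excursions across the surface. Per-region counts can instead
be accumulated per spot (`per="spot"`), since exported counts from imaging
software may be per-detection; per-track is the default and the one used by
all recovery checks.

## Drift correction

Global stage/tissue drift is estimated per frame as the coordinate-wise
*median* frame-to-frame displacement over all spots (median, not mean, so
genuinely moving cells do not drag the estimate), or over supplied anchor
positions; cumulative sums are subtracted. The median is
translation-equivariant, so the corrected output is exactly invariant to
any injected global translation field; with anchors the injected drift is
recovered exactly. Without anchors the estimate carries O(step/√n_spots)
noise per frame, which inflates speeds only at second order (verified in
the tests against a paired drift-free cohort).

## Spot linking

For unlinked per-frame detections, frames are linked pairwise by greedy
mutual nearest neighbours with a hard distance gate, ties broken by
distance then spot index. This is deliberately *not* a reproduction of
commercial tracking (whose parameters are generally unreported): it is a
deterministic stand-in that is provably exact when cells are separated by
more than twice the per-frame displacement — the regime the synthetic
fixtures guarantee — and performs no gap closing.

## Rejection kinetics

Spheroid volumes are consumed as exported measurements at 4 h and 18 h of
coculture. Each spheroid's early volume is set to 100% and the late volume
expressed relative to it; condition summaries are means ± SD of these
per-spheroid percentages. Normalizing per spheroid (rather than to a
condition-mean initial volume) is the only well-defined choice when
spheroids differ in initial size, and is scale-invariant by construction.

## Statistical pathways

Two comparisons are exposed, mirroring standard practice:

* **pooled**: every track is one observation; two-sample two-sided
  Kolmogorov–Smirnov test (exact null distribution when n·m ≤ 10⁴,
  asymptotic otherwise).
* **per-experiment**: track metrics are first averaged within each
  biological replicate; the experiment means are compared with an unpaired
  two-tailed t-test. The Welch (unequal-variance) form is used — the
  equal-variance assumption is not defensible a priori for 3–6 experiment
  means — and the output records the choice.

Significance is flagged at α = 0.05 per comparison with no multiple-testing
correction by default. Pooled and per-experiment tables are always emitted
together because with unbalanced experiments the two weightings give
different group means; the reporting layer never mixes them.

## Synthetic cohort generator

Each cell is a two-state hidden-Markov correlated random walk:

* Per 30 s step the cell is **motile** (speed s_M) or **arrested** (speed
  s_A, default 1 µm/min — arrested cells probe slowly rather than freeze,
  keeping them below both pause thresholds while exercising the
  strict-inequality logic). Transitions use per-step probabilities with
  stationary arrest fraction π_A = p_MA/(p_MA + p_AM) and a mean motile
  dwell of 2 min; initial states are drawn from the stationary law, so
  occupancy is unbiased from frame 0.
* Step directions follow a von Mises–Fisher distribution about the previous
  direction (κ = 1 by default: mildly persistent, consistent with the
  "random walk with abrupt turns" character of intratumoral migration).
* Cells are placed uniformly within their compartment (inside the sphere /
  in the 0–10 µm shell / in the far field, all intersected with the imaging
  volume, via rejection sampling) with per-group placement fractions
  realized exactly by largest-remainder rounding.
* Observed positions add isotropic Gaussian noise σ = 0.3 µm — a typical
  centroid localization error for cell-scale two-photon imaging.

**Boundary rule.** At the imaging-field faces and at compartment
boundaries, a blocked step's *direction* is resampled (persistent first,
then uniform; in the vanishing residual case the cell holds position).
Resampling directions rather than reflecting positions preserves step
lengths, hence the calibrated speed process, exactly. Cells are confined to
their placement compartment: biologically this encodes that infiltrated
cells remain engaged within the parenchyma and surface-scanning cells stay
near the surface over a 30 min movie; operationally it makes the placement
compartment recoverable by classification, which is what the recovery tests
require. Cross-compartment migration over 30 min is therefore *not*
modelled.

**Calibration.** Measurement noise adds a floor to observed speeds. The
expected observed interval speed for true speed v is the mean of a scaled
noncentral chi distribution (k = 3, scale σ√2, noncentrality L/(σ√2) with
L = vΔt/60), available in closed form; the generator solves the stationary
mixture (1 − π_A)·g(s_M) + π_A·g(s_A) = target mean for s_M by Brent's
method. With σ = 0 this reduces to the linear mixture. The closed form is
validated against Monte Carlo in the tests; recovered cohort means are
unbiased to within sampling error (≲ 0.5% at 10 × 120 tracks).

**Preset parameters.** Group mean speeds, placement fractions, the
thresholds, frame geometry, and relative-volume targets are taken from the
published group statistics the presets encode (e.g. infiltrating DSFC
means 4.83/4.85/8.05 µm/min; spheroid IL-18R-deficient compartment means
2.03/2.56/2.00 µm/min early and 3.21/2.99/5.06 µm/min late; relative
volumes 125/69/55/47%; ≈40% vs <20% infiltration). Quantities that were
never printed are fixed package choices, made once: arrest fractions
(0.20 / 0.35 / 0.45 / 0.55 for WT-Panc02 / WT-PancOVA / Il1r_ko / Il18r_ko
in vivo; 0.15–0.50 in spheroids) reproduce the published *ordering* of
arrest coefficients, not numeric values; approaching/peripheral speeds in
vivo (5.5 / 6.0 µm/min, equal across genotypes) encode the reported absence
of genotype effects outside the tumor; WT and IL-1R-deficient spheroid
speeds (≈ 2–2.6 µm/min) respect the reported early→late decline and the
faster periphery at 18 h.

**Volume generator.** Early volumes are lognormal around 2 × 10⁶ µm³; the
late/early ratio is the condition target times unit-mean lognormal noise
with CV 10% (spheroid-to-spheroid variability), so the expected relative
volume equals the target exactly.

## What the synthetic data does and does not establish

Passing recovery tests shows the pipeline measures what the generator
produces: unbiased speed/arrest/compartment/volume estimation under
measurement noise, state switching, confinement and drift. The generator
does **not** emulate: cell–cell collisions and contact-driven slowing,
chemokine-directed migration, compartment crossing, killing dynamics
coupling arrests to volume change, segmentation/tracking errors other than
Gaussian centroid noise, or non-spherical tumor geometry (meshes are
supported as inputs but presets use spheres). Agreement on synthetic
cohorts therefore validates the *analysis*, not any biological claim about
real imaging data.

## Problem sizes and numerical choices

Recovery checks use the preset sizes (300 tracks/group in vivo, 4 × 120
tracks/group in spheroids, 61 frames, 10 (in vivo) or 5 (spheroid) seeds,
1000 spheroids per condition for kinetics) — large enough that 3-SE
recovery bands are a few percent of the targets, small enough that the
whole suite runs in about a minute. Degenerate inputs are handled
explicitly: empty velocity series → NaN arrest coefficient with a warning;
single-frame cohorts → drift correction no-op with a flag; empty track sets
→ empty summaries, not errors. Tie-breaks (compartment priority, linking
order) are deterministic and documented above. All randomness derives from
one root seed per run through `numpy` SeedSequence spawning, so every
output is exactly reproducible.
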