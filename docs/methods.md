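# Methods

This note documents the models, numerical choices and limitations behind
`embryomorph`. Everything quantitative here is computed by the test suite or
by `scripts/acceptance.py`; nothing is asserted that the code does not
verify.

## Coordinate and image conventions

Arrays are indexed `(z, y, x)`, 0-based; world coordinates are micrometres,
also ordered `(z, y, x)`; the world position of voxel `i` along an axis is
`origin + i · spacing` (voxel-centre convention). Spacing is isotropic —
anisotropic inputs are rejected rather than silently resampled. Intensities
are interpolated trilinearly, labels by nearest neighbour; out-of-domain
samples take a padding value of 0. Gaussian smoothing uses reflective
boundaries so constant images are fixed points and no edge dimming leaks
into masked statistics.

## Registration engine

Transforms map fixed-space (template) world points to moving-space
(specimen) world points; warping a specimen onto the template grid uses the
transform directly, and propagating template labels onto a specimen uses
its inverse. A composite transform stores stages in the order they were
fitted and applies the most recently fitted stage first, which is the
composition that arises when each stage is optimised against the
previous stages' resampled output.

* **Stages.** Rigid (3 rotations + 3 translations about the fixed-domain
  centre), similarity (+ isotropic scale, parameterised as log-scale),
  affine (9 matrix entries + translation), then cubic B-spline free-form
  deformations on progressively finer control lattices. The default
  schedule runs rigid/similarity/affine over 3-level image pyramids
  (downsampling 4/2/1) followed by five B-spline levels with control
  spacings 64 → 32 → 16 → 12 → 8 voxels; the similarity stage can be
  disabled. A `compact_schedule` with two B-spline levels (16 → 8) is the
  practical choice for ≲64³ volumes and is what the tests use.
* **Metric.** Normalised cross-correlation over the fixed image's
  foreground (threshold at 5 % of the intensity range, dilated twice),
  chosen because it is invariant to affine intensity rescaling — specimens
  acquired with different staining/equipment have different intensity
  profiles, and NCC ignores that.
* **Optimiser.** Regular-step gradient ascent with step halving whenever a
  candidate step fails to improve the metric, stopping when the step drops
  below 10⁻³ of its initial value (default 2 voxels for linear stages, 1
  for deformable). Gradients are analytic in the metric and the sampled
  moving-image gradient; linear-stage parameter Jacobians use central
  differences on the (12 or fewer) parameters, and B-spline gradients
  scatter the per-voxel force field onto the control lattice via separable
  cubic-kernel correlations with a trilinear sampling at control-point
  positions (an approximation that only affects the ascent direction, not
  the metric). The optimisation is fully deterministic; the run seed is
  recorded and would key any stochastic voxel sampling, which is off by
  default.
* **Regularisation.** An optional bending-energy penalty on the finest
  B-spline level (weight 0.01 by default) approximated by the squared
  discrete Laplacian of the control lattice; it discourages folding on
  noisy inputs and can be set to 0.
* **Inversion.** Linear stages invert in closed form; deformable stages by
  fixed-point iteration of `v ← −u(x + v)` on a reference grid, wrapped in
  a dense displacement field. Inversion first checks the Jacobian
  determinant sign over the domain (folded transforms have no inverse and
  raise), then verifies the round-trip residual `max ‖T(T⁻¹(x)) − x‖` on a
  probe grid against a tolerance defaulting to a quarter voxel.

## Population average

A designated (or randomly drawn) specimen seeds the rigid pass; all
specimens are then re-registered to the current average once per schedule
stage (rigid, …, each B-spline level), with intensity standardisation
(mean 0 / sd 1) before each voxelwise arithmetic mean so bright specimens
cannot dominate. The per-pass mean absolute residual to the average is
recorded and is non-increasing on clean cohorts. Because rigid composition
only changes pose, the rigid-stage average is independent of the seed
choice up to a global pose — verified by rigidly aligning averages built
from different seeds. A fixed number of passes (one per stage) is run
rather than iterating each level to convergence; the schedule is the knob
if more refinement is needed.

## Label propagation and organ volumes

Specimen-space segmentations take the atlas label at `T⁻¹(x)` with
nearest-neighbour sampling. Organ volume = voxel count × spacing³, reported
in mm³. The whole-embryo volume (WEV) is the volume of the union of all
foreground labels; the atlas metadata's `is_whole_embryo` entry names the
embryo-envelope label that anchors this convention (a single-valued label
map cannot carry a separate whole-body label that also contains the
organs). WEV z-scores are computed against the wild-type WEV distribution
so developmentally delayed specimens can be spotted and excluded. Labels
flagged thin — maximum interior Euclidean distance strictly below 1.5
voxels, computed with a one-voxel background pad so the image border counts
as exterior — are excluded from statistics at configuration time, not baked
into the atlas. As a cross-check, the specimen-space propagated volume of a
structure agrees with the integral of the full-transform Jacobian
determinant over its atlas-space label; at 64³ both routes carry ~4–5 %
voxelisation error for organs of ~4-voxel radius, so the 5 % agreement is
asserted for structures of radius ≥ 5 voxels where discretisation no longer
dominates.

## Jacobian morphometry

Deformable-only displacement fields (B-spline stages of the composite;
rigid/affine pose and scale excluded so they cannot masquerade as local
volume change) are differentiated by central finite differences (one-sided
at boundaries); `det(J) > 1` means the specimen is locally larger than the
template. Raw determinants — not logs — feed the statistics, with a log
option off by default. Fields are smoothed with a 100 μm FWHM Gaussian
(σ = FWHM / 2√(2 ln 2)) *before* masking, so boundary voxels see their true
neighbourhood rather than a sentinel; outside-mask voxels are set to NaN
and excluded from testing. Voxels with `det(J) ≤ 0` indicate folding and
are counted and mapped for QC.

## Statistics

* **Model.** `organ volume / WEV ~ genotype + WEV` per organ (and
  `voxel ~ genotype + WEV` per voxel), ordinary least squares with
  two-sided p-values on the residual degrees of freedom. The WEV covariate
  is the substage surrogate; omitting it (a supported ablation) lets
  substage-correlated size differences masquerade as genotype effects,
  which the acceptance tests demonstrate and the covariate removes.
  Zero-residual-variance fits (constant voxels in masked background) return
  p = 1 with a degenerate flag instead of failing.
* **Permutation null.** Synthetic mutant lines are sampled from the
  baselines without replacement, sizes allocated to match the empirical
  line-size proportions exactly (largest-remainder rounding); sampled
  specimens are removed from the baseline side of their own fit so no
  observation appears in both groups. A warning fires when fewer than 500
  distinct synthetic lines are possible, after which the null is coarse.
* **Threshold search.** Candidate thresholds are the observed (pooled
  null + alternative) p-values at or below 0.05, scanned descending; the
  first whose estimated FDR (null fraction / alternative fraction at or
  below it) is under the target wins. Gene-level target 5 %, single-specimen
  target 20 % (single-specimen tests have little power, so a looser FDR is
  the price of any sensitivity). Because candidates are themselves observed
  p-values, a unit whose p-value *is* the chosen threshold is called
  significant (ties between null and alternative p-values have measure
  zero, so this does not inflate the FDR — confirmed by the calibration
  runs). The printed ratio direction in some descriptions of this procedure
  is inverted; the alternative/null variant is available behind
  `literal_ratio=True` but is not the default because it does not control
  the FDR at the target.
* **BH fallback.** When a contrast uses every specimen at once (e.g. a
  whole-cohort sex comparison) permutation is impossible, and
  Benjamini–Hochberg across organs at q < 0.05 is used instead.
* **Staging.** `organ volume / WEV ~ WEV` on baselines, BH across organs;
  the WEV coefficient's sign classifies organs as proportionally larger or
  smaller later in development.

## Phantom generator

The generator encodes the study conditions the statistics are validated
under. A 64³, 14 μm grid carries an ellipsoidal body (semi-axes ≈ 0.78/0.52
of the half-extent) containing eight disjoint spherical organs of radius
3.5–5.3 voxels. The substage parameter `s` (1 = nominal stage) scales the
body linearly, so WEV ∝ s³; each organ's radius scales as `s^a` with
allometric exponents spanning 0.8–1.3, so normalised volumes trend both up
and down with substage — the confound the WEV covariate must absorb, by
construction. Organ 7 is a gonad analogue whose volume is halved in
females. Biological variability is lognormal multiplicative noise on organ
volumes (CV 8 %, the low end of the reported wild-type organ-volume spread
after whole-volume normalisation) and 2 % on body volume; cohort substages
are uniform on (0.9, 1.1). Genotype effects multiply organ volume, gated by
a per-specimen Bernoulli penetrance draw, with lognormal expressivity; the
effect stream is consumed deterministically for every organ so a
zero-penetrance line reproduces the wild-type volumes of the same seed
exactly. Specimens get uniform rigid poses (±6°, ±2 voxels) and additive
Gaussian noise (σ = 0.02 against a 0.02/0.35/0.45–0.72
background/body/organ intensity scale). Per-specimen seeds derive from a
master seed, making cohorts byte-reproducible.

What the phantoms deliberately do not model: realistic anatomy and contrast
gradients, staining and beam-hardening artefacts, anisotropic or
non-ellipsoidal organ shapes, litter structure, and registration-hostile
features like touching organs. Passing tests therefore demonstrate the
machinery (calibration, recovery, inversion, schedules) under controlled
conditions, not segmentation accuracy on real micro-CT embryos.

## Problem sizes

The suite and the acceptance script run at desk scale by choice: statistics
experiments use analytic truth tables (50–93 baselines, 1000 permutations,
20 replicates) where image processing would add nothing; registration
contracts run on 48³–64³ phantoms with the compact schedule, and schedule
fidelity is checked by executing the full default schedule on a 32³ pair.
Early stopping (step-size collapse) makes the default iteration counts
(200 linear / 300 deformable) cheap on converged stages.

## Known limitations

* The registration engine is a compact gradient-ascent implementation
  adequate for phantom-scale validation; production registration of real
  embryo volumes would want stochastic sampling, multi-threading and
  stronger optimisers.
* Nearest-neighbour propagation biases volumes of structures a few voxels
  across; organ-volume accuracy at 64³ is ~5 % for 4-voxel-radius organs.
* OLS p-values are exact only under Gaussian errors; the permutation
  thresholds inherit mild conservatism/anticonservatism when residuals are
  non-normal (e.g. the bimodal gonad analogue), which the calibration tests
  bound empirically.
* Mixed-effects (litter) models, cluster-extent voxel inference and
  intensity-based voxel statistics are out of scope.
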