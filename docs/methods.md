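# Methods

## Problem

Gamma Knife stereotactic radiosurgery (GK-SRS) plans are drawn on MRI, and
MRI carries patient-specific geometric distortion (PSD): magnetic
susceptibility differs by ~9 ppm between tissue and air, so the B0 field is
perturbed near air cavities, and off-resonance Δf translates into a spatial
shift along the frequency-encoding (readout) axis.  Vestibular schwannomas
sit next to the pneumatized temporal bone, so their apparent position and
shape — and therefore the dose distribution planned on them — are
distortion-sensitive at the millimetre scale that matters for
single-fraction radiosurgery.

`psdcorr` implements the full correction chain and its evaluation:

1. **Field mapping.** From dual-echo gradient-echo phase,
   `Δf = Δφ / (2π ΔTE)` (equivalently `ΔB = Δφ/(γΔTE)`), with spatial phase
   unwrapping inside a head mask.  Field maps are stored in Hz; Tesla is a
   derived view through γ/2π = 42 577 478.518 Hz/T.
2. **Displacement.** `Δx = Δf / BW` pixels along the readout axis, BW the
   readout bandwidth per pixel.  Polarity is configurable because gradient
   polarity is sequence-dependent.
3. **Jacobian-compensated unwarping.** Because the distortion is 1D, the
   deformation Jacobian reduces to `det J = 1 + ∂(Δx)/∂x` along the readout
   axis (central differences, one-sided at boundaries).  The correction is
   the pull-back `corrected(x) = distorted(x + Δx(x)) · det J(x)`, which
   conserves integrated signal.
4. **Learned field prediction.** A patch-based 3D U-Net regresses the field
   map from the (distorted) anatomical image, so the correction can be
   applied to sequences for which no phase data were acquired.
5. **Evaluation.** Field fidelity (NMSE, SSIM), contour agreement (Dice,
   Hausdorff max and 95th percentile, centroid shift, volume) and
   radiosurgery plan indices (Dμ, Dmax, Dmin, D95%, TC, Paddick CI,
   gradient index, homogeneity index) with paired two-sided Wilcoxon
   signed-rank comparisons (exact for n ≤ 25, zero differences dropped).

## Warp conventions and numerics

The displacement field lives in the undistorted frame: a feature at true
position x appears at `x + Δx(x)` in the distorted image (polarity +1
shifts toward increasing index).  `unwarp` is the direct pull-back above
and is exact given the true field.  The simulator `forward_warp` needs the
inverse map `x_t(y)`; it is obtained by fixed-point iteration (≤10 steps,
0.01 px tolerance, convergent whenever there is no fold-over), after which
`distorted(y) = true(x_t(y)) / det J(x_t(y))`.  With this pairing,
forward-then-unwarp round-trips to interpolation accuracy and per-line
signal is conserved by construction (change of variables).

Interpolation is a line-wise cubic spline along the readout axis (linear
for masks and for the inner fixed-point lookups); out-of-field samples are
zero (air).  Fold-over (`det J ≤ 0`) raises an error naming the offending
voxel rather than being clipped silently — it signals non-physical
field/bandwidth combinations.  Masks are re-binarized at 0.5 after
geometric warping, without Jacobian weighting.

## Synthetic phantom

The phantom emulates the distortion-relevant anatomy, not MR physics:

* ellipsoidal head (soft tissue χ = −9.05 ppm SI) with a thin bone shell
  (−11.4 ppm) in air (+0.36 ppm);
* tubular ear canals entering laterally, each ending in an ellipsoidal
  air-cell bulb (default semi-axes 6×7×7 mm) that emulates temporal-bone
  pneumatization — this places the adjacent tissue in the marked-distortion
  zone where these tumors occur;
* a nasal air cavity;
* a quasi-spherical target (default 2.7 cc, drawn volume jittered ±25%,
  centre jittered ±2 mm) wrapped around one bulb tip; the sphere radius is
  rescaled so the realized voxel volume matches the drawn volume after
  carving away air and clipping to the head;
* anatomical contrast: piecewise intensities (tissue 1.0, bone 0.25,
  target 1.6), Gaussian edge smoothing (0.8 voxel), a smooth random
  multiplicative bias field (±10%) and additive Gaussian noise (σ = 0.02).

The induced field is the k-space dipole convolution
`ΔB(k) = B0 χ(k) (1/3 − k_z²/|k|²)` with the k=0 term zeroed (zero-mean
convention) and ≥32-voxel padding with the air value to suppress periodic
wrap-around.  Against the closed-form external field of a sphere,
`Δχ B0 a³ (3cos²θ−1)/(3r³)`, the implementation is within a few percent
RMS outside a 2-voxel shell at 64³ and improves with resolution.  The χ
map is smoothed by 1 voxel before the convolution: voxel-sharp χ steps are
a discretization artifact whose field gradient would exceed fold-over at
clinical bandwidths, while real interfaces are partial-volume blurred.

At the defaults (3 T, 220 Hz/px, 1 mm voxels) the maximum in-head
displacement is ≈1.7 mm and the target centroid moves ≈0.4 mm along the
readout axis only — bracketing the ~1 mm interface-distortion scale
reported for this anatomy.  What the phantom does **not** model: real ceT1
contrast and its lesion heterogeneity, fat/water chemical shift,
machine-specific distortion, motion, and contour variability.  Passing
tests therefore demonstrate the correctness of the correction machinery
and the learnability of the anatomy→field mapping at desk scale, not
clinical performance.

## Field-map predictor

Architecture: single-channel 3D U-Net with three ResNet stages per side.
Encoder stages are a stride-2 k=3 convolution followed by an identity
residual block; decoder stages are nearest-neighbour ×2 upsampling (chosen
over transposed convolution to avoid checkerboard artifacts), skip
concatenation, and a projected residual block.  Output is a k=3
convolution to one channel; input spatial dimensions must be divisible by
2^levels.  Rectifiers are leaky (slope 0.1): with the narrow desk-scale
layers, hard rectification can permanently silence a meaningful fraction
of a layer at initialization.

The network and its training loop are written directly in NumPy (one
matrix product per kernel offset, hand-derived backward passes verified
against finite differences in the test suite; Adam optimizer).  This keeps
the package free of a deep-learning framework dependency and fully
deterministic under a seed at the cost of speed, which the desk-scale
defaults absorb.

Training: L1 loss on aligned (anatomy, field) patch pairs drawn uniformly
from the head bounding box, re-drawn each epoch from seeded generators;
Adam with β = (0.9, 0.999), constant learning rate by default (a cosine
decay is available).  Patches are randomly mirrored along the axes
perpendicular to B0 — the dipole kernel is even in each k component, so a
mirrored susceptibility distribution induces exactly the mirrored field,
making these flips physics-preserving augmentation.  Inputs are normalized
per volume by a robust z-score (median/IQR inside the head mask); field
targets are divided by a single global scale (RMS of training fields
inside the head).  Both scales are stored in the model manifest and undone
at prediction.  Best-validation weights are retained.  Whole-volume
prediction tiles 50%-overlapping patches, averages overlaps, applies
test-time averaging over the same mirror flips, and zeroes the result
outside the head mask.

Desk-scale defaults (chosen so the full study runs on one CPU): 32³
patches, 3 levels, 4 base channels (~1.3×10⁵ parameters), 8 patches per
volume, batch 2, 10 epochs, lr 2×10⁻³.  The full-scale recipe (64³
patches, 16 per volume, lr 2×10⁻⁴, 150 epochs, wider channels) remains
reachable through the same configuration objects.  The learning-rate and
width defaults reflect the much smaller network and step budget; with only
~800 optimization steps the original 2×10⁻⁴ would leave the regressor far
from convergence.  At this step budget the final amplitude of the
predicted field retains noticeable run-to-run variability, which
propagates into the binarized-contour metrics (see Known limitations);
the flip augmentation and test-time averaging are there primarily to
damp that variability.

Predicted fields are post-processed in the pipeline by normalized
(masked) Gaussian smoothing (σ = 1 voxel): patch stitching leaves
small-scale noise whose displacement gradient can be unphysically steep,
and the normalization avoids attenuating the field at the head/air-cavity
boundary where the target sits.  Outside the mask the field decays
smoothly to zero instead of stepping.

## Dose model and indices

Shots are isotropic 3D Gaussians; a plan is a weighted sum rescaled so the
maximum equals `rx / rx_isodose_fraction` (default 12 Gy at the 50%
isodose, so Dmax = 24 Gy).  A plan is fitted to a target by placing a shot
at its centroid with σ such that the single-shot 50% isodose sphere
matches the target's equivalent-sphere radius (optional extra shots along
the principal axis).  Collimator presets map {4, 8, 16 mm} to σ = {2, 4,
8 mm}.

D95% is the empirical order statistic of target voxel doses (no
interpolation); the prescription isodose volume is computed on the whole
grid, as required by the conformity and gradient denominators.  For a
single Gaussian shot prescribed at 50%, isodose radii satisfy
`r(d) = σ√(2 ln(Dmax/d))`, hence GI = (ln4/ln2)^{3/2} = 2√2 independent of
σ — used as an analytic check.  The homogeneity index defaults to
Dmax(target)/rx (exactly 2 under the 50% prescription covering the hot
spot); an ICRU-style (D2%−D98%)/D50% variant is selectable because
reporting conventions differ.

The study mirror: dose is planned on the corrected contour and the same
grid is evaluated against the corrected (after) and uncorrected (before)
contours, emulating planning on corrected images with dose copied to
uncorrected geometry.

## End-to-end study and reproducibility

`run_experiment` generates a cohort (default 20 training + 3 validation +
6 test phantoms at 64³, 1 mm), trains the predictor on distorted-image →
true-field pairs, and on held-out cases corrects image and contour with
the predicted field, alongside a ground-truth-field correction that serves
as the ceiling (oracle dominance is asserted in the tests).  Geometric and
dosimetric metrics are tabulated per case and compared with the paired
Wilcoxon test when ≥5 informative pairs exist.

Every stage derives its seed from the global seed by fixed offsets
(`stage_seed`), so stages can be rerun in isolation and identical
config+seed reproduce metric tables bit-identically and the same weight
hash.  Each run writes a manifest (config, per-stage seeds, weight SHA-256,
stage timings).

## Known limitations

* The 1D distortion model ignores phase-encode (EPI-type) distortion and
  in-plane deformable components; this matches the correction being
  evaluated, not all MRI distortion.
* The Gaussian-shot dose model has no beam/collimator physics or tissue
  heterogeneity; indices are meaningful relatively (before vs after), not
  absolutely.
* The NumPy network is small; at desk scale it under-predicts field
  amplitude in proportion to its limited training budget, which is why the
  ground-truth-field ceiling is reported next to it.
* Contour corrections pass through a 0.5 re-binarization, so sub-voxel
  differences in predicted displacement flip whole voxel layers; the
  centroid-error statistics of a six-case test split are therefore
  noticeably sensitive to the training run.  The ground-truth-field
  ceiling is stable; the predictor-path numbers carry this extra variance.
* Because of the same double binarization (distort, then correct), the
  ground-truth-field correction is only an *approximate* upper bound for
  contour overlap: a slightly different (e.g., smoothed predicted)
  displacement can occasionally land the re-binarization marginally closer
  to the original contour.
* Hausdorff distances are surface-voxel based and inherit half-voxel
  discretization error.
* The SSIM "global" mode evaluates the similarity formula once per volume
  with unsquared stabilizers c1 = 0.01L, c2 = 0.03L; the windowed variant
  with conventional squared constants is available and the two are not
  numerically comparable.
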