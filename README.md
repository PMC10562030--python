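# psdcorr

Patient-specific susceptibility distortion correction for MRI used in
Gamma Knife stereotactic radiosurgery (GK-SRS) planning — and the tools to
quantify what that distortion does to plan quality.

## The problem

Magnetic susceptibility differs by about 9 ppm between air and tissue, so
the B0 field is perturbed near air cavities and every voxel with
off-resonance Δf is displaced along the frequency-encoding axis by

    Δx = Δf / BW   pixels,       Δf = Δφ / (2π ΔTE)   (dual-echo phase),

with BW the readout bandwidth in Hz/pixel.  For targets next to the
pneumatized temporal bone — vestibular schwannomas are the canonical case —
this shifts and deforms the contour by around a millimetre, which is
dosimetrically meaningful for single-fraction radiosurgery.  Because the
distortion is one-dimensional, the deformation Jacobian reduces to
`det J = 1 + ∂(Δx)/∂x` and the correction is the signal-conserving
pull-back

    corrected(x) = distorted(x + Δx(x)) · det J(x).

`psdcorr` implements this chain end to end:

* **field mapping** from dual-echo phase (with spatial unwrapping), or
* **learned field prediction** with a patch-based 3D U-Net (ResNet
  encoder/decoder stages, written in NumPy with hand-derived backprop)
  that regresses the field map directly from the anatomical image;
* **displacement + Jacobian-compensated unwarping** along the readout axis;
* **a synthetic susceptibility head phantom** (air cavities, k-space
  dipole field, forward distortion) that makes the whole pipeline
  buildable and testable without clinical data;
* **evaluation**: NMSE/SSIM for field maps, Dice/Hausdorff/centroid/volume
  for contours, and GK-SRS plan indices (Dμ, Dmax, Dmin, D95%, TC, Paddick
  CI, gradient index, homogeneity index) on simulated Gaussian-shot dose
  grids prescribed 12 Gy at the 50% isodose, with paired Wilcoxon
  signed-rank comparisons.

All volumes are NIfTI-1; field maps in Hz, displacements in mm, doses in
Gy, masks as uint8.  See `docs/methods.md` for conventions, parameter
defaults and limitations.

## Worked example

Simulate a distorted acquisition of a head phantom (3 T, 220 Hz/px, 1 mm
voxels) and measure what the distortion did to the target contour:

```sh
$ psd simulate --seed 3 --out-dir case3
$ psd evaluate-geometry --mask-a case3/target_mask.nii.gz \
                        --mask-b case3/target_distorted.nii.gz
{
  "dice": 0.9551401869158879,
  "hausdorff_mm": 1.0,
  "hd95_mm": 1.0,
  "centroid_shift_mm": [
    -0.4913741995709202,
    -0.028512471135421436,
    -0.007869725902516223
  ],
  "volume_a_cc": 2.145,
  "volume_b_cc": 2.135
}
```

The distortion moved the 2.1 cc target 0.49 mm along the readout axis
(axis 0) and essentially nothing along the other two — the signature of
susceptibility distortion — with a 1 mm Hausdorff distance and Dice 0.96
between the true and distorted contours.

The full study (generate a cohort, train the field-map predictor, correct
held-out cases, tabulate geometric and dosimetric indices before/after
correction with Wilcoxon p-values) is one command; it runs in minutes on a
single CPU:

```sh
$ psd run --seed 0 --out-dir study0    # writes metrics.csv,
                                       # geometry_comparison.csv,
                                       # dose_comparison.csv, manifest.json
```

Python API mirrors the CLI: `make_head_phantom`, `make_distorted_pair`,
`fieldmap_from_phase_pair`, `displacement_from_fieldmap`, `unwarp`,
`train_predictor`, `predict_fieldmap`, `run_experiment`, ...

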