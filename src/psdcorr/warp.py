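"""Susceptibility distortion as a 1D warp along the readout axis.

Off-resonance Δf (Hz) displaces signal along the frequency-encoding axis by
``Δx = Δf / BW`` pixels, with BW the readout bandwidth per pixel.  Because
the distortion acts along a single axis, the deformation Jacobian reduces to
``det J = 1 + ∂(Δx)/∂x`` evaluated along that axis only, and stretched or
compressed voxels are intensity-compensated by that determinant so total
signal is conserved.

Frame convention: the displacement field d(x) lives in the *undistorted*
frame; a feature at true position x appears at x + d(x) in the distorted
image (for polarity +1, positive Δf shifts toward increasing index).  The
correction (``unwarp``) is the direct pull-back
``corrected(x) = distorted(x + d(x)) · det J(x)``, which is exact.  The
simulator (``forward_warp``) inverts the map x ↦ x + d(x) by fixed-point
iteration so that forward-then-unwarp round-trips to interpolation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fieldmap import FieldMap
from .volume import Mask3D, Volume3D


@dataclass
class SequenceParams:
    """Readout parameters that set the distortion scale."""

    bandwidth_hz_per_px: float
    freq_axis: int = 0
    polarity: int = 1

    def __post_init__(self) -> None:
        if self.bandwidth_hz_per_px <= 0:
            raise ValueError("bandwidth must be positive (Hz/pixel)")
        if self.freq_axis not in (0, 1, 2):
            raise ValueError("freq_axis must be 0, 1 or 2")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class DisplacementField:
    """Per-voxel shift along the frequency-encoding axis, in pixels."""

    shift_px: Volume3D

    def __post_init__(self) -> None:
        if self.shift_px.freq_axis is None:
            raise ValueError("displacement field requires a designated freq_axis")

    @property
    def axis(self) -> int:
        return self.shift_px.freq_axis

    @property
    def shift_mm(self) -> Volume3D:
        """Derived view: shift in mm (pixels x spacing along the readout axis)."""
        sp = self.shift_px.spacing[self.axis]
        return self.shift_px.with_data(self.shift_px.data * sp)


@dataclass
class JacobianMap:
    """det J = 1 + d(shift)/dx along the readout axis; unitless."""

    det_j: Volume3D


def displacement_from_fieldmap(fm: FieldMap, seq: SequenceParams,
                               mask: Mask3D | None = None) -> DisplacementField:
    """Δx[px] = polarity x Δf[Hz] / BW[Hz/px]; optionally zeroed outside a mask."""
    offres = np.asarray(fm.offres_hz.data, dtype=float)
    if mask is not None:
        inside = mask.data
        if not np.all(np.isfinite(offres[inside])):
            raise ValueError("field map contains non-finite values inside the mask")
        offres = np.where(inside, offres, 0.0)
    elif not np.all(np.isfinite(offres)):
        raise ValueError("field map contains non-finite values")
    shift = seq.polarity * offres / seq.bandwidth_hz_per_px
    vol = Volume3D(shift, fm.offres_hz.affine, freq_axis=seq.freq_axis)
    return DisplacementField(shift_px=vol)


def jacobian_determinant(disp: DisplacementField) -> JacobianMap:
    """1 + central-difference derivative of the pixel shift along the readout
    axis (one-sided at the boundaries); other axes contribute nothing."""
    d = np.asarray(disp.shift_px.data, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("displacement contains non-finite values")
    det = 1.0 + np.gradient(d, axis=disp.axis)
    return JacobianMap(det_j=disp.shift_px.with_data(det))


def _check_foldover(det_j: np.ndarray) -> None:
    if det_j.min() <= 0.0:
        idx = np.unravel_index(int(np.argmin(det_j)), det_j.shape)
        raise ValueError(
            f"displacement folds over (det J = {det_j.min():.4f} <= 0 at voxel {idx}); "
            "the field/bandwidth combination is non-physical"
        )


def _sample_along_axis(data: np.ndarray, pos: np.ndarray, axis: int,
                       order: int) -> np.ndarray:
    """Resample ``data`` at fractional positions ``pos`` along one axis.

    ``pos`` has the full grid shape and gives, per output voxel, the source
    coordinate along ``axis``; the other two coordinates stay on-grid, so
    this is line-wise 1D interpolation (cubic spline by default).  Samples
    outside the grid are zero-filled.
    """
    shape = data.shape
    idx = np.indices(shape, dtype=float)
    idx[axis] = pos
    return ndimage.map_coordinates(np.asarray(data, dtype=float), idx,
                                   order=order, mode="constant", cval=0.0)


def _invert_shift(d: np.ndarray, axis: int, n_iter: int = 10,
                  tol: float = 0.01) -> np.ndarray:
    """Solve x_t + d(x_t) = y per voxel by fixed-point iteration.

    Returns the true-frame coordinate x_t for each distorted-frame voxel y.
    Converges for |d'| < 1, i.e. whenever there is no fold-over.
    """
    grid = np.indices(d.shape, dtype=float)[axis]
    xt = grid - d
    for _ in range(n_iter):
        d_at = _sample_along_axis(d, xt, axis, order=1)
        xt_new = grid - d_at
        if np.max(np.abs(xt_new - xt)) < tol:
            xt = xt_new
            break
        xt = xt_new
    return xt


def forward_warp(img: Volume3D, disp: DisplacementField, order: int = 3) -> Volume3D:
    """Simulate distortion: resample the true image into the distorted frame
    with Jacobian intensity compensation, conserving per-line signal.

    The map x ↦ x + d(x) is inverted by fixed-point iteration (≤10 steps,
    0.01 px tolerance), then ``distorted(y) = true(x_t(y)) / det J(x_t(y))``.
    """
    d = np.asarray(disp.shift_px.data, dtype=float)
    axis = disp.axis
    if np.max(np.abs(d)) >= img.shape[axis]:
        raise ValueError("displacement exceeds image extent along the readout axis")
    det_j = jacobian_determinant(disp).det_j.data
    _check_foldover(det_j)
    if not np.any(d):
        return img.with_data(img.data.copy())
    xt = _invert_shift(d, axis)
    warped = _sample_along_axis(img.data, xt, axis, order=order)
    j_at = _sample_along_axis(det_j - 1.0, xt, axis, order=1) + 1.0
    return img.with_data(warped / j_at)


def unwarp(img_distorted: Volume3D, disp: DisplacementField, order: int = 3) -> Volume3D:
    """Correct distortion: ``corrected(x) = distorted(x + d(x)) · det J(x)``.

    This is the direct pull-back with Jacobian intensity compensation; it is
    the exact inverse of :func:`forward_warp` up to interpolation error.
    """
    d = np.asarray(disp.shift_px.data, dtype=float)
    axis = disp.axis
    det_j = jacobian_determinant(disp).det_j.data
    _check_foldover(det_j)
    if not np.any(d):
        return img_distorted.with_data(img_distorted.data.copy())
    grid = np.indices(d.shape, dtype=float)[axis]
    sampled = _sample_along_axis(img_distorted.data, grid + d, axis, order=order)
    return img_distorted.with_data(sampled * det_j)


def warp_mask(mask: Mask3D, disp: DisplacementField, direction: str = "forward") -> Mask3D:
    """Transport a binary mask with the same geometric transform (no Jacobian),
    linear interpolation, re-binarised at 0.5."""
    if direction not in ("forward", "inverse"):
        raise ValueError("direction must be 'forward' or 'inverse'")
    d = np.asarray(disp.shift_px.data, dtype=float)
    axis = disp.axis
    det_j = jacobian_determinant(disp).det_j.data
    _check_foldover(det_j)
    m = mask.data.astype(float)
    if not np.any(d):
        return Mask3D(mask.data.copy(), mask.affine)
    if direction == "forward":
        xt = _invert_shift(d, axis)
        warped = _sample_along_axis(m, xt, axis, order=1)
    elif direction == "inverse":
        grid = np.indices(d.shape, dtype=float)[axis]
        warped = _sample_along_axis(m, grid + d, axis, order=1)
    return Mask3D(warped >= 0.5, mask.affine)
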