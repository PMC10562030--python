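"""Synthetic susceptibility head phantoms and their induced B0 fields.

The phantom emulates the anatomy that makes vestibular-schwannoma imaging
distortion-sensitive: an ellipsoidal head (soft tissue, thin bone shell) in
air, tubular ear-canal air cavities entering laterally, a nasal air cavity,
and a small roughly spherical target abutting one canal tip.  Volume
susceptibility takes literature SI values (air +0.36 ppm, soft tissue
−9.05 ppm, cortical bone −11.4 ppm), so air–tissue interfaces carry the
~9 ppm contrast that drives the distortion.

The induced field deviation is computed by k-space dipole convolution,

    ΔB(k) = B0 · χ(k) · (1/3 − k_z² / |k|²),    ΔB(k=0) := 0,

with k_z along the main-field axis; the grid is zero-order-hold padded with
the air value before the FFT to suppress wrap-around from the periodic
boundary.  Anatomical contrast is piecewise intensity plus a smooth bias
field and Gaussian noise — no MR signal simulation.

Everything is deterministic under a seed: the same seed and configuration
reproduce the phantom bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy import ndimage
from scipy.fft import fftn, ifftn, fftfreq

from .fieldmap import FieldMap, GAMMA_OVER_2PI_HZ_PER_T
from .volume import Mask3D, Volume3D
from .warp import DisplacementField, SequenceParams, displacement_from_fieldmap, forward_warp, warp_mask


@dataclass
class PhantomConfig:
    """Geometry, susceptibility and contrast parameters of the head phantom.

    Lengths are mm; susceptibilities are SI volume susceptibility in ppm.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 1.0
    b0_tesla: float = 3.0
    b0_axis: int = 2
    chi_air_ppm: float = 0.36
    chi_tissue_ppm: float = -9.05
    chi_bone_ppm: float = -11.4
    head_semiaxes_frac: tuple[float, float, float] = (0.40, 0.42, 0.42)
    skull_thickness_frac: float = 0.10
    canal_radius_mm: float = 3.0
    canal_inner_frac: float = 0.19   # inner canal tip, fraction of FOV from center
    bulb_semiaxes_mm: tuple[float, float, float] = (6.0, 7.0, 7.0)
    nasal_semiaxes_mm: tuple[float, float, float] = (5.0, 7.0, 6.0)
    target_volume_cc: float = 2.7
    target_volume_jitter: float = 0.25
    target_center_jitter_mm: float = 2.0
    noise_sigma: float = 0.02
    bias_amplitude: float = 0.10
    pad_voxels: int = 32
    interface_smoothing_vox: float = 1.0

    def __post_init__(self) -> None:
        if min(self.shape) < 32:
            raise ValueError("phantom grid must be at least 32 voxels per axis")
        if not 0.5 <= self.spacing_mm <= 2.0:
            raise ValueError("voxel spacing must lie in 0.5-2 mm")


@dataclass
class SusceptibilityPhantom:
    """χ-map, anatomical image and structure masks on one lattice."""

    chi: Volume3D            # ppm
    anat: Volume3D           # arbitrary T1-like intensity
    head_mask: Mask3D
    target_mask: Mask3D
    air_masks: Dict[str, Mask3D]
    b0_tesla: float
    b0_axis: int
    seed: int
    config: PhantomConfig = field(repr=False, default=None)


@dataclass
class DistortedCase:
    """A ground-truth pair: distorted image + the field that produced it."""

    anat_distorted: Volume3D
    fieldmap_true: FieldMap
    disp_true: DisplacementField
    target_distorted: Mask3D


def _ellipsoid(shape, center, semiaxes):
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape)
    for g, c, a in zip(grids, center, semiaxes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def make_head_phantom(config: PhantomConfig | None = None, seed: int = 0) -> SusceptibilityPhantom:
    """Build a seeded head phantom on a regular grid.

    The target volume is drawn uniformly within ±`target_volume_jitter` of
    the configured value (default 2.7 cc) and its center jittered
    perpendicular to the canal axis; the sphere is placed abutting the left
    ear-canal tip.  Raises if the target cannot be realised inside the head
    on the given grid.
    """
    cfg = config or PhantomConfig()
    rng = np.random.default_rng(seed)
    shape = tuple(cfg.shape)
    sp = cfg.spacing_mm
    affine = np.diag([sp, sp, sp, 1.0])
    center = np.array([(n - 1) / 2.0 for n in shape])
    fov = np.array(shape) * sp

    semi_vox = np.array(cfg.head_semiaxes_frac) * np.array(shape)
    head = _ellipsoid(shape, center, semi_vox)
    inner = _ellipsoid(shape, center, semi_vox * (1.0 - cfg.skull_thickness_frac))
    skull = head & ~inner

    # tubular ear canals along axis 0, entering from both lateral surfaces,
    # each ending in an ellipsoidal air-cell "bulb" (vestibule/mastoid-like
    # pneumatization) that puts the adjacent tissue in the marked-distortion
    # zone typical of the vestibular-schwannoma location
    gx, gy, gz = np.indices(shape, dtype=float)
    r_vox = cfg.canal_radius_mm / sp
    inner_tip = cfg.canal_inner_frac * shape[0]
    radial = ((gy - center[1]) ** 2 + (gz - center[2]) ** 2) <= r_vox**2
    bulb_semi_vox = np.array(cfg.bulb_semiaxes_mm) / sp
    canal_l = (radial & (gx <= center[0] - inner_tip)) | _ellipsoid(
        shape, center - np.array([inner_tip, 0, 0]), bulb_semi_vox)
    canal_r = (radial & (gx >= center[0] + inner_tip)) | _ellipsoid(
        shape, center + np.array([inner_tip, 0, 0]), bulb_semi_vox)

    nasal_semi_vox = np.array(cfg.nasal_semiaxes_mm) / sp
    nasal_center = center + np.array([0.0, 0.32 * shape[1], -0.10 * shape[2]])
    nasal = _ellipsoid(shape, nasal_center, nasal_semi_vox)

    air = (canal_l | canal_r | nasal) | ~head

    # target: sphere of ~target_volume_cc wrapped around the left bulb tip;
    # the radius is re-scaled so the *realized* voxel volume (after carving
    # away air and staying inside the head) matches the drawn volume
    vol_cc = cfg.target_volume_cc * (1.0 + cfg.target_volume_jitter * (2 * rng.random() - 1))
    r_t_mm = (3.0 * vol_cc * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    jit = cfg.target_center_jitter_mm / sp
    jy = jit * (2 * rng.random() - 1)
    jz = jit * (2 * rng.random() - 1)
    voxel_cc = (sp**3) / 1000.0
    target = np.zeros(shape, dtype=bool)
    for _ in range(6):
        t_center = np.array([
            center[0] - inner_tip + bulb_semi_vox[0] + 0.5 * r_t_mm / sp,
            center[1] + jy,
            center[2] + jz,
        ])
        target = _ellipsoid(shape, t_center, np.full(3, r_t_mm / sp)) & inner & ~air
        realized = target.sum() * voxel_cc
        if realized <= 0:
            break
        if abs(realized - vol_cc) / vol_cc < 0.05:
            break
        r_t_mm *= (vol_cc / realized) ** (1.0 / 3.0)
    realized = target.sum() * voxel_cc
    if realized < 0.75 * vol_cc:
        raise ValueError(
            f"target of {vol_cc:.2f} cc not realizable inside the head on this grid"
        )

    chi = np.full(shape, cfg.chi_air_ppm)
    chi[head] = cfg.chi_tissue_ppm
    chi[skull] = cfg.chi_bone_ppm
    chi[air] = cfg.chi_air_ppm

    # synthetic T1-like contrast: piecewise intensities, smoothed edges,
    # smooth multiplicative bias, additive Gaussian noise
    anat = np.zeros(shape)
    anat[head & ~skull] = 1.0
    anat[skull] = 0.25
    anat[air] = 0.0
    anat[target] = 1.6
    anat = ndimage.gaussian_filter(anat, sigma=0.8)
    bias = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=12.0 / sp)
    peak = np.max(np.abs(bias))
    if peak > 0:
        bias = bias / peak
    anat = anat * (1.0 + cfg.bias_amplitude * bias)
    anat = anat + cfg.noise_sigma * rng.standard_normal(shape)
    anat = np.clip(anat, 0.0, None)

    mk = lambda m: Mask3D(m, affine)
    return SusceptibilityPhantom(
        chi=Volume3D(chi, affine),
        anat=Volume3D(anat.astype(np.float32), affine),
        head_mask=mk(head),
        target_mask=mk(target),
        air_masks={"ear_left": mk(canal_l & head), "ear_right": mk(canal_r & head),
                   "nasal": mk(nasal & head)},
        b0_tesla=cfg.b0_tesla,
        b0_axis=cfg.b0_axis,
        seed=seed,
        config=cfg,
    )


def dipole_field_ppm(chi_ppm: np.ndarray, b0_axis: int = 2, pad: int = 32,
                     pad_value: float | None = None) -> np.ndarray:
    """Field deviation (ppm of B0) induced by a susceptibility map, via FFT
    dipole convolution with the k=0 term zeroed (zero-mean convention)."""
    chi = np.asarray(chi_ppm, dtype=float)
    if pad_value is None:
        pad_value = float(chi.flat[0])
    padded = np.pad(chi, pad, mode="constant", constant_values=pad_value)
    ks = np.meshgrid(*[fftfreq(n) for n in padded.shape], indexing="ij", sparse=True)
    k2 = sum(k**2 for k in ks)
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = 1.0 / 3.0 - ks[b0_axis] ** 2 / k2
    kernel = np.where(k2 == 0, 0.0, kernel)
    fieldp = np.real(ifftn(kernel * fftn(padded)))
    sl = tuple(slice(pad, pad + n) for n in chi.shape)
    return fieldp[sl]


def field_from_susceptibility(phantom: SusceptibilityPhantom) -> FieldMap:
    """Off-resonance map (Hz) induced by the phantom's χ distribution at its
    field strength.  Severe grid anisotropy (>4:1) is tolerated with a warning."""
    chi = phantom.chi
    if not np.all(np.isfinite(chi.data)):
        raise ValueError("susceptibility map contains non-finite values")
    if phantom.b0_tesla <= 0:
        raise ValueError("B0 must be positive")
    spacing = chi.spacing
    if spacing.max() / spacing.min() > 4.0:
        import warnings

        warnings.warn("severely anisotropic grid (>4:1); dipole kernel assumes "
                      "isotropic normalized frequencies", stacklevel=2)
    pad = phantom.config.pad_voxels if phantom.config is not None else 32
    smooth = (phantom.config.interface_smoothing_vox
              if phantom.config is not None else 1.0)
    chi_data = chi.data
    if smooth > 0:
        # partial-volume smoothing: tissue interfaces are not voxel-sharp
        # steps; without it the discrete field gradient at an air-tissue
        # boundary is unphysically steep
        chi_data = ndimage.gaussian_filter(np.asarray(chi_data, dtype=float), smooth)
    ppm = dipole_field_ppm(chi_data, b0_axis=phantom.b0_axis, pad=pad)
    hz = ppm * 1e-6 * phantom.b0_tesla * GAMMA_OVER_2PI_HZ_PER_T
    return FieldMap(offres_hz=chi.with_data(hz), b0_tesla=phantom.b0_tesla)


def make_distorted_pair(phantom: SusceptibilityPhantom, seq: SequenceParams) -> DistortedCase:
    """Forward-simulate a distorted acquisition of the phantom.

    Composes the dipole field, the pixel-displacement map at the given
    bandwidth, and the Jacobian-compensated forward warp of the anatomical
    image, plus the plain geometric warp of the target mask.
    """
    fm = field_from_susceptibility(phantom)
    disp = displacement_from_fieldmap(fm, seq)
    try:
        anat_d = forward_warp(_with_axis(phantom.anat, seq.freq_axis), disp)
        target_d = warp_mask(phantom.target_mask, disp, direction="forward")
    except ValueError as exc:
        if "folds over" in str(exc):
            raise ValueError(
                f"{exc}; increase the readout bandwidth ({seq.bandwidth_hz_per_px} Hz/px)"
            ) from exc
        raise
    return DistortedCase(anat_distorted=anat_d, fieldmap_true=fm,
                         disp_true=disp, target_distorted=target_d)


def _with_axis(vol: Volume3D, freq_axis: int) -> Volume3D:
    return Volume3D(vol.data, vol.affine, freq_axis=freq_axis)
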