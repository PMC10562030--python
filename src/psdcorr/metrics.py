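"""Image- and contour-level evaluation metrics.

Field-map / image fidelity: NMSE (‖X̂−X‖²/‖X‖²) and SSIM.  The default SSIM
mode ("global") evaluates the similarity formula once over the whole volume
with stabilisers c1 = 0.01·L and c2 = 0.03·L, L the maximum voxel intensity
of the reference; the conventional windowed variant with squared constants
(c1 = (0.01L)², c2 = (0.03L)²) is available as mode="windowed".

Contour agreement: Sørensen–Dice, Hausdorff distance (max and 95th
percentile, both always reported, surface-voxel based, physical mm),
per-axis centroid shift in mm, and structure volume in cc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy import ndimage

from .volume import Mask3D, Volume3D


@dataclass
class SsimParams:
    """Stabiliser configuration for SSIM; L is the reference maximum."""

    c1_factor: float = 0.01
    c2_factor: float = 0.03
    mode: str = "global"       # "global" (single-window, unsquared constants)
    window: int = 7            # edge length for the windowed variant


@dataclass
class MetricReport:
    """Named scalar metrics for one case; units recorded per metric."""

    case_id: str
    condition: str                      # e.g. "uncorrected" / "corrected"
    values: Dict[str, float] = field(default_factory=dict)
    units: Dict[str, str] = field(default_factory=dict)

    def add(self, name: str, value: float, unit: str) -> None:
        self.values[name] = float(value)
        self.units[name] = unit


def nmse(pred: Volume3D, ref: Volume3D, mask: Mask3D | None = None) -> float:
    """Normalized mean square error ‖X̂−X‖² / ‖X‖² over the mask (fraction;
    multiply by 100 to report %).  Scale-covariant by construction: no hidden
    normalization beyond the reference norm."""
    p = np.asarray(pred.data, dtype=float)
    r = np.asarray(ref.data, dtype=float)
    if mask is not None:
        p, r = p[mask.data], r[mask.data]
    denom = np.sum(r**2)
    if denom == 0:
        raise ValueError("reference has zero norm inside the mask; NMSE undefined")
    return float(np.sum((p - r) ** 2) / denom)


def ssim(pred: Volume3D, ref: Volume3D, params: SsimParams | None = None) -> float:
    """Structural similarity between a predicted and a reference volume.

    Global mode evaluates (2μμ̂+c1)(2σ_xx̂+c2)/((μ²+μ̂²+c1)(σ²+σ̂²+c2)) over
    the full volume.  Both modes share L = max(ref); symmetric given shared L.
    """
    params = params or SsimParams()
    r = np.asarray(ref.data, dtype=float)
    p = np.asarray(pred.data, dtype=float)
    L = float(r.max())
    if L <= 0:
        raise ValueError("reference maximum intensity must be positive for SSIM")
    if params.mode == "global":
        c1 = params.c1_factor * L
        c2 = params.c2_factor * L
        mu_r, mu_p = r.mean(), p.mean()
        var_r, var_p = r.var(), p.var()
        cov = ((r - mu_r) * (p - mu_p)).mean()
        return float(
            (2 * mu_r * mu_p + c1) * (2 * cov + c2)
            / ((mu_r**2 + mu_p**2 + c1) * (var_r + var_p + c2))
        )
    if params.mode == "windowed":
        from skimage.metrics import structural_similarity

        return float(structural_similarity(
            r, p, win_size=params.window, data_range=L,
            K1=params.c1_factor, K2=params.c2_factor,
        ))
    raise ValueError(f"unknown SSIM mode {params.mode!r}")


def dice(a: Mask3D, b: Mask3D) -> float:
    """Sørensen–Dice overlap 2|A∩B|/(|A|+|B|); undefined for two empty masks."""
    if a.shape != b.shape:
        raise ValueError("masks are not on the same lattice")
    na, nb = a.count(), b.count()
    if na + nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask)


def _directed_distances(src: np.ndarray, dst: np.ndarray, spacing) -> np.ndarray:
    """Distances (mm) from each surface voxel of src to the nearest surface
    voxel of dst, via a sampled Euclidean distance transform."""
    dt = ndimage.distance_transform_edt(~_surface(dst), sampling=spacing)
    return dt[_surface(src)]


def hausdorff(a: Mask3D, b: Mask3D, spacing=None) -> tuple[float, float]:
    """Symmetric surface Hausdorff distance in mm: ``(max_hd, hd95)``.

    Surfaces are mask voxels minus their erosion; hd95 is the larger of the
    two directed 95th percentiles.  Both variants are always returned since
    reporting conventions differ.
    """
    if a.count() == 0 or b.count() == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    if spacing is None:
        spacing = a.spacing
    d_ab = _directed_distances(a.data, b.data, spacing)
    d_ba = _directed_distances(b.data, a.data, spacing)
    hd = max(d_ab.max(), d_ba.max())
    hd95 = max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))
    return float(hd), float(hd95)


def centroid_shift(a: Mask3D, b: Mask3D) -> np.ndarray:
    """Difference of (unweighted) mask centroids, b − a, in physical mm per axis."""
    if a.count() == 0 or b.count() == 0:
        raise ValueError("centroid undefined for an empty mask")
    ca = np.array(ndimage.center_of_mass(a.data))
    cb = np.array(ndimage.center_of_mass(b.data))
    lin = a.affine[:3, :3]
    return lin @ (cb - ca)


def volume_cc(a: Mask3D, spacing=None) -> float:
    """Structure volume: voxel count x voxel volume, in cc."""
    if spacing is not None:
        vox_mm3 = float(np.prod(spacing))
    else:
        vox_mm3 = a.voxel_volume_mm3
    return a.count() * vox_mm3 / 1000.0
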