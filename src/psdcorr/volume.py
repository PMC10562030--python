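"""3D volume and mask containers backed by NIfTI-1 files.

All per-voxel quantities in the package (anatomical images, off-resonance
field maps, displacement fields, dose grids, binary structure masks) travel
as :class:`Volume3D` / :class:`Mask3D`: a data grid plus an affine mapping
0-based voxel indices to physical millimetres, and optionally the index of
the frequency-encoding (readout) axis along which susceptibility-induced
distortion acts.

Geometry conventions
--------------------
* Voxel coordinates are 0-based indices; physical coordinates are mm,
  obtained through the affine.  Every distance metric downstream is in mm.
* The frequency-encoding axis is always supplied explicitly (config/CLI);
  NIfTI headers do not reliably record the readout direction.
* Masks are voxelised contours on the same lattice as their paired volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel->mm affine and optional readout axis.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values.
    affine : ndarray, shape (4, 4)
        Invertible mapping from 0-based voxel indices to physical mm.
    freq_axis : int or None
        Index (0, 1 or 2) of the frequency-encoding axis, if designated.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    freq_axis: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume3D requires 3 spatial dimensions, got {self.data.ndim}D data"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible (singular 3x3 block)")
        if self.freq_axis is not None and self.freq_axis not in (0, 1, 2):
            raise ValueError(f"freq_axis must be 0, 1 or 2, got {self.freq_axis}")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive on all axes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_lattice(self, other: "Volume3D | Mask3D", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def require_same_lattice(self, other: "Volume3D | Mask3D", what: str = "volumes") -> None:
        if not self.same_lattice(other):
            raise ValueError(f"{what} are not on the same lattice (shape/affine mismatch)")

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on this lattice carrying different voxel values."""
        return replace(self, data=np.asarray(data))

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class Mask3D:
    """Binary voxel mask on the lattice of an associated :class:`Volume3D`."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = arr.astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"Mask3D requires 3D data, got {self.data.ndim}D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def count(self) -> int:
        return int(self.data.sum())

    def same_lattice(self, other: "Volume3D | Mask3D", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def read_volume(path, freq_axis: int | None = None) -> Volume3D:
    """Read a 3D NIfTI-1 volume, recording the readout axis.

    Raises on non-3D images, unreadable files, or singular affines; spacing
    and affine are taken from the header.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - message path
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D volume, file has {data.ndim} dimensions"
        )
    return Volume3D(data=data, affine=np.asarray(img.affine), freq_axis=freq_axis)


def write_volume(vol: Volume3D | Mask3D, path, dtype=None) -> None:
    """Write a volume or mask as NIfTI-1.

    Float data defaults to float32 (lossless for float32 inputs); masks are
    written as uint8.
    """
    if isinstance(vol, Mask3D):
        data = vol.data.astype(np.uint8)
    else:
        data = vol.data
        if dtype is None:
            dtype = np.float32 if np.issubdtype(data.dtype, np.floating) else data.dtype
        data = data.astype(dtype)
    img = nib.Nifti1Image(data, vol.affine)
    nib.save(img, str(path))


def read_mask(path) -> Mask3D:
    vol = read_volume(path)
    return Mask3D(data=vol.data > 0.5, affine=vol.affine)


def threshold_mask(magnitude: Volume3D, fraction: float = 0.2) -> Mask3D:
    """Head mask from a magnitude image: threshold, keep the largest
    connected component, fill holes.

    The threshold is ``fraction`` times a robust maximum (99th percentile),
    so isolated hot voxels do not set the scale.  This is a deliberately
    simple stand-in for a full skull-stripping step, sufficient for the
    synthetic phantoms and for restricting metrics to the head.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    data = np.asarray(magnitude.data, dtype=float)
    robust_max = np.percentile(data, 99.0)
    # tolerate slight negative ringing from cubic resampling, nothing more
    if np.any(data < -0.02 * max(robust_max, 0)) or robust_max <= 0:
        raise ValueError("magnitude image must be non-negative")
    data = np.clip(data, 0.0, None)
    binary = data >= fraction * robust_max
    if not binary.any():
        raise ValueError("thresholding produced an empty mask")
    labels, nlab = ndimage.label(binary)
    if nlab > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, nlab + 1))
        binary = labels == (1 + int(np.argmax(sizes)))
    binary = ndimage.binary_fill_holes(binary)
    return Mask3D(data=binary, affine=magnitude.affine)
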