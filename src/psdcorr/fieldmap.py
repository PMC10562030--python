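"""B0 field mapping from dual-echo gradient-echo phase images.

The off-resonance field is estimated from the phase evolution between two
echoes: ``ΔB = Δφ / (γ ΔTE)`` with the phase difference Δφ in radians, γ the
proton gyromagnetic ratio in rad/s/T and ΔTE in seconds.  Field maps are
stored as off-resonance *frequency* in Hz (Δf = γΔB/2π), because sequence
bandwidth is quoted in Hz/pixel and the displacement computation consumes
Hz directly; Tesla values are derived views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_phase

from .volume import Mask3D, Volume3D

#: Proton gyromagnetic ratio over 2π, Hz/T (CODATA).
GAMMA_OVER_2PI_HZ_PER_T = 42_577_478.518


@dataclass
class PhasePair:
    """Phase volumes (radians) acquired at two echo times (ms), TE2 > TE1."""

    phase_te1: Volume3D
    phase_te2: Volume3D
    te1_ms: float
    te2_ms: float

    def __post_init__(self) -> None:
        if not (self.te2_ms > self.te1_ms > 0):
            raise ValueError(
                f"echo times must satisfy TE2 > TE1 > 0, got TE1={self.te1_ms}, TE2={self.te2_ms}"
            )
        self.phase_te1.require_same_lattice(self.phase_te2, "phase volumes")


@dataclass
class FieldMap:
    """Per-voxel off-resonance in Hz, with the field strength as metadata."""

    offres_hz: Volume3D
    b0_tesla: float = 3.0
    gamma_over_2pi: float = GAMMA_OVER_2PI_HZ_PER_T

    @property
    def delta_b_tesla(self) -> Volume3D:
        """Off-resonance expressed as a field deviation ΔB in Tesla."""
        return self.offres_hz.with_data(self.offres_hz.data / self.gamma_over_2pi)

    @classmethod
    def from_delta_b(cls, delta_b: Volume3D, b0_tesla: float = 3.0,
                     gamma_over_2pi: float = GAMMA_OVER_2PI_HZ_PER_T) -> "FieldMap":
        return cls(offres_hz=delta_b.with_data(delta_b.data * gamma_over_2pi),
                   b0_tesla=b0_tesla, gamma_over_2pi=gamma_over_2pi)


def wrap_to_pi(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi), 2.0 * np.pi)


def phase_difference(pair: PhasePair) -> Volume3D:
    """Elementwise phase difference φ(TE2) − φ(TE1), re-wrapped to (−π, π].

    Computed through the complex ratio exp(iφ2)·exp(−iφ1) so the result is
    insensitive to how many 2π turns either input carries.
    """
    p1 = np.asarray(pair.phase_te1.data, dtype=float)
    p2 = np.asarray(pair.phase_te2.data, dtype=float)
    dphi = np.angle(np.exp(1j * (p2 - p1)))
    # np.angle returns (-pi, pi]; -pi can appear from rounding, fold it back
    dphi = np.where(dphi <= -np.pi, np.pi, dphi)
    return pair.phase_te1.with_data(dphi)


def unwrap_delta_phi(dphi: Volume3D, mask: Mask3D) -> Volume3D:
    """Spatially unwrap a wrapped phase-difference volume inside a mask.

    Uses reliability-sorted region-growing unwrapping restricted to the
    mask.  The output is defined up to one global 2π multiple; voxels
    outside the mask are set to zero.
    """
    if mask.count() == 0:
        raise ValueError("unwrapping mask is empty")
    dphi.require_same_lattice(Volume3D(np.zeros(mask.shape), mask.affine), "phase and mask")
    marr = np.ma.MaskedArray(np.asarray(dphi.data, dtype=float), mask=~mask.data)
    unwrapped = _unwrap_phase(marr)
    out = np.where(mask.data, np.ma.filled(unwrapped, 0.0), 0.0)
    return dphi.with_data(out)


def fieldmap_from_phase(dphi_unwrapped: Volume3D, te1_ms: float, te2_ms: float,
                        b0_tesla: float = 3.0) -> FieldMap:
    """Convert an unwrapped phase difference to an off-resonance map.

    Δf [Hz] = Δφ / (2π · ΔTE[s]); equivalently ΔB = Δφ/(γΔTE) in Tesla.
    """
    if not te2_ms > te1_ms:
        raise ValueError(f"TE2 must exceed TE1, got TE1={te1_ms} ms, TE2={te2_ms} ms")
    dte_s = (te2_ms - te1_ms) * 1e-3
    hz = np.asarray(dphi_unwrapped.data, dtype=float) / (2.0 * np.pi * dte_s)
    return FieldMap(offres_hz=dphi_unwrapped.with_data(hz), b0_tesla=b0_tesla)


def fieldmap_from_phase_pair(pair: PhasePair, mask: Mask3D, *, unwrap: bool = True,
                             b0_tesla: float = 3.0) -> FieldMap:
    """Full dual-echo pipeline: difference, (optional) unwrap, scale to Hz.

    ``unwrap=False`` passes the wrapped difference straight through, for
    inputs that were unwrapped upstream.
    """
    dphi = phase_difference(pair)
    if unwrap:
        dphi = unwrap_delta_phi(dphi, mask)
    return fieldmap_from_phase(dphi, pair.te1_ms, pair.te2_ms, b0_tesla=b0_tesla)
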