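"""Gamma-Knife-like dose simulation and plan quality indices.

The dose model is a sum of isotropic 3D Gaussian "shots" (a deliberate
simplification of Gamma Knife isocenters), globally rescaled so that the
prescription isodose equals the prescription dose — by default 12 Gy at the
50% isodose line, i.e. a 24 Gy maximum.  On that dose grid the standard
stereotactic indices are computed against a target mask:

* DVH point doses Dμ, Dmax, Dmin and D95% (dose received by ≥95% of the
  target, from the empirical voxel-counting DVH),
* target coverage TC = TV_PIV / TV,
* Paddick conformity index PCI = TV_PIV² / (TV · PIV),
* gradient index GI = V(rx/2) / V(rx),
* homogeneity index, by default Dmax(target)/rx (=2 under a 50% isodose
  prescription); an ICRU-style (D2−D98)/D50 variant is available,

where TV is the target volume, PIV the prescription isodose volume and
TV_PIV their intersection.  Paired before/after-correction comparisons use
the two-sided Wilcoxon signed-rank test (exact for n ≤ 25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volume import Mask3D, Volume3D


@dataclass
class Shot:
    """One Gaussian shot: center (physical mm), width sigma (mm), weight."""

    center_mm: tuple[float, float, float]
    sigma_mm: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("shot sigma must be positive")
        if self.weight <= 0:
            raise ValueError("shot weight must be positive")


#: Nominal collimator-size (mm) to Gaussian sigma (mm) presets.
COLLIMATOR_SIGMA_MM = {4: 2.0, 8: 4.0, 16: 8.0}


@dataclass
class PlanSpec:
    """A stand-in radiosurgery plan: shots plus the prescription rule."""

    shots: Sequence[Shot]
    rx_dose_gy: float = 12.0
    rx_isodose_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.shots:
            raise ValueError("plan must contain at least one shot")
        if not 0.0 < self.rx_isodose_fraction < 1.0:
            raise ValueError("rx_isodose_fraction must lie in (0, 1)")


@dataclass
class DoseGrid:
    """Dose in Gy on a Volume3D lattice."""

    dose: Volume3D
    rx_dose_gy: float = 12.0
    rx_isodose_fraction: float = 0.5


def simulate_gk_dose(plan: PlanSpec, grid: Volume3D) -> DoseGrid:
    """Sum of weighted Gaussians, normalized so max dose = rx / isodose
    fraction (scale-invariant in the weights).  Shot centers must lie inside
    the grid."""
    shape = grid.shape
    inv = np.linalg.inv(grid.affine)
    idx = np.indices(shape, dtype=float)
    phys = np.stack([
        sum(grid.affine[i, j] * idx[j] for j in range(3)) + grid.affine[i, 3]
        for i in range(3)
    ])
    dose = np.zeros(shape)
    for shot in plan.shots:
        c = np.asarray(shot.center_mm, dtype=float)
        vox = inv[:3, :3] @ c + inv[:3, 3]
        if np.any(vox < -0.5) or np.any(vox > np.array(shape) - 0.5):
            raise ValueError(f"shot center {tuple(c)} mm lies outside the dose grid")
        r2 = sum((phys[i] - c[i]) ** 2 for i in range(3))
        dose += shot.weight * np.exp(-r2 / (2.0 * shot.sigma_mm**2))
    peak = dose.max()
    dose *= (plan.rx_dose_gy / plan.rx_isodose_fraction) / peak
    return DoseGrid(dose=grid.with_data(dose), rx_dose_gy=plan.rx_dose_gy,
                    rx_isodose_fraction=plan.rx_isodose_fraction)


def dvh_metrics(dose: DoseGrid, target: Mask3D) -> dict[str, float]:
    """Dμ, Dmax, Dmin and D95% (Gy) of the target from the voxel-level DVH.

    D95% is the largest dose d such that ≥95% of target voxels receive ≥ d
    (empirical order statistic, no interpolation)."""
    if target.count() == 0:
        raise ValueError("target mask is empty")
    d = np.asarray(dose.dose.data, dtype=float)[target.data]
    d_sorted = np.sort(d)[::-1]
    n = d_sorted.size
    k = int(np.ceil(0.95 * n))
    return {
        "Dmean_gy": float(d.mean()),
        "Dmax_gy": float(d.max()),
        "Dmin_gy": float(d.min()),
        "D95_gy": float(d_sorted[k - 1]),
    }


def _piv(dose: DoseGrid, rx: float) -> np.ndarray:
    return np.asarray(dose.dose.data, dtype=float) >= rx


def coverage_tc(dose: DoseGrid, target: Mask3D, rx: float | None = None) -> float:
    """Target coverage TV_PIV / TV: fraction of target receiving >= rx."""
    if target.count() == 0:
        raise ValueError("target mask is empty")
    rx = dose.rx_dose_gy if rx is None else rx
    piv = _piv(dose, rx)
    return float(np.logical_and(piv, target.data).sum() / target.count())


def paddick_ci(dose: DoseGrid, target: Mask3D, rx: float | None = None) -> float:
    """Paddick conformity index TV_PIV² / (TV · PIV), in [0, 1]."""
    if target.count() == 0:
        raise ValueError("target mask is empty")
    rx = dose.rx_dose_gy if rx is None else rx
    piv = _piv(dose, rx)
    n_piv = int(piv.sum())
    if n_piv == 0:
        raise ValueError("prescription isodose volume is empty")
    tv_piv = int(np.logical_and(piv, target.data).sum())
    return float(tv_piv**2 / (target.count() * n_piv))


def gradient_index(dose: DoseGrid, rx: float | None = None) -> float:
    """Paddick gradient index V(rx/2)/V(rx); ≥1 whenever the dose peaks above rx."""
    rx = dose.rx_dose_gy if rx is None else rx
    v_rx = int(_piv(dose, rx).sum())
    if v_rx == 0:
        raise ValueError("prescription isodose volume is empty; GI undefined")
    v_half = int(_piv(dose, rx / 2.0).sum())
    return float(v_half / v_rx)


def homogeneity_index(dose: DoseGrid, target: Mask3D, rx: float | None = None,
                      mode: str = "dmax") -> float:
    """Target dose homogeneity.

    ``mode="dmax"`` (default): Dmax(target)/rx — equals 2 under a 50%-isodose
    prescription covering the hot spot.  ``mode="icru"``: (D2% − D98%)/D50%.
    """
    if target.count() == 0:
        raise ValueError("target mask is empty")
    rx = dose.rx_dose_gy if rx is None else rx
    d = np.asarray(dose.dose.data, dtype=float)[target.data]
    if mode == "dmax":
        return float(d.max() / rx)
    if mode == "icru":
        d2, d50, d98 = np.percentile(d, [98, 50, 2])
        return float((d2 - d98) / d50)
    raise ValueError(f"unknown homogeneity mode {mode!r}")


def evaluate_plan(dose: DoseGrid, target: Mask3D, case_id: str = "",
                  condition: str = "") -> dict[str, float]:
    """All dosimetric indices of one dose grid against one target mask."""
    out = dvh_metrics(dose, target)
    out["TC"] = coverage_tc(dose, target)
    out["PCI"] = paddick_ci(dose, target)
    out["GI"] = gradient_index(dose)
    out["HI"] = homogeneity_index(dose, target)
    return out


def compare_plans(before: pd.DataFrame, after: pd.DataFrame,
                  strict: bool = True) -> pd.DataFrame:
    """Paired before/after comparison across cases.

    Inputs are case-indexed DataFrames with one column per metric (identical
    case ids and columns).  Returns per-metric means ± SD and the two-sided
    Wilcoxon signed-rank p-value (exact for n ≤ 25, normal approximation
    above; zero differences dropped).  A metric with fewer than 5
    informative (non-tied) pairs raises when ``strict``, otherwise gets a
    NaN p-value.
    """
    if sorted(before.index) != sorted(after.index):
        raise ValueError("before/after tables must cover the same case ids")
    after = after.loc[before.index]
    rows = []
    for col in before.columns:
        x = before[col].to_numpy(dtype=float)
        y = after[col].to_numpy(dtype=float)
        diff = y - x
        informative = diff != 0
        n_inf = int(informative.sum())
        if n_inf < 5:
            if strict:
                raise ValueError(
                    f"metric {col!r}: fewer than 5 informative (non-tied) pairs (n={n_inf})"
                )
            rows.append({
                "metric": col,
                "mean_before": x.mean(), "sd_before": x.std(ddof=1),
                "mean_after": y.mean(), "sd_after": y.std(ddof=1),
                "n_pairs": n_inf,
                "wilcoxon_p": float("nan"),
                "significant_p05": False,
            })
            continue
        method = "exact" if n_inf <= 25 else "approx"
        res = stats.wilcoxon(x[informative], y[informative],
                             alternative="two-sided", method=method)
        rows.append({
            "metric": col,
            "mean_before": x.mean(), "sd_before": x.std(ddof=1),
            "mean_after": y.mean(), "sd_after": y.std(ddof=1),
            "n_pairs": n_inf,
            "wilcoxon_p": float(res.pvalue),
            "significant_p05": bool(res.pvalue < 0.05),
        })
    return pd.DataFrame(rows).set_index("metric")


def plan_for_target(target: Mask3D, rx_dose_gy: float = 12.0,
                    rx_isodose_fraction: float = 0.5,
                    n_shots: int = 1) -> PlanSpec:
    """Fit a simple plan to a target: shots at the centroid (and, for
    n_shots > 1, offset along the longest principal axis), with sigma chosen
    so the 50% isodose sphere of a single shot matches the target's
    equivalent-sphere radius."""
    if target.count() == 0:
        raise ValueError("target mask is empty")
    vol_mm3 = target.count() * target.voxel_volume_mm3
    r_eq = (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    sigma = r_eq / np.sqrt(2.0 * np.log(1.0 / rx_isodose_fraction))
    com_vox = np.array(ndimage.center_of_mass(target.data))
    lin, trans = target.affine[:3, :3], target.affine[:3, 3]
    center = lin @ com_vox + trans
    shots = [Shot(center_mm=tuple(center), sigma_mm=float(sigma))]
    if n_shots > 1:
        pts = np.argwhere(target.data) @ lin.T + trans
        cov = np.cov((pts - center).T)
        w, v = np.linalg.eigh(cov)
        axis = v[:, -1]
        for k in range(1, n_shots):
            off = center + ((-1) ** k) * 0.6 * sigma * ((k + 1) // 2) * axis
            shots.append(Shot(center_mm=tuple(off), sigma_mm=float(sigma), weight=0.6))
    return PlanSpec(shots=shots, rx_dose_gy=rx_dose_gy,
                    rx_isodose_fraction=rx_isodose_fraction)
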