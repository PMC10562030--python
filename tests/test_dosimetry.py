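import itertools

import numpy as np
import pandas as pd
import pytest

from psdcorr.dosimetry import (DoseGrid, PlanSpec, Shot, compare_plans,
                               coverage_tc, dvh_metrics, gradient_index,
                               homogeneity_index, paddick_ci, plan_for_target,
                               simulate_gk_dose)
from psdcorr.volume import Mask3D, Volume3D

from conftest import make_sphere_mask


def grid(n=64, spacing=1.0):
    return Volume3D(np.zeros((n, n, n)), np.diag([spacing, spacing, spacing, 1.0]))


def single_shot_dose(n=64, spacing=1.0, sigma=5.0):
    c = (n - 1) / 2 * spacing
    plan = PlanSpec([Shot((c, c, c), sigma)])
    return simulate_gk_dose(plan, grid(n, spacing))


class TestSimulateDose:
    def test_prescription_normalization(self):
        dose = single_shot_dose()
        assert dose.dose.data.max() == pytest.approx(24.0)

    def test_isodose_radius_closed_form(self):
        # 12 Gy surface of a single default shot is a sphere of radius
        # sigma*sqrt(2 ln 2)
        sigma, spacing = 5.0, 0.5
        dose = single_shot_dose(n=128, spacing=spacing, sigma=sigma)
        piv = dose.dose.data >= 12.0
        vol = piv.sum() * spacing**3
        r = sigma * np.sqrt(2 * np.log(2))
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.02)

    def test_weight_scale_invariance(self):
        c = 31.5
        p1 = PlanSpec([Shot((c, c, c), 4.0, 1.0), Shot((c + 6, c, c), 4.0, 0.5)])
        p2 = PlanSpec([Shot((c, c, c), 4.0, 2.0), Shot((c + 6, c, c), 4.0, 1.0)])
        d1 = simulate_gk_dose(p1, grid()).dose.data
        d2 = simulate_gk_dose(p2, grid()).dose.data
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_two_separated_shots_symmetric_lobes(self):
        c = 31.5
        plan = PlanSpec([Shot((c - 12, c, c), 3.0), Shot((c + 12, c, c), 3.0)])
        d = simulate_gk_dose(plan, grid()).dose.data
        np.testing.assert_allclose(d, d[::-1], atol=1e-9)

    def test_shot_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            simulate_gk_dose(PlanSpec([Shot((200.0, 0, 0), 4.0)]), grid())


class TestDvh:
    def test_uniform_dose(self):
        target = make_sphere_mask(radius=5)
        dose = DoseGrid(Volume3D(np.full((32, 32, 32), 12.0), np.eye(4)))
        m = dvh_metrics(dose, target)
        assert all(v == pytest.approx(12.0) for v in m.values())

    def test_two_voxel_order_statistics(self):
        data = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[0, 0, 1] = True
        data[0, 0, 0], data[0, 0, 1] = 10.0, 20.0
        m = dvh_metrics(DoseGrid(Volume3D(data, np.eye(4))), Mask3D(mask, np.eye(4)))
        assert m == {"Dmean_gy": 15.0, "Dmax_gy": 20.0, "Dmin_gy": 10.0, "D95_gy": 10.0}

    def test_ordering_invariant_on_random_cases(self, rng):
        for _ in range(100):
            data = rng.gamma(2.0, 4.0, (12, 12, 12))
            mask = rng.random((12, 12, 12)) > 0.6
            if not mask.any():
                continue
            m = dvh_metrics(DoseGrid(Volume3D(data, np.eye(4))), Mask3D(mask, np.eye(4)))
            assert m["Dmin_gy"] <= m["D95_gy"] <= m["Dmean_gy"] <= m["Dmax_gy"]

    def test_gaussian_dose_matches_oversampled_oracle(self):
        # 10x oversampled DVH on an analytically known Gaussian dose
        sigma = 6.0
        dose = single_shot_dose(n=64, spacing=1.0, sigma=sigma)
        target = make_sphere_mask((64, 64, 64), radius=8)
        m = dvh_metrics(dose, target)
        rngo = np.random.default_rng(5)
        pts = rngo.uniform(-0.5, 0.5, (200_000, 3)) * 16 + 31.5
        pts = pts[np.linalg.norm(pts - 31.5, axis=1) <= 8]
        r2 = np.sum((pts - 31.5) ** 2, axis=1)
        doses = 24.0 * np.exp(-r2 / (2 * sigma**2))
        assert m["Dmean_gy"] == pytest.approx(doses.mean(), rel=0.01)
        d95 = np.quantile(doses, 0.05)
        assert m["D95_gy"] == pytest.approx(d95, rel=0.01)


class TestIndices:
    def test_coverage_extremes_and_half(self):
        data = np.zeros((8, 8, 8))
        data[:4] = 20.0
        dose = DoseGrid(Volume3D(data, np.eye(4)))
        inside = Mask3D(np.concatenate([np.ones((4, 8, 8)), np.zeros((4, 8, 8))]).astype(bool), np.eye(4))
        outside = Mask3D(~inside.data, np.eye(4))
        half = np.zeros((8, 8, 8), dtype=bool)
        half[2:6] = True
        assert coverage_tc(dose, inside, 12.0) == 1.0
        assert coverage_tc(dose, outside, 12.0) == 0.0
        assert coverage_tc(dose, Mask3D(half, np.eye(4)), 12.0) == 0.5

    def test_paddick_arithmetic(self):
        # TV=100, PIV=150, TV_PIV=90 -> 0.54
        data = np.zeros((10, 10, 10))
        data.flat[:150] = 20.0
        target = np.zeros((10, 10, 10), dtype=bool)
        target.flat[60:160] = True  # 100 voxels, 90 inside PIV
        pci = paddick_ci(DoseGrid(Volume3D(data, np.eye(4))),
                         Mask3D(target, np.eye(4)), 12.0)
        assert pci == pytest.approx(90**2 / (100 * 150))

    def test_paddick_identity_and_extremes(self):
        dose = single_shot_dose(sigma=6.0)
        piv_mask = Mask3D(dose.dose.data >= 12.0, np.eye(4))
        assert paddick_ci(dose, piv_mask) == pytest.approx(1.0)
        far = np.zeros((64, 64, 64), dtype=bool)
        far[0:3, 0:3, 0:3] = True
        assert paddick_ci(dose, Mask3D(far, np.eye(4))) == 0.0

    def test_pci_equals_tc_times_precision(self, rng):
        # identity PCI = TC * (TV_PIV / PIV) on random plans
        for seed in range(5):
            r = np.random.default_rng(seed)
            c = 31.5
            shots = [Shot(tuple(c + r.uniform(-6, 6, 3)), r.uniform(3, 6), r.uniform(0.5, 1))
                     for _ in range(r.integers(1, 4))]
            dose = simulate_gk_dose(PlanSpec(shots), grid())
            target = make_sphere_mask((64, 64, 64),
                                      center=tuple(31.5 + r.uniform(-3, 3, 3)),
                                      radius=r.uniform(5, 9))
            piv = dose.dose.data >= 12.0
            tv_piv = np.logical_and(piv, target.data).sum()
            lhs = paddick_ci(dose, target)
            rhs = coverage_tc(dose, target) * (tv_piv / piv.sum())
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_gradient_index_gaussian_closed_form(self):
        # GI of a Gaussian shot at 50% prescription is 2*sqrt(2), any sigma
        for sigma in (3.0, 5.0, 8.0):
            dose = single_shot_dose(n=128, spacing=0.5, sigma=sigma)
            assert gradient_index(dose) == pytest.approx(2 * np.sqrt(2), rel=0.02)

    def test_gradient_index_linear_falloff(self):
        # D = Dmax(1 - r/R), rx = Dmax/2 -> GI = (0.75/0.5)^3 = 3.375
        n, R = 96, 40.0
        g = np.indices((n, n, n), dtype=float)
        r = np.sqrt(sum((gi - (n - 1) / 2) ** 2 for gi in g))
        data = np.clip(24.0 * (1 - r / R), 0, None)
        dose = DoseGrid(Volume3D(data, np.eye(4)))
        assert gradient_index(dose) == pytest.approx(3.375, rel=0.02)

    def test_gradient_index_voxel_ratio(self):
        data = np.zeros((10, 10, 10))
        data.flat[:100] = 13.0
        data.flat[100:220] = 7.0
        assert gradient_index(DoseGrid(Volume3D(data, np.eye(4))), 12.0) == pytest.approx(2.2)

    def test_homogeneity_default_and_icru(self):
        dose = single_shot_dose(sigma=6.0)
        target = Mask3D(dose.dose.data >= 12.0, np.eye(4))
        assert homogeneity_index(dose, target) == pytest.approx(2.0)
        uniform = DoseGrid(Volume3D(np.full((8, 8, 8), 12.0), np.eye(4)))
        t = make_sphere_mask((8, 8, 8), radius=3)
        assert homogeneity_index(uniform, t) == pytest.approx(1.0)
        assert homogeneity_index(uniform, t, mode="icru") == pytest.approx(0.0)


class TestComparePlans:
    @staticmethod
    def exact_sign_flip_p(diffs):
        """Exhaustive enumeration oracle for the two-sided exact Wilcoxon
        signed-rank p-value (no ties in |diffs|)."""
        diffs = np.asarray(diffs, dtype=float)
        ranks = np.argsort(np.argsort(np.abs(diffs))) + 1.0
        w_obs = ranks[diffs > 0].sum()
        n = len(diffs)
        stats_all = [np.sum(ranks[list(signs)]) for signs in
                     (np.array(c, dtype=bool) for c in itertools.product([0, 1], repeat=n))]
        stats_all = np.array(stats_all)
        mu = stats_all.mean()
        p = np.mean(np.abs(stats_all - mu) >= abs(w_obs - mu) - 1e-12)
        return p

    def test_five_positive_differences(self):
        before = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=list("abcde"))
        after = before.copy()
        after["m"] += [0.4, 0.3, 0.2, 0.5, 0.1]
        table = compare_plans(before, after)
        assert table.loc["m", "wilcoxon_p"] == pytest.approx(0.0625)
        assert table.loc["m", "n_pairs"] == 5

    @pytest.mark.parametrize("n", [5, 6, 8, 10])
    def test_matches_enumeration_oracle(self, n, rng):
        diffs = rng.standard_normal(n)
        diffs += 0.01 * np.sign(diffs)  # avoid zeros
        before = pd.DataFrame({"m": np.arange(n, dtype=float)},
                              index=[f"c{i}" for i in range(n)])
        after = before.copy()
        after["m"] += diffs
        table = compare_plans(before, after)
        assert table.loc["m", "wilcoxon_p"] == pytest.approx(
            self.exact_sign_flip_p(diffs), abs=1e-12)

    def test_all_ties_rejected(self):
        before = pd.DataFrame({"m": [1.0, 2, 3, 4, 5]}, index=list("abcde"))
        with pytest.raises(ValueError, match="informative"):
            compare_plans(before, before.copy())

    def test_relabel_symmetry(self, rng):
        n = 8
        before = pd.DataFrame({"m": rng.standard_normal(n)},
                              index=[f"c{i}" for i in range(n)])
        after = pd.DataFrame({"m": rng.standard_normal(n)}, index=before.index)
        p1 = compare_plans(before, after).loc["m", "wilcoxon_p"]
        p2 = compare_plans(after, before).loc["m", "wilcoxon_p"]
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestPlanForTarget:
    def test_single_shot_covers_spherical_target(self):
        target = make_sphere_mask((64, 64, 64), radius=8)
        plan = plan_for_target(target)
        dose = simulate_gk_dose(plan, grid())
        assert coverage_tc(dose, target) > 0.95
        assert paddick_ci(dose, target) > 0.8
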