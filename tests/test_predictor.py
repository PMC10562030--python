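import numpy as np
import pytest

from psdcorr.fieldmap import FieldMap
from psdcorr.nn import Adam, UNet3D, l1_loss
from psdcorr.predictor import (NetConfig, TrainConfig, TrainingCase,
                               build_unet, predict_fieldmap, sample_patches,
                               train_predictor)
from psdcorr.volume import Mask3D, Volume3D


def head_like_volume(n=48, seed=0):
    rng = np.random.default_rng(seed)
    g = np.indices((n, n, n), dtype=float)
    c = (n - 1) / 2
    head = np.sqrt(sum((gi - c) ** 2 for gi in g)) <= 0.45 * n
    anat = head * 1.0 + 0.02 * rng.standard_normal((n, n, n))
    return (Volume3D(np.clip(anat, 0, None).astype(np.float32), np.eye(4), freq_axis=0),
            Mask3D(head, np.eye(4)))


def constant_field(vol, value=0.0):
    return FieldMap(offres_hz=vol.with_data(np.full(vol.shape, value, dtype=np.float32)))


class TestSamplePatches:
    def test_count_and_shape(self):
        anat, head = head_like_volume(80)
        fm = constant_field(anat)
        patches = sample_patches(anat, fm, n=16, size=64, seed=1, head_mask=head)
        assert len(patches) == 16
        assert all(a.shape == (64, 64, 64) and f.shape == (64, 64, 64)
                   for a, f, _ in patches)

    def test_seed_determinism(self):
        anat, head = head_like_volume()
        fm = constant_field(anat)
        a = [c for _, _, c in sample_patches(anat, fm, 8, 32, seed=5, head_mask=head)]
        b = [c for _, _, c in sample_patches(anat, fm, 8, 32, seed=5, head_mask=head)]
        assert a == b

    def test_volume_smaller_than_patch_rejected(self):
        anat, head = head_like_volume(32)
        with pytest.raises(ValueError, match="smaller"):
            sample_patches(anat, constant_field(anat), 4, 64, seed=0, head_mask=head)

    def test_octant_coverage(self):
        # over 100 seeded draws every octant of the head bounding box is hit
        anat, head = head_like_volume(64)
        fm = constant_field(anat)
        idx = np.argwhere(head.data)
        bmin, bmax = idx.min(0), idx.max(0)
        mid = (bmin + bmax) / 2
        hit = set()
        for a, f, corner in sample_patches(anat, fm, 100, 32, seed=3, head_mask=head):
            lo, hi = np.array(corner), np.array(corner) + 32
            for oct_id in range(8):
                bits = [(oct_id >> k) & 1 for k in range(3)]
                olo = [mid[k] if bits[k] else bmin[k] for k in range(3)]
                ohi = [bmax[k] if bits[k] else mid[k] for k in range(3)]
                if all(lo[k] < ohi[k] and hi[k] > olo[k] for k in range(3)):
                    hit.add(oct_id)
        assert hit == set(range(8))


class TestUNet:
    @pytest.mark.parametrize("n", [16, 32])
    def test_shape_contract(self, n):
        net = build_unet(NetConfig(levels=3, base_channels=2, patch=32), seed=0)
        x = np.zeros((1, 1, n, n, n), dtype=np.float32)
        assert net.forward(x, train=False).shape == x.shape

    def test_indivisible_shape_rejected(self):
        net = build_unet(NetConfig(levels=3, base_channels=2, patch=32), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 20, 20, 20), dtype=np.float32))

    def test_invalid_patch_config_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(levels=3, patch=30)

    def test_param_count_scales_quadratically(self):
        # interior k=3 convolutions have C_in*C_out*27 weights, so doubling
        # the width multiplies their count by ~4
        def interior(net):
            return sum(c.W.size for c in net.convs()
                       if c.cin > 1 and c.cout > 1)

        n1 = interior(UNet3D(levels=3, base_channels=4, seed=0))
        n2 = interior(UNet3D(levels=3, base_channels=8, seed=0))
        assert n2 / n1 == pytest.approx(4.0, rel=0.05)

    def test_seeded_init_is_identical(self):
        a = UNet3D(levels=2, base_channels=4, seed=9)
        b = UNet3D(levels=2, base_channels=4, seed=9)
        assert a.weights_hash() == b.weights_hash()
        c = UNet3D(levels=2, base_channels=4, seed=10)
        assert a.weights_hash() != c.weights_hash()

    def test_gradients_match_finite_differences(self):
        net = UNet3D(levels=2, base_channels=2, seed=3).astype(np.float64)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 8, 8, 8))
        y = rng.standard_normal((2, 1, 8, 8, 8))
        loss, g = l1_loss(net.forward(x), y)
        dx = net.backward(g)
        eps = 1e-6
        for conv in [net.convs()[0], net.convs()[len(net.convs()) // 2], net.convs()[-1]]:
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in conv.W.shape)
                w0 = conv.W[idx]
                conv.W[idx] = w0 + eps
                lp, _ = l1_loss(net.forward(x, train=False), y)
                conv.W[idx] = w0 - eps
                lm, _ = l1_loss(net.forward(x, train=False), y)
                conv.W[idx] = w0
                assert conv.dW[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)
        idx = (0, 0, 4, 4, 4)
        x0 = x[idx]
        x[idx] = x0 + eps
        lp, _ = l1_loss(net.forward(x, train=False), y)
        x[idx] = x0 - eps
        lm, _ = l1_loss(net.forward(x, train=False), y)
        assert dx[idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-7)

    def test_adam_validates_hyperparameters(self):
        net = UNet3D(levels=2, base_channels=2, seed=0)
        with pytest.raises(ValueError):
            Adam(net, lr=-1.0)
        with pytest.raises(ValueError):
            Adam(net, lr=1e-3, betas=(0.9, 1.0))


def tiny_cases(n, n_vox=32, field_value=0.0, seed0=0):
    cases = []
    for i in range(n):
        anat, head = head_like_volume(n_vox, seed=seed0 + i)
        fm = constant_field(anat, field_value)
        cases.append(TrainingCase(anat=anat, field=fm, head_mask=head))
    return cases


class TestTraining:
    def test_learns_constant_zero_field(self):
        netcfg = NetConfig(levels=2, base_channels=2, patch=16)
        traincfg = TrainConfig(lr=1e-2, epochs=5, patches_per_volume=8,
                               batch_size=2, lr_schedule="constant", seed=1)
        pred = train_predictor(tiny_cases(3), tiny_cases(1, seed0=50),
                               netcfg=netcfg, traincfg=traincfg)
        # scale is dominated by input noise; loss must fall well below it
        assert pred.history["train_loss"][-1] < 0.1 * pred.history["train_loss"][0] + 1e-3

    def test_identical_seeds_identical_runs(self):
        netcfg = NetConfig(levels=2, base_channels=2, patch=16)
        traincfg = TrainConfig(lr=1e-3, epochs=2, patches_per_volume=2, seed=4)
        a = train_predictor(tiny_cases(2), tiny_cases(1, seed0=50), netcfg, traincfg)
        b = train_predictor(tiny_cases(2), tiny_cases(1, seed0=50), netcfg, traincfg)
        assert a.history == b.history
        assert a.model.weights_hash() == b.model.weights_hash()

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train_predictor([], tiny_cases(1), NetConfig(patch=16), TrainConfig())


@pytest.fixture(scope="module")
def zero_field_predictor():
    netcfg = NetConfig(levels=2, base_channels=2, patch=16)
    traincfg = TrainConfig(lr=2e-3, epochs=6, patches_per_volume=4, seed=2)
    return train_predictor(tiny_cases(3), tiny_cases(1, seed0=50),
                           netcfg=netcfg, traincfg=traincfg)


class TestPredict:
    def test_output_lattice_matches_input(self, zero_field_predictor):
        anat, head = head_like_volume(40, seed=99)
        fm = predict_fieldmap(zero_field_predictor, anat, head)
        assert fm.offres_hz.shape == anat.shape
        np.testing.assert_array_equal(fm.offres_hz.affine, anat.affine)

    def test_zero_outside_head(self, zero_field_predictor):
        anat, head = head_like_volume(40, seed=99)
        fm = predict_fieldmap(zero_field_predictor, anat, head)
        assert np.all(fm.offres_hz.data[~head.data] == 0.0)

    def test_stitching_has_no_seams(self, zero_field_predictor):
        # stitched overlap-averaged prediction vs single-patch prediction
        anat, head = head_like_volume(32, seed=41)
        fm = predict_fieldmap(zero_field_predictor, anat, head)
        x, _, _ = __import__("psdcorr.predictor", fromlist=["robust_zscore"]).robust_zscore(
            np.asarray(anat.data, dtype=np.float32), head.data)
        grad = np.abs(np.diff(fm.offres_hz.data, axis=0))
        interior = grad[np.isfinite(grad)]
        # discontinuity at patch borders no worse than intra-patch gradients
        border = grad[15, :, :]
        assert border.max() <= interior.max() + 1e-6

    def test_scale_mismatch_warns(self, zero_field_predictor):
        anat, head = head_like_volume(32, seed=4)
        big = anat.with_data(anat.data * 1000.0)
        with pytest.warns(UserWarning, match="scale"):
            predict_fieldmap(zero_field_predictor, big, head)

    def test_save_load_roundtrip(self, zero_field_predictor, tmp_path):
        from psdcorr.predictor import TrainedPredictor

        zero_field_predictor.save(tmp_path / "w.npz", tmp_path / "m.json")
        back = TrainedPredictor.load(tmp_path / "w.npz", tmp_path / "m.json")
        assert back.model.weights_hash() == zero_field_predictor.model.weights_hash()
        assert back.field_scale_hz == zero_field_predictor.field_scale_hz
        anat, head = head_like_volume(32, seed=13)
        a = predict_fieldmap(zero_field_predictor, anat, head).offres_hz.data
        b = predict_fieldmap(back, anat, head).offres_hz.data
        np.testing.assert_array_equal(a, b)
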