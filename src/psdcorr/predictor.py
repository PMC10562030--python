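"""Learned field-map prediction from anatomical images.

A patch-based 3D U-Net regressor maps a (distorted) anatomical volume to
its off-resonance field map in Hz.  Training follows the volumetric-patch
recipe: a fixed number of randomly placed cubic patches per volume, L1 loss,
Adam (lr 2e-4, betas 0.9/0.999), best-validation weights retained.  Inputs
are normalized per volume by a robust z-score (median / IQR inside the head
mask); field targets are divided by one global scale (RMS of the training
fields inside the head) and de-normalized at prediction time.  Both scales
live in the model manifest.

Whole-volume prediction tiles the volume with 50% patch overlap and
averages overlapping predictions, then zeroes everything outside the head
mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .fieldmap import FieldMap
from .nn import Adam, UNet3D, l1_loss
from .volume import Mask3D, Volume3D, threshold_mask


@dataclass
class NetConfig:
    """Architecture of the field-map U-Net."""

    levels: int = 3
    base_channels: int = 8
    patch: int = 32

    def __post_init__(self) -> None:
        if self.patch % 2**self.levels:
            raise ValueError(
                f"patch edge {self.patch} must be divisible by 2^levels = {2**self.levels}"
            )


@dataclass
class TrainConfig:
    """Optimization settings (full-scale epochs/patches are configurable;
    the defaults here are desk-scale)."""

    lr: float = 2e-4
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 10
    patches_per_volume: int = 16
    batch_size: int = 4
    loss: str = "l1"
    #: "cosine" decays the learning rate to lr/10 over the run; "constant"
    #: keeps it fixed.
    lr_schedule: str = "constant"
    #: Axes along which training patches may be randomly mirrored.  The
    #: dipole field is exactly mirror-symmetric under flips of the axes
    #: perpendicular to B0, so flips of those axes are physics-preserving
    #: augmentation; never include the B0 axis.
    augment_flip_axes: tuple[int, ...] = (0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not all(0 < b < 1 for b in self.betas):
            raise ValueError("betas must lie in (0, 1)")
        if self.loss != "l1":
            raise ValueError("only the L1 loss is supported")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError("lr_schedule must be 'cosine' or 'constant'")


@dataclass
class TrainingCase:
    """One training example: input volume, target field, head mask."""

    anat: Volume3D
    field: FieldMap
    head_mask: Mask3D


def robust_zscore(data: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(x - median)/ (IQR/1.349) computed inside the mask; returns the
    normalized array plus (median, scale)."""
    vals = data[mask]
    med = float(np.median(vals))
    q75, q25 = np.percentile(vals, [75, 25])
    scale = float((q75 - q25) / 1.349)
    if scale <= 0:
        scale = float(np.std(vals)) or 1.0
    return (data - med) / scale, med, scale


def sample_patches(anat: Volume3D, target_field: FieldMap, n: int, size: int,
                   seed: int, head_mask: Mask3D | None = None):
    """n aligned (input, target) cubic patch pairs at uniformly random corner
    offsets inside the head bounding box; deterministic under the seed."""
    if n < 1:
        raise ValueError("need at least one patch")
    shape = np.array(anat.shape)
    if np.any(shape < size):
        raise ValueError(f"volume shape {tuple(shape)} is smaller than patch size {size}")
    if head_mask is None:
        head_mask = threshold_mask(anat, 0.2)
    idx = np.argwhere(head_mask.data)
    bmin, bmax = idx.min(axis=0), idx.max(axis=0)
    lo = np.clip(bmin, 0, shape - size)
    hi = np.clip(bmax - size + 1, lo + 1, shape - size + 1)
    rng = np.random.default_rng(seed)
    out = []
    a = np.asarray(anat.data)
    f = np.asarray(target_field.offres_hz.data)
    for _ in range(n):
        c = np.array([rng.integers(l, h) for l, h in zip(lo, hi)])
        sl = tuple(slice(ci, ci + size) for ci in c)
        out.append((a[sl], f[sl], tuple(int(ci) for ci in c)))
    return out


def build_unet(cfg: NetConfig, seed: int = 0) -> UNet3D:
    """Construct the U-Net regressor for single-channel volumes."""
    return UNet3D(levels=cfg.levels, base_channels=cfg.base_channels,
                  in_channels=1, out_channels=1, seed=seed)


@dataclass
class TrainedPredictor:
    """A trained model plus the manifest needed to apply and reproduce it."""

    model: UNet3D
    netcfg: NetConfig
    traincfg: TrainConfig
    field_scale_hz: float
    input_scale_median: float
    history: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return {
            "net": asdict(self.netcfg),
            "train": {**asdict(self.traincfg), "betas": list(self.traincfg.betas)},
            "field_scale_hz": self.field_scale_hz,
            "input_scale_median": self.input_scale_median,
            "normalization": "per-volume robust z-score (median/IQR) inside head mask",
            "history": self.history,
            "weights_sha256": self.model.weights_hash(),
            "n_parameters": self.model.n_parameters(),
        }

    def save(self, weights_path, manifest_path) -> None:
        ws = self.model.get_weights()
        np.savez(weights_path, *ws)
        Path(manifest_path).write_text(json.dumps(self.manifest(), indent=2))

    @classmethod
    def load(cls, weights_path, manifest_path) -> "TrainedPredictor":
        man = json.loads(Path(manifest_path).read_text())
        netcfg = NetConfig(**man["net"])
        tr = dict(man["train"])
        tr["betas"] = tuple(tr["betas"])
        if "augment_flip_axes" in tr:
            tr["augment_flip_axes"] = tuple(tr["augment_flip_axes"])
        traincfg = TrainConfig(**tr)
        model = build_unet(netcfg, seed=traincfg.seed)
        with np.load(weights_path) as z:
            model.set_weights([z[k] for k in z.files])
        return cls(model=model, netcfg=netcfg, traincfg=traincfg,
                   field_scale_hz=man["field_scale_hz"],
                   input_scale_median=man["input_scale_median"],
                   history=man["history"])


def _prepare_case(case: TrainingCase, fscale: float):
    x, _, scale = robust_zscore(np.asarray(case.anat.data, dtype=np.float32),
                                case.head_mask.data)
    y = np.asarray(case.field.offres_hz.data, dtype=np.float32) / fscale
    return x.astype(np.float32), y.astype(np.float32), scale


def train_predictor(train_cases: list[TrainingCase], val_cases: list[TrainingCase],
                    netcfg: NetConfig | None = None,
                    traincfg: TrainConfig | None = None) -> TrainedPredictor:
    """Train the patch-based field-map regressor.

    Patches are re-drawn each epoch from seeds derived from the global seed,
    so the whole run (init, sampling order, optimization) is reproducible.
    Validation patches are a fixed set; the weights with the best validation
    loss are retained.  Aborts on a non-finite loss.
    """
    if not train_cases or not val_cases:
        raise ValueError("need at least one training and one validation volume")
    netcfg = netcfg or NetConfig()
    traincfg = traincfg or TrainConfig()
    seed = traincfg.seed

    # global field scale from the training set (RMS inside head masks)
    sq, n = 0.0, 0
    scales = []
    for case in train_cases:
        vals = np.asarray(case.field.offres_hz.data, dtype=float)[case.head_mask.data]
        sq += float(np.sum(vals**2))
        n += vals.size
    fscale = float(np.sqrt(sq / n)) or 1.0

    prepared = [_prepare_case(c, fscale) for c in train_cases]
    scales = [p[2] for p in prepared]
    val_prepared = [_prepare_case(c, fscale) for c in val_cases]
    val_patches = []
    for i, (case, (x, y, _)) in enumerate(zip(val_cases, val_prepared)):
        for ap, fp, corner in sample_patches(
                case.anat, case.field, traincfg.patches_per_volume, netcfg.patch,
                seed=int(np.random.default_rng([seed, 9999, i]).integers(2**31)),
                head_mask=case.head_mask):
            sl = tuple(slice(c, c + netcfg.patch) for c in corner)
            val_patches.append((x[sl], y[sl]))

    model = build_unet(netcfg, seed=seed)
    opt = Adam(model, lr=traincfg.lr, betas=traincfg.betas)
    order_rng = np.random.default_rng([seed, 7777])

    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, model.get_weights())
    for epoch in range(traincfg.epochs):
        if traincfg.lr_schedule == "cosine":
            frac = epoch / max(traincfg.epochs - 1, 1)
            opt.lr = traincfg.lr * (0.1 + 0.45 * (1.0 + np.cos(np.pi * frac)))
        pool = []
        flip_rng = np.random.default_rng([seed, epoch, 5555])
        for i, (case, (x, y, _)) in enumerate(zip(train_cases, prepared)):
            ps = int(np.random.default_rng([seed, epoch, i]).integers(2**31))
            for _, _, corner in sample_patches(case.anat, case.field,
                                               traincfg.patches_per_volume,
                                               netcfg.patch, seed=ps,
                                               head_mask=case.head_mask):
                sl = tuple(slice(c, c + netcfg.patch) for c in corner)
                xp, yp = x[sl], y[sl]
                for ax in traincfg.augment_flip_axes:
                    if flip_rng.random() < 0.5:
                        xp = np.flip(xp, axis=ax)
                        yp = np.flip(yp, axis=ax)
                pool.append((np.ascontiguousarray(xp), np.ascontiguousarray(yp)))
        order_rng.shuffle(pool)
        losses = []
        for start in range(0, len(pool), traincfg.batch_size):
            batch = pool[start:start + traincfg.batch_size]
            xb = np.stack([b[0] for b in batch])[:, None]
            yb = np.stack([b[1] for b in batch])[:, None]
            pred = model.forward(xb, train=True)
            loss, grad = l1_loss(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(f"training aborted: non-finite loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            losses.append(loss)
        vlosses = []
        for start in range(0, len(val_patches), traincfg.batch_size):
            batch = val_patches[start:start + traincfg.batch_size]
            xb = np.stack([b[0] for b in batch])[:, None]
            yb = np.stack([b[1] for b in batch])[:, None]
            pred = model.forward(xb, train=False)
            vlosses.append(l1_loss(pred, yb)[0])
        tr_loss, v_loss = float(np.mean(losses)), float(np.mean(vlosses))
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(v_loss)
        if v_loss < best[0]:
            best = (v_loss, model.get_weights())
    model.set_weights(best[1])
    return TrainedPredictor(model=model, netcfg=netcfg, traincfg=traincfg,
                            field_scale_hz=fscale,
                            input_scale_median=float(np.median(scales)),
                            history=history)


def predict_fieldmap(predictor: TrainedPredictor, anat: Volume3D,
                     head_mask: Mask3D | None = None) -> FieldMap:
    """Whole-volume field-map prediction by overlapping patch tiling.

    Patches at 50% stride are predicted independently and averaged where
    they overlap; the result is de-normalized to Hz and zeroed outside the
    head mask.  Warns if the input intensity scale is >10x away from the
    training scale (suggesting un-normalized input).
    """
    if head_mask is None:
        head_mask = threshold_mask(anat, 0.2)
    data = np.asarray(anat.data, dtype=np.float32)
    x, _, scale = robust_zscore(data, head_mask.data)
    ref = predictor.input_scale_median
    if ref > 0 and not (0.1 < scale / ref < 10.0):
        import warnings

        warnings.warn(
            f"input intensity scale {scale:.3g} differs >10x from training scale "
            f"{ref:.3g}; was the volume normalized like the training data?",
            stacklevel=2,
        )
    size = predictor.netcfg.patch
    shape = np.array(anat.shape)
    if np.any(shape < size):
        raise ValueError(f"volume {tuple(shape)} smaller than patch size {size}")
    stride = max(size // 2, 1)
    starts = []
    for dim in shape:
        s = list(range(0, int(dim) - size + 1, stride))
        if s[-1] != dim - size:
            s.append(int(dim) - size)
        starts.append(s)
    # test-time augmentation over the physics-preserving mirror flips the
    # model was trained with (averaging the unflipped-back predictions)
    from itertools import chain, combinations

    axes = tuple(predictor.traincfg.augment_flip_axes)
    flip_sets = list(chain.from_iterable(
        combinations(axes, k) for k in range(len(axes) + 1)))
    acc = np.zeros(anat.shape, dtype=np.float64)
    cnt = np.zeros(anat.shape, dtype=np.float64)
    for i0 in starts[0]:
        for i1 in starts[1]:
            for i2 in starts[2]:
                sl = (slice(i0, i0 + size), slice(i1, i1 + size), slice(i2, i2 + size))
                patch = x[sl]
                pred = np.zeros((size, size, size), dtype=np.float64)
                for fs in flip_sets:
                    p = np.ascontiguousarray(np.flip(patch, axis=fs)) if fs else patch
                    out = predictor.model.forward(p[None, None], train=False)[0, 0]
                    pred += np.flip(out, axis=fs) if fs else out
                acc[sl] += pred / len(flip_sets)
                cnt[sl] += 1.0
    out = acc / cnt * predictor.field_scale_hz
    out[~head_mask.data] = 0.0
    return FieldMap(offres_hz=anat.with_data(out.astype(np.float32)))
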