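"""Patch sampling, augmentation and the training loop.

Training patches are sampled at random from whole-core images subject to
a foreground constraint: every patch must contain at least one annotated
pixel (ring boundary or duct), otherwise the network would mostly see
plain wood.  Sampling uses rejection with a retry cap so an unusable
mask fails fast instead of hanging.  Augmentation applies the same
geometric transform to the image and its mask (flips, small rotation and
shear); mask resampling is nearest-neighbour so no new label values can
appear.  The loop minimises categorical cross-entropy with Adam and
stops early when validation loss has not improved for ``patience``
epochs, returning the weights of the best validation epoch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ductseg.nn import layers as L
from ductseg.nn.unet import AttentionUNet
from ductseg.synthetic import one_hot_maps

__all__ = ["TrainConfig", "sample_patches", "augment", "train", "EarlyStopper"]

_RETRY_CAP = 10_000


@dataclass(frozen=True)
class TrainConfig:
    patches_per_image: int = 1500
    patch_size: int = 128
    val_fraction: float = 0.2
    patience: int = 10
    max_epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    augment_enabled: bool = True
    rotation_deg: float = 10.0
    shear_deg: float = 5.0
    class_weights: tuple[float, float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1 or self.patches_per_image < 1:
            raise ValueError("patience and patches_per_image must be positive")


def sample_patches(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Randomly crop ``patches_per_image`` aligned (image, mask) patch pairs.

    Every returned mask patch contains at least one foreground pixel
    (label 1 or 2).  Seed-reproducible via ``cfg.seed`` (or an explicit
    generator).
    """
    rng = rng or np.random.default_rng(cfg.seed)
    ps = cfg.patch_size
    h, w = mask.shape
    if h < ps or w < ps:
        raise ValueError(f"image {h}x{w} smaller than patch size {ps}")
    if not (mask > 0).any():
        raise ValueError("mask has no foreground anywhere; patch constraint unsatisfiable")
    pairs = []
    for _ in range(cfg.patches_per_image):
        for _attempt in range(_RETRY_CAP):
            r = int(rng.integers(0, h - ps + 1))
            c = int(rng.integers(0, w - ps + 1))
            mp = mask[r:r + ps, c:c + ps]
            if (mp > 0).any():
                pairs.append((image[r:r + ps, c:c + ps].copy(), mp.copy()))
                break
        else:
            raise RuntimeError(f"no foreground patch found in {_RETRY_CAP} draws")
    return pairs


def _affine_pair(img: np.ndarray, mask: np.ndarray,
                 rot_deg: float, shear_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Rotate+shear both members about the patch centre (mask: nearest)."""
    theta, phi = np.deg2rad(rot_deg), np.deg2rad(shear_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, np.tan(phi)], [0.0, 1.0]])
    a = rot @ shr
    a_inv = np.linalg.inv(a)
    center = (np.asarray(mask.shape, dtype=float) - 1) / 2
    offset = center - a_inv @ center
    out_img = np.stack(
        [ndi.affine_transform(img[..., ch], a_inv, offset=offset, order=1, mode="reflect")
         for ch in range(img.shape[-1])], axis=-1)
    out_mask = ndi.affine_transform(mask, a_inv, offset=offset, order=0, mode="reflect")
    return out_img.astype(img.dtype), out_mask.astype(mask.dtype)


def augment(
    pair: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator | int,
    rotation_deg: float = 10.0,
    shear_deg: float = 5.0,
    enabled: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one random geometric augmentation to an (image, mask) pair.

    Vertical and horizontal flips, rotation within ``±rotation_deg`` and
    shear within ``±shear_deg`` are each applied with probability 1/2;
    the identical transform hits both members.  With ``enabled=False``
    the pair is returned unchanged.
    """
    img, mask = pair
    if not enabled:
        return img, mask
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if rng.random() < 0.5:
        img, mask = img[::-1].copy(), mask[::-1].copy()
    if rng.random() < 0.5:
        img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
    do_rot, do_shear = rng.random() < 0.5, rng.random() < 0.5
    rot = float(rng.uniform(-rotation_deg, rotation_deg)) if do_rot else 0.0
    shear = float(rng.uniform(-shear_deg, shear_deg)) if do_shear else 0.0
    if do_rot or do_shear:
        img, mask = _affine_pair(img, mask, rot, shear)
    return img, mask


class EarlyStopper:
    """Track best validation loss; signal stop after ``patience`` bad epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.bad_epochs = 0
        self.best_epoch = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch's validation loss; return True when training should stop."""
        if loss < self.best:
            self.best, self.best_epoch, self.bad_epochs = loss, epoch, 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _batch_tensors(pairs: list[tuple[np.ndarray, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs into NHWC image and one-hot target tensors."""
    xs = np.stack([p[0] for p in pairs]).astype(np.float32)
    ys = np.stack([one_hot_maps(p[1]) for p in pairs]).astype(np.float32)
    return xs, ys


def _eval_loss(model: AttentionUNet, pairs, batch_size: int, weights) -> float:
    total, n = 0.0, 0
    for i in range(0, len(pairs), batch_size):
        x, y = _batch_tensors(pairs[i:i + batch_size])
        probs = L.softmax_channels(model.forward(x, train=False))
        loss, _ = L.cross_entropy(probs, y, weights)
        total += loss * x.shape[0]
        n += x.shape[0]
    return total / n


def train(
    model: AttentionUNet,
    patch_pairs: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> tuple[AttentionUNet, dict[str, list[float]]]:
    """Fit the network on patch pairs with early stopping.

    Splits the patches into train/validation (``val_fraction`` held out),
    augments training patches afresh each epoch, and stops once the
    validation loss has not improved for ``patience`` epochs (or at
    ``max_epochs``).  The returned model carries the weights of the best
    validation epoch; ``history`` has one train/val loss entry per epoch
    actually run.
    """
    if len(patch_pairs) < 2:
        raise ValueError("need at least 2 patch pairs (train + validation)")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(patch_pairs))
    n_val = max(1, int(round(cfg.val_fraction * len(patch_pairs))))
    val_pairs = [patch_pairs[i] for i in order[:n_val]]
    train_pairs = [patch_pairs[i] for i in order[n_val:]]
    if not train_pairs:
        raise ValueError("validation split consumed all patches")

    weights = None if cfg.class_weights is None else np.asarray(cfg.class_weights, np.float32)
    opt = L.Adam(model.params(), lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.patience)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_state = model.state_dict()

    for epoch in range(1, cfg.max_epochs + 1):
        idx = rng.permutation(len(train_pairs))
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(idx), cfg.batch_size):
            batch = [train_pairs[j] for j in idx[i:i + cfg.batch_size]]
            if cfg.augment_enabled:
                batch = [augment(p, rng, cfg.rotation_deg, cfg.shear_deg) for p in batch]
            x, y = _batch_tensors(batch)
            probs = L.softmax_channels(model.forward(x, train=True))
            loss, dlogits = L.cross_entropy(probs, y, weights)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_loss += loss * x.shape[0]
            seen += x.shape[0]
        history["train_loss"].append(epoch_loss / seen)
        val_loss = _eval_loss(model, val_pairs, cfg.batch_size, weights)
        history["val_loss"].append(val_loss)
        if val_loss <= stopper.best:
            best_state = model.state_dict()
        if stopper.update(val_loss, epoch):
            break
    model.load_state_dict(best_state)
    return model, history
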