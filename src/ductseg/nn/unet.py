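"""Downscaled attention U-Net for 3-class wood-core patch segmentation.

Encoder-decoder with two 3x3 conv + batch-norm + ReLU blocks per level,
2x2 max pooling on the way down and nearest-neighbour upsampling on the
way up.  Filter counts double per level starting from ``base_filters``
(4, 8, 16, 32, 64 at the defaults -- a quarter of the customary U-Net
widths, which suffices at a 128 px input).  Skip connections pass through
additive soft attention gates driven by the coarser decoder feature, so
the decoder can suppress skip activations in irrelevant regions.  The
head is a 1x1 convolution to 3 channels (ring boundary, resin duct,
background) with per-pixel softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ductseg.nn import layers as L

__all__ = ["ModelConfig", "AttentionUNet", "build_model"]


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 128
    input_channels: int = 3
    base_filters: int = 4
    depth: int = 4
    classes: int = 3
    attention_gates: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        s, d = self.input_size, self.depth
        if s < 2**d or (s & (s - 1)) != 0:
            raise ValueError(
                f"input_size must be a power of two >= 2^depth, got {s} with depth {d}"
            )

    @property
    def encoder_filters(self) -> tuple[int, ...]:
        """Filter count per level, shallow to deep (bottleneck last)."""
        return tuple(self.base_filters * 2**i for i in range(self.depth + 1))


class _ConvBlock:
    """(conv3x3 -> BN -> ReLU) x 2."""

    def __init__(self, name: str, c_in: int, c_out: int, rng: np.random.Generator):
        self.ops = [
            L.Conv2D(f"{name}.conv1", c_in, c_out, 3, rng), L.BatchNorm2D(f"{name}.bn1", c_out), L.ReLU(),
            L.Conv2D(f"{name}.conv2", c_out, c_out, 3, rng), L.BatchNorm2D(f"{name}.bn2", c_out), L.ReLU(),
        ]

    def params(self):
        return [p for op in self.ops for p in op.params()]

    def bns(self):
        return [op for op in self.ops if isinstance(op, L.BatchNorm2D)]

    def forward(self, x, train=True):
        for op in self.ops:
            x = op.forward(x, train)
        return x

    def backward(self, d):
        for op in reversed(self.ops):
            d = op.backward(d)
        return d


class _UpBlock:
    """Nearest x2 upsampling followed by conv3x3 -> BN -> ReLU (halves channels)."""

    def __init__(self, name: str, c_in: int, c_out: int, rng: np.random.Generator):
        self.up = L.UpsampleNearest2()
        self.ops = [L.Conv2D(f"{name}.conv", c_in, c_out, 3, rng),
                    L.BatchNorm2D(f"{name}.bn", c_out), L.ReLU()]

    def params(self):
        return [p for op in self.ops for p in op.params()]

    def bns(self):
        return [op for op in self.ops if isinstance(op, L.BatchNorm2D)]

    def forward(self, x, train=True):
        x = self.up.forward(x, train)
        for op in self.ops:
            x = op.forward(x, train)
        return x

    def backward(self, d):
        for op in reversed(self.ops):
            d = op.backward(d)
        return self.up.backward(d)


class _AttentionGate:
    """Additive soft attention on a skip connection.

    ``alpha = sigmoid(psi(relu(Wx x + Wg g)))`` with 1x1 convolutions;
    the skip feature ``x`` is scaled per pixel by ``alpha``.  The gating
    signal ``g`` comes from the coarser decoder level (already upsampled
    to the skip resolution).
    """

    def __init__(self, name: str, c: int, rng: np.random.Generator):
        c_int = max(c // 2, 1)
        self.wx = L.Conv2D(f"{name}.wx", c, c_int, 1, rng)
        self.wg = L.Conv2D(f"{name}.wg", c, c_int, 1, rng)
        self.psi = L.Conv2D(f"{name}.psi", c_int, 1, 1, rng)
        self.relu, self.sig = L.ReLU(), L.Sigmoid()
        self._cache = None

    def params(self):
        return self.wx.params() + self.wg.params() + self.psi.params()

    def bns(self):
        return []

    def forward(self, x, g, train=True):
        s = self.wx.forward(x, train) + self.wg.forward(g, train)
        alpha = self.sig.forward(self.psi.forward(self.relu.forward(s, train), train), train)
        if train:
            self._cache = (x, alpha)
        return x * alpha

    def backward(self, dout):
        x, alpha = self._cache
        self._cache = None
        dx = dout * alpha
        dalpha = (dout * x).sum(axis=-1, keepdims=True)
        ds = self.relu.backward(self.psi.backward(self.sig.backward(dalpha)))
        dx = dx + self.wx.backward(ds)
        dg = self.wg.backward(ds)
        return dx, dg


class AttentionUNet:
    """The full patch-to-probability-map segmentation network."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        filt = cfg.encoder_filters  # shallow..deep, len depth+1
        self.enc: list[_ConvBlock] = []
        self.pools: list[L.MaxPool2] = []
        c = cfg.input_channels
        for lvl in range(cfg.depth):
            self.enc.append(_ConvBlock(f"enc{lvl}", c, filt[lvl], rng))
            self.pools.append(L.MaxPool2())
            c = filt[lvl]
        self.bottleneck = _ConvBlock("bottleneck", c, filt[-1], rng)
        self.ups: list[_UpBlock] = []
        self.gates: list[_AttentionGate | None] = []
        self.dec: list[_ConvBlock] = []
        c = filt[-1]
        for lvl in reversed(range(cfg.depth)):  # deep to shallow
            f = filt[lvl]
            self.ups.append(_UpBlock(f"up{lvl}", c, f, rng))
            self.gates.append(_AttentionGate(f"att{lvl}", f, rng) if cfg.attention_gates else None)
            self.dec.append(_ConvBlock(f"dec{lvl}", 2 * f, f, rng))
            c = f
        self.head = L.Conv2D("head", c, cfg.classes, 1, rng)

    # -- parameter plumbing --------------------------------------------------

    def params(self) -> list[L.Param]:
        ps: list[L.Param] = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for up, gate, dec in zip(self.ups, self.gates, self.dec):
            ps += up.params()
            if gate is not None:
                ps += gate.params()
            ps += dec.params()
        ps += self.head.params()
        return ps

    def _bns(self) -> list[L.BatchNorm2D]:
        bns: list[L.BatchNorm2D] = []
        for blk in self.enc:
            bns += blk.bns()
        bns += self.bottleneck.bns()
        for up, dec in zip(self.ups, self.dec):
            bns += up.bns() + dec.bns()
        return bns

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        for i, bn in enumerate(self._bns()):
            state[f"bn{i}.running_mean"] = bn.running_mean.copy()
            state[f"bn{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        for i, bn in enumerate(self._bns()):
            bn.running_mean = state[f"bn{i}.running_mean"].copy()
            bn.running_var = state[f"bn{i}.running_var"].copy()

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    @classmethod
    def load(cls, path, cfg: ModelConfig | None = None) -> "AttentionUNet":
        model = cls(cfg or ModelConfig())
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
        return model

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """NHWC float input -> NHWC logits (no softmax)."""
        n, h, w, c = x.shape
        step = 2**self.cfg.depth
        if h % step or w % step:
            raise ValueError(f"spatial size {h}x{w} not divisible by 2^depth = {step}")
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._concat_sizes = []
        for up, gate, dec, skip in zip(self.ups, self.gates, self.dec, reversed(skips)):
            u = up.forward(x, train)
            s = skip if gate is None else gate.forward(skip, u, train)
            x = dec.forward(np.concatenate([s, u], axis=-1), train)
            self._concat_sizes.append(s.shape[-1])
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, gate, dec, csz in zip(reversed(self.ups), reversed(self.gates),
                                      reversed(self.dec), reversed(self._concat_sizes)):
            dcat = dec.backward(d)
            ds, du = dcat[..., :csz], dcat[..., csz:]
            if gate is not None:
                ds, dg = gate.backward(ds)
                du = du + dg
            dskips.append(ds)
            d = up.backward(du)
        # dskips is shallow..deep (decoder ran deep..shallow, backward reverses it);
        # encoder backward walks deep..shallow, so reverse again
        d = self.bottleneck.backward(d)
        for pool, blk, ds in zip(reversed(self.pools), reversed(self.enc), reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + ds)

    # -- inference -----------------------------------------------------------

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """(N, H, W, C) float images in [0,1] -> (N, H, W, classes) probabilities."""
        x = np.ascontiguousarray(batch, dtype=np.float32)
        return L.softmax_channels(self.forward(x, train=False))

    __call__ = predict_proba


def build_model(cfg: ModelConfig | None = None) -> AttentionUNet:
    """Construct an untrained network from a configuration."""
    return AttentionUNet(cfg or ModelConfig())
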