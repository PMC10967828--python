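"""Hybrid attention U-Net for multi-class B-scan segmentation.

The network is a 5-level encoder/decoder U-Net with one base stage and two
departures from the standard design:

* **Residual skip connections** — at each encoder stage the max-pooled pixel
  of every pooling window is zeroed out of the feature map that travels
  along the skip path.  The pooled maximum is already processed by the
  deeper stages, so the skip carries only the complementary (residual)
  information.

* **Hybrid attention on the skips** — the two shallowest skips pass through
  an *edge attention* (EA) block that enhances gradient structure with a
  fixed transverse/longitudinal derivative-operator pair (the gradient
  kernels of the Canny detector) before computing additive attention
  coefficients in [0, 1]; the three deepest skips pass through a *spatial
  attention* (SA) block built from channel-wise max/average pooling and a
  sigmoid.  Shallow features are edge-dominated, deep features are
  shape-dominated, hence the split.

Ablation layouts: A (attention inside encoder stages only), B (inside
decoder stages only), C (EA on all five skips), D (SA on all five skips),
and a no-attention baseline of identical stage capacity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ArgumentError, ConfigurationError
from .nn import core
from .nn.core import Tensor
from .nn.layers import Conv2d, ConvTranspose2x2, DoubleConv, Module

# Gradient-operator pair used inside the Canny edge detector: transverse
# (lateral derivative) and longitudinal (depth derivative) 3x3 Sobel kernels.
SOBEL_TRANSVERSE = np.array([[-1.0, 0.0, 1.0],
                             [-2.0, 0.0, 2.0],
                             [-1.0, 0.0, 1.0]])
SOBEL_LONGITUDINAL = SOBEL_TRANSVERSE.T.copy()

DEFAULT_ATTENTION_LAYOUT = {1: "EA", 2: "EA", 3: "SA", 4: "SA", 5: "SA"}


@dataclass(frozen=True)
class EdgeKernels:
    transverse: np.ndarray = field(default_factory=lambda: SOBEL_TRANSVERSE.copy())
    longitudinal: np.ndarray = field(default_factory=lambda: SOBEL_LONGITUDINAL.copy())

    def validate(self) -> None:
        for name, k in (("transverse", self.transverse),
                        ("longitudinal", self.longitudinal)):
            if abs(float(np.sum(k))) > 1e-12:
                raise ConfigurationError(f"{name} kernel entries must sum to 0")


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 5
    base_channels: int = 16
    n_classes: int = 5
    input_shape: tuple = (512, 256)
    attention_layout: dict = field(
        default_factory=lambda: dict(DEFAULT_ATTENTION_LAYOUT))
    variant: str = "proposed"
    seed: int = 0

    def validate(self) -> None:
        if self.depth < 1:
            raise ConfigurationError(f"depth must be >= 1, got {self.depth}")
        h, w = self.input_shape
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ConfigurationError(
                f"input_shape {self.input_shape} must be divisible by 2^depth"
                f" = {2 ** self.depth}")
        for k, v in self.attention_layout.items():
            if v not in ("EA", "SA", "none"):
                raise ConfigurationError(f"unknown attention type {v!r} at stage {k}")
        if self.variant not in ("proposed", "A", "B", "C", "D", "baseline"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")


# ---------------------------------------------------------------------------
# functional operations (numpy in, numpy out) — the testable primitives
# ---------------------------------------------------------------------------

def canny_edge_response(x: np.ndarray, kernels: EdgeKernels | None = None) -> np.ndarray:
    """Sum of the true convolutions of each channel with the transverse and
    longitudinal edge operators, edge-replicate padded to the input size.

    Accepts (C, H, W) or (N, C, H, W); both zero-sum kernels annihilate
    constant regions, so the response is supported on intensity edges.
    """
    kernels = kernels or EdgeKernels()
    kernels.validate()
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.shape[-2] < kernels.transverse.shape[0] or x.shape[-1] < kernels.transverse.shape[1]:
        raise ArgumentError(
            f"feature map {x.shape[-2:]} smaller than kernel "
            f"{kernels.transverse.shape}")
    # linearity: x*Kt + x*Kl == x*(Kt+Kl); true convolution = correlation
    # with the flipped kernel
    ksum = (kernels.transverse + kernels.longitudinal)[::-1, ::-1]
    out = core._corr_same_perchannel(x, ksum)
    return out[0] if squeeze else out


def residual_skip(x: np.ndarray, pool_size: int = 2):
    """Max-pool *x* and zero the argmax of each window in the returned residual.

    Returns ``(pooled, residual)``; ties break to the first occurrence in
    row-major window order.  Scattering the pooled values back into the
    zeroed positions reconstructs the input exactly.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    if x.shape[2] % pool_size or x.shape[3] % pool_size:
        raise ArgumentError(
            f"spatial dims {x.shape[2:]} not divisible by pool size {pool_size}")
    pooled_t, residual_t = core.maxpool_residual(Tensor(x), pool_size)
    pooled, residual = pooled_t.data, residual_t.data
    if squeeze:
        pooled, residual = pooled[0], residual[0]
    return pooled, residual


def spatial_attention(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Functional SA: returns (gated output, attention map in (0, 1)).

    The channel-wise max map and average map are stacked (the padding that
    makes the two pooled maps a single 2-channel tensor), passed through a
    sigmoid, and the two sigmoid channels are averaged into one broadcast
    map that scales the input.
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    mx = x.max(axis=1, keepdims=True)
    av = x.mean(axis=1, keepdims=True)
    att = 0.5 * (core._sigmoid(mx) + core._sigmoid(av))
    out = x * att
    if squeeze:
        return out[0], att[0, 0]
    return out, att[:, 0]


# ---------------------------------------------------------------------------
# attention blocks (modules)
# ---------------------------------------------------------------------------

class EdgeAttentionBlock(Module):
    """Edge-enhanced additive attention gate for a skip connection.

    The skip feature map is enriched with its edge response (fusion by
    addition), then gated by alpha = sigmoid(psi(ReLU(Ws.enhanced +
    Wg.gate))) computed with 1x1 convolutions; the block returns
    alpha * enhanced with every coefficient in [0, 1].
    """

    def __init__(self, skip_ch: int, gate_ch: int, rng: np.random.Generator,
                 kernels: EdgeKernels | None = None, dtype=np.float32):
        super().__init__()
        inter = max(skip_ch // 2, 1)
        self.kernels = kernels or EdgeKernels()
        self.kernels.validate()
        self.w_skip = Conv2d(skip_ch, inter, 1, rng, pad=0, dtype=dtype)
        self.w_gate = Conv2d(gate_ch, inter, 1, rng, pad=0, dtype=dtype)
        self.psi = Conv2d(inter, 1, 1, rng, pad=0, dtype=dtype)
        self.last_alpha: np.ndarray | None = None
        self._ksum = (self.kernels.transverse + self.kernels.longitudinal)[::-1, ::-1]

    def __call__(self, skip: Tensor, gate: Tensor,
                 upsample_gate: bool = False) -> Tensor:
        if upsample_gate:
            gate = core.upsample_nearest2(gate)
        if gate.data.shape[2:] != skip.data.shape[2:]:
            raise ArgumentError(
                f"gate spatial dims {gate.data.shape[2:]} incompatible with "
                f"skip {skip.data.shape[2:]}")
        edges = core.fixed_conv3(skip, self._ksum)
        enhanced = core.add(skip, edges)
        summed = core.add(self.w_skip(enhanced), self.w_gate(gate))
        alpha = core.sigmoid(self.psi(core.relu(summed)))
        self.last_alpha = alpha.data[:, 0]
        return core.mul(enhanced, alpha)


class SpatialAttentionBlock(Module):
    """Parameter-free spatial gate from channel max/average pooling."""

    def __init__(self):
        super().__init__()
        self.last_attention: np.ndarray | None = None

    def __call__(self, x: Tensor) -> Tensor:
        mx = core.sigmoid(core.channel_max(x))
        av = core.sigmoid(core.channel_mean(x))
        att = core.mul(core.add(mx, av), 0.5)
        self.last_attention = att.data[:, 0]
        return core.mul(x, att)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class SegmentationModel(Module):
    """Encoder/decoder segmentation network with configurable attention."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
        d = config.depth
        chans = [config.base_channels * 2 ** i for i in range(d)]
        self.stage_channels = chans

        layout = self._resolve_layout(config)
        self.skip_layout = layout["skip"]
        self.encoder_layout = layout["encoder"]
        self.decoder_layout = layout["decoder"]

        cin = 1
        for i, ch in enumerate(chans, start=1):
            setattr(self, f"enc{i}", DoubleConv(cin, ch, rng))
            cin = ch
        self.base = DoubleConv(chans[-1], chans[-1] * 2, rng)

        deep = chans[-1] * 2
        for i in range(d, 0, -1):
            ch = chans[i - 1]
            setattr(self, f"up{i}", ConvTranspose2x2(deep, ch, rng))
            setattr(self, f"dec{i}", DoubleConv(ch * 2, ch, rng))
            if self.skip_layout.get(i) == "EA":
                setattr(self, f"skip_att{i}", EdgeAttentionBlock(ch, deep, rng))
            elif self.skip_layout.get(i) == "SA":
                setattr(self, f"skip_att{i}", SpatialAttentionBlock())
            if self.encoder_layout.get(i) == "EA":
                setattr(self, f"enc_att{i}", EdgeAttentionBlock(ch, ch, rng))
            elif self.encoder_layout.get(i) == "SA":
                setattr(self, f"enc_att{i}", SpatialAttentionBlock())
            if self.decoder_layout.get(i) == "EA":
                setattr(self, f"dec_att{i}", EdgeAttentionBlock(ch, ch, rng))
            elif self.decoder_layout.get(i) == "SA":
                setattr(self, f"dec_att{i}", SpatialAttentionBlock())
            deep = ch
        self.head = Conv2d(chans[0], config.n_classes, 1, rng, pad=0)

    @staticmethod
    def _resolve_layout(config: ModelConfig) -> dict:
        d = config.depth
        none = {i: "none" for i in range(1, d + 1)}
        if config.variant == "proposed":
            skip = dict(none)
            skip.update(config.attention_layout)
            return {"skip": skip, "encoder": dict(none), "decoder": dict(none)}
        if config.variant == "baseline":
            return {"skip": dict(none), "encoder": dict(none), "decoder": dict(none)}
        shallow_deep = {i: ("EA" if i <= 2 else "SA") for i in range(1, d + 1)}
        if config.variant == "A":
            return {"skip": dict(none), "encoder": shallow_deep, "decoder": dict(none)}
        if config.variant == "B":
            return {"skip": dict(none), "encoder": dict(none), "decoder": shallow_deep}
        if config.variant == "C":
            return {"skip": {i: "EA" for i in range(1, d + 1)},
                    "encoder": dict(none), "decoder": dict(none)}
        if config.variant == "D":
            return {"skip": {i: "SA" for i in range(1, d + 1)},
                    "encoder": dict(none), "decoder": dict(none)}
        raise ConfigurationError(f"unknown variant {config.variant!r}")

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor, train: bool = False) -> Tensor:
        """Logits (N, n_classes, H, W) for input (N, 1, H, W)."""
        self.train(train)
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        d = self.config.depth
        skips: dict[int, Tensor] = {}
        h = x
        for i in range(1, d + 1):
            h = getattr(self, f"enc{i}")(h)
            if self.encoder_layout.get(i) == "EA":
                h = getattr(self, f"enc_att{i}")(h, h)
            elif self.encoder_layout.get(i) == "SA":
                h = getattr(self, f"enc_att{i}")(h)
            pooled, residual = core.maxpool_residual(h, 2)
            skips[i] = residual
            h = pooled
        h = self.base(h)
        for i in range(d, 0, -1):
            gate = h                      # deeper feature gates the skip
            up = getattr(self, f"up{i}")(h)
            skip = skips[i]
            kind = self.skip_layout.get(i)
            if kind == "EA":
                skip = getattr(self, f"skip_att{i}")(skip, gate, upsample_gate=True)
            elif kind == "SA":
                skip = getattr(self, f"skip_att{i}")(skip)
            h = getattr(self, f"dec{i}")(core.concat_channels([up, skip]))
            if self.decoder_layout.get(i) == "EA":
                h = getattr(self, f"dec_att{i}")(h, h)
            elif self.decoder_layout.get(i) == "SA":
                h = getattr(self, f"dec_att{i}")(h)
        return self.head(h)

    __call__ = forward

    def predict_proba(self, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
        """Per-pixel class probabilities (N, n_classes, H, W), eval mode."""
        images = _as_nchw(images)
        outs = []
        for i in range(0, images.shape[0], batch_size):
            logits = self.forward(images[i:i + batch_size], train=False)
            outs.append(core.softmax(logits.data, axis=1))
        return np.concatenate(outs, axis=0)

    def predict(self, images: np.ndarray, batch_size: int = 4) -> np.ndarray:
        """Label masks (N, H, W)."""
        return self.predict_proba(images, batch_size).argmax(axis=1).astype(np.uint8)

    # -- introspection ------------------------------------------------------
    def count_blocks(self) -> dict:
        n_ea = sum(isinstance(m, EdgeAttentionBlock) for m in self.modules())
        n_sa = sum(isinstance(m, SpatialAttentionBlock) for m in self.modules())
        return {
            "encoder_stages": self.config.depth,
            "decoder_stages": self.config.depth,
            "base_stages": 1,
            "edge_attention": n_ea,
            "spatial_attention": n_sa,
        }

    def attention_maps(self) -> dict[str, np.ndarray]:
        """Attention coefficients recorded on the most recent forward pass."""
        maps = {}
        for name, m in self._modules.items():
            if isinstance(m, EdgeAttentionBlock) and m.last_alpha is not None:
                maps[name] = m.last_alpha
            if isinstance(m, SpatialAttentionBlock) and m.last_attention is not None:
                maps[name] = m.last_attention
        return maps

    def summary(self) -> dict:
        stages = []
        for i in range(1, self.config.depth + 1):
            stages.append({"stage": i, "channels": self.stage_channels[i - 1],
                           "skip_attention": self.skip_layout.get(i, "none"),
                           "encoder_attention": self.encoder_layout.get(i, "none"),
                           "decoder_attention": self.decoder_layout.get(i, "none")})
        return {
            "variant": self.config.variant,
            "n_classes": self.config.n_classes,
            "input_shape": list(self.config.input_shape),
            "n_parameters": self.n_parameters(),
            "blocks": self.count_blocks(),
            "stages": stages,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def _as_nchw(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 2:
        images = images[None]
    if images.ndim == 3:
        images = images[:, None]
    return images


def build_model(config: ModelConfig | None = None) -> SegmentationModel:
    """Construct the hybrid attention U-Net described by *config*."""
    return SegmentationModel(config or ModelConfig())


def build_ablation_variant(code: str, config: ModelConfig | None = None) -> SegmentationModel:
    """Attention-placement ablations: A (encoder-only), B (decoder-only),
    C (edge attention on all skips), D (spatial attention on all skips)."""
    if code not in ("A", "B", "C", "D"):
        raise ArgumentError(f"unknown ablation code {code!r}; valid: A, B, C, D")
    base = config or ModelConfig()
    cfg = ModelConfig(depth=base.depth, base_channels=base.base_channels,
                      n_classes=base.n_classes, input_shape=base.input_shape,
                      attention_layout=dict(base.attention_layout),
                      variant=code, seed=base.seed)
    return SegmentationModel(cfg)
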