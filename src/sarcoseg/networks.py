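"""Segmentation architectures: multi-encoder UNets with attention-weighted fusion.

Three variants share one encoder/decoder skeleton:

``sunet``
    A single-encoder UNet whose input is the M modality slices stacked as
    channels; skip connections carry the encoder feature maps unchanged.
``munet``
    One encoder path per modality; at every skip level the M feature maps
    are concatenated along channels before entering the decoder.
``ours``
    One encoder path per modality; at every skip level (and at the
    bottleneck input) the concatenated multi-modal feature map F is passed
    through the attention-weighted fusion block

        F_c = sigmoid(W2 . ReLU(W1 . GAP(F)))  broadcast-multiplied onto F
        F_s = sigmoid(maxpool_channels(F) + conv1x1(F)) multiplied onto F
        F_f = F_c + F_s

    i.e. a channel gate driven by globally pooled statistics and a spatial
    gate driven by the channel-wise maximum plus a learned 1x1 projection.

Encoders have 4 levels of two 3x3 convolutions followed by 2x2 max-pooling;
channel counts double per level from ``base_channels`` (64 -> 512 at the
default width).  The decoder mirrors this with 2x2 transposed convolutions
and ends in a 1x1 convolution and a per-pixel softmax over the two classes
(background / tumor).

The module also exposes framework-free functional versions of the attention
operations (`channel_attention`, `spatial_attention`, `attention_fusion`)
operating on H x W x C arrays, which the trainable blocks are tested
against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ValidationError

MODALITIES = ("T1WI", "T2WI", "STIR")

__all__ = [
    "MODALITIES",
    "ChannelGateParams",
    "SpatialGateParams",
    "FusionParams",
    "channel_attention",
    "spatial_attention",
    "attention_fusion",
    "ModelConfig",
    "SegModel",
    "build_model",
    "forward_segment",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------------
# functional attention ops on H x W x C arrays


@dataclass
class ChannelGateParams:
    """Weights of the two fully connected layers of the channel gate.

    ``w1`` maps C -> C/2 and ``w2`` maps C/2 -> C (stored as (C/2, C) and
    (C, C/2) matrices acting on column vectors); the activations are fixed
    to ReLU between the layers and a sigmoid on the output.
    """

    w1: np.ndarray
    w2: np.ndarray

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        self.w2 = np.asarray(self.w2, dtype=np.float64)
        c_half, c = self.w1.shape
        if c != 2 * c_half or self.w2.shape != (c, c_half):
            raise ValidationError(
                f"channel gate weights must be (C/2, C) and (C, C/2); got "
                f"{self.w1.shape} and {self.w2.shape}"
            )

    @property
    def n_channels(self) -> int:
        return self.w1.shape[1]


@dataclass
class SpatialGateParams:
    """Weight of the 1x1 convolution projecting C channels to one map."""

    ws: np.ndarray

    def __post_init__(self):
        self.ws = np.asarray(self.ws, dtype=np.float64).reshape(-1)

    @property
    def n_channels(self) -> int:
        return self.ws.size


@dataclass
class FusionParams:
    channel: ChannelGateParams
    spatial: SpatialGateParams

    def __post_init__(self):
        if self.channel.n_channels != self.spatial.n_channels:
            raise ValidationError("channel/spatial gate channel counts differ")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _check_channels(f: np.ndarray, expected: int, op: str) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValidationError(f"{op} expects an H x W x C array, got shape {f.shape}")
    if f.shape[2] != expected:
        raise ValidationError(
            f"{op}: feature map has {f.shape[2]} channels, params expect {expected}"
        )
    return f


def channel_attention(f: np.ndarray, params: ChannelGateParams) -> np.ndarray:
    """Gate each channel by a squeeze-and-excitation style weight.

    Z_k is the global average of channel k; the gate is
    sigmoid(W2 . ReLU(W1 . Z)) and multiplies channel k of the input.
    """
    f = _check_channels(f, params.n_channels, "channel_attention")
    z = f.mean(axis=(0, 1))
    zhat = params.w2 @ np.maximum(params.w1 @ z, 0.0)
    gate = _sigmoid(zhat)
    return f * gate[None, None, :]


def spatial_attention(f: np.ndarray, params: SpatialGateParams) -> np.ndarray:
    """Gate each spatial position by sigmoid(p + q).

    q is a learned linear combination of the channels at each position
    (a 1x1 convolution); p is the channel-wise maximum at that position.
    """
    f = _check_channels(f, params.n_channels, "spatial_attention")
    q = f @ params.ws
    p = f.max(axis=2)
    gate = _sigmoid(p + q)
    return f * gate[:, :, None]


def attention_fusion(features, params: FusionParams) -> np.ndarray:
    """Concatenate modality feature maps along channels and apply F_c + F_s."""
    features = [np.asarray(f, dtype=np.float64) for f in features]
    if not features:
        raise ValidationError("attention_fusion needs at least one feature map")
    shape = features[0].shape
    if any(f.shape != shape for f in features):
        raise ValidationError(
            f"attention_fusion: heterogeneous shapes {[f.shape for f in features]}"
        )
    f = np.concatenate(features, axis=2)
    return channel_attention(f, params.channel) + spatial_attention(f, params.spatial)


# ---------------------------------------------------------------------------
# trainable modules


class Module:
    """Tiny module base: parameter/buffer discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def set_training(self, mode: bool):
        self.training = mode
        for _, child in self._children():
            child.set_training(mode)
        return self


def _kaiming_uniform(rng, shape, fan_in):
    bound = np.sqrt(6.0 / fan_in)
    return (rng.uniform(-bound, bound, size=shape)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, bias=True):
        super().__init__()
        self.k = k
        self.w = Tensor(_kaiming_uniform(rng, (cout, cin, k, k), cin * k * k),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b)


class ConvTranspose2d(Module):
    """2x2 stride-2 learned upsampling."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.w = Tensor(_kaiming_uniform(rng, (cin, cout, 2, 2), cin * 4),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True)

    def __call__(self, x):
        return ad.conv_transpose2d_2x2(x, self.w, self.b)


class Linear(Module):
    def __init__(self, cin, cout, rng, bias=False):
        super().__init__()
        self.w = Tensor(_kaiming_uniform(rng, (cin, cout), cin), requires_grad=True)
        self.b = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def __call__(self, x):
        y = ad.matmul(x, self.w)
        return y if self.b is None else ad.add(y, self.b)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self._buffer_names = ("running_mean", "running_var")
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x):
        c = x.shape[1]
        if self.training:
            mean = ad.reduce_mean(x, axis=(0, 2, 3), keepdims=True)
            centered = ad.sub(x, mean)
            var = ad.reduce_mean(ad.mul(centered, centered), axis=(0, 2, 3),
                                 keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (mean.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            inv = ad.div(ad.constant(np.float32(1.0)),
                         ad.sqrt(ad.add(var, ad.constant(np.float32(self.eps)))))
            xhat = ad.mul(centered, inv)
        else:
            mean = self.running_mean.reshape(1, c, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = ad.mul(ad.sub(x, ad.constant(mean)),
                          ad.constant(inv.reshape(1, c, 1, 1).astype(np.float32)))
        g = ad.reshape(self.gamma, (1, c, 1, 1))
        b = ad.reshape(self.beta, (1, c, 1, 1))
        return ad.add(ad.mul(xhat, g), b)


class DoubleConv(Module):
    """Two 3x3 conv (+BN) + ReLU blocks, optionally with an identity shortcut."""

    def __init__(self, cin, cout, rng, batchnorm=True, residual=False):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, rng, bias=not batchnorm)
        self.conv2 = Conv2d(cout, cout, 3, rng, bias=not batchnorm)
        self.bn1 = BatchNorm2d(cout) if batchnorm else None
        self.bn2 = BatchNorm2d(cout) if batchnorm else None
        self.residual = residual
        if residual and cin != cout:
            self.proj = Conv2d(cin, cout, 1, rng, bias=False)
        else:
            self.proj = None

    def __call__(self, x):
        y = self.conv1(x)
        if self.bn1 is not None:
            y = self.bn1(y)
        y = ad.relu(y)
        y = self.conv2(y)
        if self.bn2 is not None:
            y = self.bn2(y)
        if self.residual:
            shortcut = self.proj(x) if self.proj is not None else x
            y = ad.add(y, shortcut)
        return ad.relu(y)


class ChannelGate(Module):
    """Trainable channel gate: GAP -> FC(C -> C/2) -> ReLU -> FC(C/2 -> C) -> sigmoid."""

    def __init__(self, c, rng):
        super().__init__()
        if c % 2:
            raise ValidationError(f"channel gate needs an even channel count, got {c}")
        self.fc1 = Linear(c, c // 2, rng)
        self.fc2 = Linear(c // 2, c, rng)
        self.c = c

    def __call__(self, f):
        z = ad.reduce_mean(f, axis=(2, 3))
        gate = ad.sigmoid(self.fc2(ad.relu(self.fc1(z))))
        return ad.mul(f, ad.reshape(gate, (f.shape[0], self.c, 1, 1)))


class SpatialGate(Module):
    """Trainable spatial gate: sigmoid(channel-max + 1x1 conv projection)."""

    def __init__(self, c, rng):
        super().__init__()
        self.conv = Conv2d(c, 1, 1, rng, bias=False)

    def __call__(self, f):
        q = self.conv(f)
        p = ad.reduce_max(f, axis=1, keepdims=True)
        gate = ad.sigmoid(ad.add(p, q))
        return ad.mul(f, gate)


class FusionBlock(Module):
    """Attention-weighted fusion F_f = F_c + F_s on channel-concatenated inputs."""

    def __init__(self, c_total, rng):
        super().__init__()
        self.channel_gate = ChannelGate(c_total, rng)
        self.spatial_gate = SpatialGate(c_total, rng)

    def __call__(self, features):
        f = features[0] if len(features) == 1 else ad.concat(features, axis=1)
        return ad.add(self.channel_gate(f), self.spatial_gate(f))

    def functional_params(self) -> FusionParams:
        """Export the gate weights in the functional H x W x C convention."""
        return FusionParams(
            channel=ChannelGateParams(
                w1=self.channel_gate.fc1.w.data.T, w2=self.channel_gate.fc2.w.data.T
            ),
            spatial=SpatialGateParams(ws=self.spatial_gate.conv.w.data.reshape(-1)),
        )


class EncoderPath(Module):
    """4 levels of DoubleConv + 2x2 max-pool; returns per-level skips + pooled output."""

    def __init__(self, cin, config: "ModelConfig", rng):
        super().__init__()
        chans = config.channel_schedule
        self.blocks = []
        prev = cin
        for c in chans:
            self.blocks.append(
                DoubleConv(prev, c, rng, config.batchnorm, config.residual_blocks)
            )
            prev = c

    def __call__(self, x):
        skips = []
        for block in self.blocks:
            x = block(x)
            skips.append(x)
            x = ad.maxpool2d_2x2(x)
        return skips, x


# ---------------------------------------------------------------------------
# model configuration and assembly


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``variant`` selects the fusion strategy (``sunet`` / ``munet`` / ``ours``);
    the encoder always has 4 levels with channel counts doubling from
    ``base_channels`` and the bottleneck doubles once more (1024 at the
    default width of 64).
    """

    n_modalities: int = 3
    n_layers: int = 4
    base_channels: int = 64
    n_classes: int = 2
    variant: str = "ours"
    residual_blocks: bool = False
    batchnorm: bool = True

    def __post_init__(self):
        if self.variant not in ("sunet", "munet", "ours"):
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.n_layers != 4:
            raise ValidationError("the architecture is fixed at 4 encoder levels")
        if self.n_modalities < 1:
            raise ValidationError("need at least one modality")
        if self.base_channels % 2:
            raise ValidationError("base_channels must be even (channel gate C/2)")

    @property
    def channel_schedule(self):
        return [self.base_channels * 2**l for l in range(self.n_layers)]

    @property
    def bottleneck_channels(self):
        return self.base_channels * 2**self.n_layers


class SegModel(Module):
    """Encoder(s) + fusion + decoder + softmax head; built by :func:`build_model`."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        m = config.n_modalities
        chans = config.channel_schedule
        deep = chans[-1]

        if config.variant == "sunet":
            self.encoders = [EncoderPath(m, config, rng)]
            skip_ch = list(chans)
            bottleneck_in = deep
        else:
            self.encoders = [EncoderPath(1, config, rng) for _ in range(m)]
            skip_ch = [m * c for c in chans]
            bottleneck_in = m * deep

        if config.variant == "ours":
            self.fusions = [FusionBlock(c, rng) for c in skip_ch]
            self.bottleneck_fusion = FusionBlock(bottleneck_in, rng)
        else:
            self.fusions = None
            self.bottleneck_fusion = None

        self.bottleneck = DoubleConv(
            bottleneck_in, config.bottleneck_channels, rng,
            config.batchnorm, config.residual_blocks,
        )
        self.upconvs = []
        self.dec_blocks = []
        for l in reversed(range(config.n_layers)):
            c_l = chans[l]
            self.upconvs.append(ConvTranspose2d(2 * c_l, c_l, rng))
            self.dec_blocks.append(
                DoubleConv(c_l + skip_ch[l], c_l, rng,
                           config.batchnorm, config.residual_blocks)
            )
        self.head = Conv2d(chans[0], config.n_classes, 1, rng)

    # -- forward -----------------------------------------------------------

    def _fuse(self, features, level):
        if self.config.variant == "ours":
            return self.fusions[level](features)
        if len(features) == 1:
            return features[0]
        return ad.concat(features, axis=1)

    def __call__(self, stack, return_features: bool = False):
        """Map an (N, M, H, W) batch to (N, n_classes, H, W) probabilities.

        With ``return_features`` also return the per-modality deepest
        (post-pool) encoder activations, used by the self-supervised
        pretraining stage.
        """
        x = np.asarray(stack, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        n, m, h, w = x.shape
        if m != self.config.n_modalities:
            raise ValidationError(
                f"model expects {self.config.n_modalities} modalities, got {m}"
            )
        if h % 16 or w % 16:
            raise ValidationError(
                f"spatial size must be divisible by 16, got {h}x{w}"
            )
        xt = ad.constant(x)
        if self.config.variant == "sunet":
            skips, pooled = self.encoders[0](xt)
            per_level = [[s] for s in skips]
            pooled_all = [pooled]
        else:
            per_level = [[] for _ in range(self.config.n_layers)]
            pooled_all = []
            for mi, enc in enumerate(self.encoders):
                xm = ad.constant(x[:, mi : mi + 1])
                skips, pooled = enc(xm)
                for l, s in enumerate(skips):
                    per_level[l].append(s)
                pooled_all.append(pooled)

        if self.config.variant == "ours":
            bott_in = self.bottleneck_fusion(pooled_all)
        elif len(pooled_all) == 1:
            bott_in = pooled_all[0]
        else:
            bott_in = ad.concat(pooled_all, axis=1)

        y = self.bottleneck(bott_in)
        for i, l in enumerate(reversed(range(self.config.n_layers))):
            y = self.upconvs[i](y)
            fused = self._fuse(per_level[l], l)
            y = ad.concat([y, fused], axis=1)
            y = self.dec_blocks[i](y)
        prob = ad.softmax_channel(self.head(y))
        if return_features:
            return prob, pooled_all
        return prob

    # -- state -------------------------------------------------------------

    def state_dict(self) -> dict:
        state = {name: t.data.copy() for name, t in self.named_parameters()}
        state.update({name: np.array(buf) for name, buf in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        for name, buf in self.named_buffers():
            own[name] = buf
        missing = set(own) - set(state)
        if missing:
            raise ValidationError(f"state dict missing keys: {sorted(missing)[:5]} ...")
        for name, target in own.items():
            value = np.asarray(state[name], dtype=np.float32)
            if isinstance(target, Tensor):
                if target.data.shape != value.shape:
                    raise ValidationError(
                        f"shape mismatch for {name}: {target.data.shape} vs {value.shape}"
                    )
                target.data[...] = value
            else:
                target[...] = value
        return self


def build_model(config: ModelConfig, seed: int = 0) -> SegModel:
    """Construct a segmentation model with seed-determined initial weights."""
    return SegModel(config, seed=seed)


def forward_segment(model: SegModel, stack):
    """Inference on one modality stack: (probability map, binary prediction).

    The prediction is the per-pixel argmax with ties resolved to background.
    """
    model.set_training(False)
    prob = model(np.asarray(stack, dtype=np.float32)[None]).data[0]
    pred = (prob[1] > prob[0]).astype(np.uint8)
    return prob, pred


def count_parameters(model: SegModel) -> int:
    return int(sum(t.data.size for t in model.parameters()))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: SegModel, path, extra: dict | None = None):
    """Write weights + config (+ free-form metadata) as a single npz file."""
    meta = {"config": asdict(model.config), "seed": model.seed,
            "extra": extra or {}}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    ).copy()
    # write through a handle so numpy does not append ".npz" to bare paths
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[SegModel, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    model = SegModel(ModelConfig(**meta["config"]), seed=meta["seed"])
    model.load_state_dict(state)
    return model, meta.get("extra", {})
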