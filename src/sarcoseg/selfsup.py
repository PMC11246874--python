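"""Masked-input self-supervised pretraining of the modality encoders.

Each modality's encoder path is pretrained on its own slices with a twin
weight-sharing setup: the clean slice I runs through the full single-path
segmentation network (encoder + decoder, supervised by the Dice term on
the box ground truth), and a corrupted copy I' — the same slice with one
30 x 30 patch at the tumor boundary replaced by a fill value — runs through
the *same* encoder to produce a second feature vector.  Writing Fvec and
Gvec for the flattened deepest encoder activations of I and I', the step
loss is

    L_total = L_similarity + L_dice
    L_similarity = 1 - <Fvec, Gvec> / (||Fvec||_2 ||Gvec||_2)
    L_dice = -(2 sum(y_p y_t) + eps) / (sum(y_p) + sum(y_t) + eps)

Minimizing L_similarity pulls the features of the corrupted input toward
those of the clean input (the printed cosine form is available as
``mode="literal_cos"`` for fidelity experiments, but minimizing the raw
cosine would push the two apart).  Only the clean branch contributes the
Dice term.  After pretraining, `transfer_weights` copies the three encoder
parameter sets into the corresponding paths of a multi-encoder model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .errors import DegenerateInputError, TransferError, ValidationError
from .networks import ModelConfig, SegModel, build_model

__all__ = [
    "MaskCorruption",
    "SslLossTerms",
    "PretrainConfig",
    "apply_boundary_mask",
    "cosine_similarity_loss",
    "dice_loss",
    "pretrain_encoder",
    "transfer_weights",
]

DICE_EPS = 1e-5


@dataclass(frozen=True)
class MaskCorruption:
    """Where and how one slice was corrupted (patch in row/col pixel units)."""

    patch_size: int
    patch_top_left: tuple[int, int]
    fill_value: float = 0.0


@dataclass(frozen=True)
class SslLossTerms:
    l_similarity: float
    l_dice: float

    @property
    def l_total(self) -> float:
        return self.l_similarity + self.l_dice


def apply_boundary_mask(slice_2d, gt_mask, patch_size: int = 30, rng=None,
                        fill_value: float = 0.0):
    """Blank one patch at the tumor boundary.

    The patch center is drawn uniformly from the boundary pixels of the
    ground-truth mask (mask pixels 4-adjacent to a non-mask pixel, image
    border included), the window is clamped inside the slice, and pixels in
    the window are set to ``fill_value``.
    """
    rng = np.random.default_rng(rng)
    img = np.array(slice_2d, dtype=np.float32, copy=True)
    mask = np.asarray(gt_mask).astype(bool)
    if img.shape != mask.shape:
        raise ValidationError(f"slice {img.shape} and mask {mask.shape} differ")
    if not mask.any():
        raise ValidationError("ground-truth mask is empty: no tumor boundary to shield")
    boundary = _boundary_pixels(mask)
    ys, xs = np.nonzero(boundary)
    pick = rng.integers(ys.size)
    cy, cx = int(ys[pick]), int(xs[pick])
    rows, cols = img.shape
    y0 = min(max(cy - patch_size // 2, 0), max(rows - patch_size, 0))
    x0 = min(max(cx - patch_size // 2, 0), max(cols - patch_size, 0))
    img[y0 : y0 + patch_size, x0 : x0 + patch_size] = fill_value
    return img, MaskCorruption(patch_size=patch_size, patch_top_left=(y0, x0),
                               fill_value=fill_value)


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 4-neighbour outside the mask."""
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return mask & ~interior


def cosine_similarity_loss(f, g, mode: str = "one_minus_cos"):
    """Feature-agreement loss between two flattened feature vectors.

    Accepts numpy arrays (returns a float) or autodiff tensors (returns a
    scalar Tensor on the graph).  ``one_minus_cos`` is the trainable form
    in [0, 2]; ``literal_cos`` returns the raw cosine.
    """
    if mode not in ("one_minus_cos", "literal_cos"):
        raise ValidationError(f"unknown mode {mode!r}")
    if isinstance(f, ad.Tensor) or isinstance(g, ad.Tensor):
        ft = f if isinstance(f, ad.Tensor) else ad.constant(np.asarray(f, np.float32))
        gt = g if isinstance(g, ad.Tensor) else ad.constant(np.asarray(g, np.float32))
        _check_nonzero(ft.data, gt.data)
        dot = ad.reduce_sum(ad.mul(ft, gt))
        nf = ad.sqrt(ad.reduce_sum(ad.mul(ft, ft)))
        ng = ad.sqrt(ad.reduce_sum(ad.mul(gt, gt)))
        cos = ad.div(dot, ad.mul(nf, ng))
        return ad.sub(ad.constant(np.float32(1.0)), cos) if mode == "one_minus_cos" else cos
    f = np.asarray(f, dtype=np.float64).ravel()
    g = np.asarray(g, dtype=np.float64).ravel()
    if f.shape != g.shape:
        raise ValidationError("feature vectors differ in length")
    _check_nonzero(f, g)
    # rounding can push |cos| infinitesimally past 1 for (anti)parallel vectors
    cos = float(np.clip(f @ g / (np.linalg.norm(f) * np.linalg.norm(g)), -1.0, 1.0))
    return 1.0 - cos if mode == "one_minus_cos" else cos


def _check_nonzero(f, g):
    if not np.any(f) or not np.any(g):
        raise DegenerateInputError("zero-norm feature vector in cosine similarity")


def dice_loss(y_p, y_t, eps: float = DICE_EPS):
    """Soft Dice loss -(2 sum(y_p y_t) + eps)/(sum(y_p) + sum(y_t) + eps) in [-1, 0].

    ``y_p`` are foreground probabilities, ``y_t`` the binary ground truth;
    the smoothing constant defines the empty-vs-empty case as -1 (perfect).
    Accepts numpy arrays (float result) or an autodiff tensor prediction.
    """
    if isinstance(y_p, ad.Tensor):
        yt = ad.constant(np.asarray(y_t, np.float32))
        if y_p.shape != yt.shape:
            raise ValidationError(f"shape mismatch {y_p.shape} vs {yt.shape}")
        num = ad.add(ad.mul(ad.constant(np.float32(2.0)),
                            ad.reduce_sum(ad.mul(y_p, yt))),
                     ad.constant(np.float32(eps)))
        den = ad.add(ad.add(ad.reduce_sum(y_p), ad.reduce_sum(yt)),
                     ad.constant(np.float32(eps)))
        return ad.neg(ad.div(num, den))
    y_p = np.asarray(y_p, dtype=np.float64)
    y_t = np.asarray(y_t, dtype=np.float64)
    if y_p.shape != y_t.shape:
        raise ValidationError(f"shape mismatch {y_p.shape} vs {y_t.shape}")
    if y_p.min() < 0 or y_p.max() > 1:
        raise ValidationError("probabilities must lie in [0, 1]")
    return float(-(2.0 * (y_p * y_t).sum() + eps) / (y_p.sum() + y_t.sum() + eps))


# ---------------------------------------------------------------------------
# pretraining


@dataclass
class PretrainConfig:
    """Optimization settings for encoder pretraining (defaults mirror the
    supervised protocol; the step budget is config-exposed)."""

    steps: int = 200
    learning_rate: float = 1e-5
    patch_size: int = 30
    fill_value: float = 0.0
    base_channels: int = 64
    batchnorm: bool = True
    seed: int = 0


def _encoder_features(model: SegModel, x: np.ndarray):
    """Flattened deepest (post-pool) encoder activation for a (1,1,H,W) input."""
    skips, pooled = model.encoders[0](ad.constant(x))
    return ad.reshape(pooled, (-1,))


def pretrain_encoder(slices, gt_masks, config: PretrainConfig | None = None):
    """Pretrain one modality's encoder on (slice, mask) pairs.

    ``slices``: iterable of (H, W) normalized single-modality slices;
    ``gt_masks``: matching binary masks (all nonempty).  Builds a
    single-path UNet, runs ``config.steps`` optimization steps (one slice
    per step, cycled in shuffled order), and returns
    ``(encoder_state, history)`` where ``encoder_state`` maps encoder
    parameter names to arrays and ``history`` is a list of
    :class:`SslLossTerms` per step.
    """
    config = config or PretrainConfig()
    slices = [np.asarray(s, dtype=np.float32) for s in slices]
    masks = [np.asarray(m).astype(np.float32) for m in gt_masks]
    if len(slices) != len(masks) or not slices:
        raise ValidationError("need equally many slices and masks, at least one each")
    for i, (s, m) in enumerate(zip(slices, masks)):
        if s.shape != m.shape:
            raise ValidationError(f"slice {i}: image {s.shape} vs mask {m.shape}")
        if not m.any():
            raise ValidationError(f"slice {i}: empty ground-truth mask")

    model_cfg = ModelConfig(
        n_modalities=1, variant="sunet",
        base_channels=config.base_channels, batchnorm=config.batchnorm,
    )
    model = build_model(model_cfg, seed=config.seed)
    model.set_training(True)
    opt = ad.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)

    history: list[SslLossTerms] = []
    order = []
    for step in range(config.steps):
        if not order:
            order = list(rng.permutation(len(slices)))
        i = int(order.pop(0))
        clean, mask = slices[i], masks[i]
        corrupted, _ = apply_boundary_mask(
            clean, mask, config.patch_size, rng, config.fill_value
        )
        x_clean = clean[None, None]
        x_corr = corrupted[None, None]

        prob, pooled = model(x_clean, return_features=True)
        f_vec = ad.reshape(pooled[0], (-1,))
        g_vec = _encoder_features(model, x_corr)
        l_sim = cosine_similarity_loss(f_vec, g_vec)
        l_dice = dice_loss(_take_channel(prob, 1), mask[None])
        loss = ad.add(l_sim, l_dice)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(
            SslLossTerms(l_similarity=float(l_sim.data), l_dice=float(l_dice.data))
        )

    encoder_state = {
        name: t.data.copy()
        for name, t in model.encoders[0].named_parameters("encoders.0.")
    }
    for name, buf in model.encoders[0].named_buffers("encoders.0."):
        encoder_state[name] = np.array(buf)
    return encoder_state, history


def _take_channel(prob, channel: int):
    """(N, H, W) channel plane of an (N, C, H, W) graph tensor (one-hot contraction)."""
    n, c, h, w = prob.shape
    onehot = np.zeros((1, c, 1, 1), dtype=np.float32)
    onehot[0, channel, 0, 0] = 1.0
    return ad.reduce_sum(ad.mul(prob, ad.constant(onehot)), axis=1)


def transfer_weights(pretrained: dict, model: SegModel) -> SegModel:
    """Load per-modality encoder states into a multi-encoder model.

    ``pretrained`` maps modality index (or name-keyed order) to the
    encoder state returned by :func:`pretrain_encoder`.  Decoder and fusion
    weights are untouched.  Every transferred tensor is verified for exact
    numerical equality after copying.
    """
    if model.config.variant == "sunet":
        raise TransferError("cannot transfer per-modality encoders into a sunet")
    states = list(pretrained.values()) if isinstance(pretrained, dict) else list(pretrained)
    if len(states) != model.config.n_modalities:
        raise TransferError(
            f"got {len(states)} encoder states for {model.config.n_modalities} paths"
        )
    for m, state in enumerate(states):
        target = dict(model.encoders[m].named_parameters("encoders.0."))
        for name, buf in model.encoders[m].named_buffers("encoders.0."):
            target[name] = buf
        if set(target) != set(state):
            raise TransferError(
                f"encoder {m}: parameter names differ "
                f"(missing {sorted(set(target) - set(state))[:3]}...)"
            )
        for name, value in state.items():
            dest = target[name]
            arr = np.asarray(value, dtype=np.float32)
            dest_data = dest.data if isinstance(dest, ad.Tensor) else dest
            if dest_data.shape != arr.shape:
                raise TransferError(
                    f"encoder {m}, layer {name}: shape {dest_data.shape} vs {arr.shape}"
                )
            dest_data[...] = arr
            if not np.array_equal(dest_data, arr):
                raise TransferError(f"verification failed for {name}")
    return model
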