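"""Supervised training protocol, segmentation metrics, and model comparison.

Training follows the clinical study protocol: Adam at learning rate 1e-5,
at most 100 epochs, early stopping when the validation loss has not
improved for 10 consecutive epochs, and an 80/20 train/test split drawn at
patient granularity (all slices of a patient land on one side).  The
supervised objective is the soft Dice loss on the foreground probability;
a pixelwise cross-entropy term can be added behind a config flag.

Evaluation is pixelwise binary classification (tumor vs background).  From
the confusion counts:

    Dice        = 2TP / (2TP + FN + FP)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)
    Accuracy    = (TP + TN) / (TP + FP + TN + FN)

plus the symmetric Hausdorff distance between the foreground pixel sets,
at the 100th (classic) or 95th percentile of the directed distances, in mm
via the pixel spacing.  Metrics with empty denominators (e.g. Hausdorff
against an empty mask) are flagged undefined and excluded from aggregation
with a logged count.  ``evaluate`` produces a table with columns
Model / Acc / Dice / Sensitivity / Specificity / Hausdorff95 (mean over
test slices) plus a per-patient breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import autodiff as ad
from .errors import ValidationError
from .networks import SegModel, forward_segment
from .preprocess import load_slice_stack
from .selfsup import dice_loss, _take_channel

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "patient_split",
    "train",
    "confusion_counts",
    "dice_score",
    "sensitivity",
    "specificity",
    "accuracy",
    "hausdorff",
    "evaluate",
]

REPORT_COLUMNS = ["Model", "Acc", "Dice", "Sensitivity", "Specificity", "Hausdorff95"]


@dataclass
class TrainConfig:
    """Supervised training protocol parameters."""

    learning_rate: float = 1e-5
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 4
    split_fraction: float = 0.8
    val_fraction: float = 0.1
    add_cross_entropy: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.split_fraction < 1:
            raise ValidationError("split_fraction must lie in (0, 1)")
        if self.early_stop_patience >= self.max_epochs:
            raise ValidationError("patience must be below max_epochs")


def patient_split(manifest: pd.DataFrame, fraction: float = 0.8, seed: int = 0):
    """Split a manifest into train/test at patient granularity.

    |train patients| = round(fraction * N); the assignment is a seeded
    permutation of the sorted patient ids, so it is deterministic and
    disjoint/exhaustive by construction.
    """
    patients = sorted(manifest["patient"].unique())
    n = len(patients)
    if n < 2:
        raise ValidationError(f"need at least 2 patients to split, got {n}")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    train_ids = {patients[i] for i in order[:n_train]}
    is_train = manifest["patient"].isin(train_ids)
    train_m = manifest[is_train].copy()
    test_m = manifest[~is_train].copy()
    train_m["split"] = "train"
    test_m["split"] = "test"
    return train_m, test_m


# ---------------------------------------------------------------------------
# training


class SliceArrayDataset:
    """In-memory dataset of (stack, mask) pairs grouped by patient."""

    def __init__(self, stacks, masks, patients):
        self.stacks = [np.asarray(s, np.float32) for s in stacks]
        self.masks = [np.asarray(m, np.float32) for m in masks]
        self.patients = list(patients)
        if not (len(self.stacks) == len(self.masks) == len(self.patients)):
            raise ValidationError("stacks/masks/patients length mismatch")
        if not self.stacks:
            raise ValidationError("empty dataset")

    @classmethod
    def from_manifest(cls, dataset_dir, manifest: pd.DataFrame):
        stacks, masks, patients = [], [], []
        for _, row in manifest.iterrows():
            stack, mask = load_slice_stack(dataset_dir, row)
            stacks.append(stack)
            masks.append(mask)
            patients.append(row["patient"])
        return cls(stacks, masks, patients)

    def __len__(self):
        return len(self.stacks)


def _batch_loss(model: SegModel, stacks, masks, config: TrainConfig):
    x = np.stack(stacks)
    y = np.stack(masks)
    prob = model(x)
    fg = _take_channel(prob, 1)
    loss = dice_loss(fg, y)
    if config.add_cross_entropy:
        eps = ad.constant(np.float32(1e-7))
        target = ad.constant(np.stack([1.0 - y, y], axis=1).astype(np.float32))
        log_p = _log(ad.add(prob, eps))
        ce = ad.neg(ad.reduce_mean(ad.reduce_sum(ad.mul(target, log_p), axis=1)))
        loss = ad.add(loss, ce)
    return loss


def _log(t):
    # log(x) built from exp's inverse is unavailable; use data-level log with
    # analytic gradient 1/x.
    out = ad.Tensor(np.log(t.data), parents=(t,), backward=None)

    def bwd(g):
        ad._accumulate(t, g / t.data)

    out._backward = bwd
    return out


def _mean_val_loss(model: SegModel, dataset, indices, config):
    model.set_training(False)
    losses = []
    for i in indices:
        prob = model(dataset.stacks[i][None])
        fg = _take_channel(prob, 1)
        losses.append(float(dice_loss(fg, dataset.masks[i][None]).data))
    model.set_training(True)
    return float(np.mean(losses))


def train(model: SegModel, dataset: SliceArrayDataset, config: TrainConfig | None = None,
          max_steps_per_epoch: int | None = None):
    """Train a model with Adam + Dice loss and patient-level early stopping.

    A fraction of the training patients (``val_fraction``, at least one
    patient) is held out for validation; training stops at ``max_epochs``
    or when the validation loss has not improved for
    ``early_stop_patience`` consecutive epochs.  Returns
    ``(best_state, history)`` where ``best_state`` is the state dict at the
    best validation loss and ``history`` is a per-epoch DataFrame.
    The model is left holding the best weights.
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    patients = sorted(set(dataset.patients))
    if len(patients) >= 2:
        n_val = max(int(round(config.val_fraction * len(patients))), 1)
        order = rng.permutation(len(patients))
        val_patients = {patients[i] for i in order[:n_val]}
    else:
        val_patients = set()
    train_idx = [i for i, p in enumerate(dataset.patients) if p not in val_patients]
    val_idx = [i for i, p in enumerate(dataset.patients) if p in val_patients]
    if not train_idx:
        raise ValidationError("empty training set after validation carve-out")
    if not val_idx:
        val_idx = train_idx  # degenerate single-patient case

    model.set_training(True)
    opt = ad.Adam(model.parameters(), lr=config.learning_rate)
    best_loss = np.inf
    best_state = model.state_dict()
    since_improve = 0
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        n_steps = 0
        for start in range(0, len(order), config.batch_size):
            batch = [train_idx[j] for j in order[start : start + config.batch_size]]
            loss = _batch_loss(
                model,
                [dataset.stacks[i] for i in batch],
                [dataset.masks[i] for i in batch],
                config,
            )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            n_steps += 1
            if max_steps_per_epoch and n_steps >= max_steps_per_epoch:
                break
        val_loss = _mean_val_loss(model, dataset, val_idx, config)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
             "val_loss": val_loss}
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.early_stop_patience:
                break
    model.load_state_dict(best_state)
    return best_state, pd.DataFrame.from_records(history)


def run_early_stopping(val_losses, patience: int, max_epochs: int) -> int:
    """Number of epochs the protocol would run for a given val-loss sequence.

    Pure helper for auditing the early-stop rule: consumes losses in order,
    stops after ``patience`` consecutive non-improvements or at
    ``max_epochs``, and returns the number of epochs consumed.
    """
    best = np.inf
    since = 0
    for epoch, loss in enumerate(val_losses):
        if epoch >= max_epochs:
            return max_epochs
        if loss < best:
            best = loss
            since = 0
        else:
            since += 1
            if since >= patience:
                return epoch + 1
    return min(len(val_losses), max_epochs)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Pixelwise TP/FP/TN/FN tallies for binary masks of equal shape."""
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {gt.shape}")
    for name, arr in (("pred", pred), ("gt", gt)):
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError(f"{name} mask is not binary (values {vals[:5]})")
    p = pred.astype(bool)
    g = gt.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & g)),
        fp=int(np.count_nonzero(p & ~g)),
        tn=int(np.count_nonzero(~p & ~g)),
        fn=int(np.count_nonzero(~p & g)),
    )


def _ratio(num, den):
    return float(num) / float(den) if den > 0 else None


def dice_score(c: ConfusionCounts):
    """Dice = 2TP/(2TP+FN+FP); None when the denominator is zero."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp)


def sensitivity(c: ConfusionCounts):
    """Sensitivity (recall) = TP/(TP+FN)."""
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts):
    """Specificity = TN/(TN+FP)."""
    return _ratio(c.tn, c.tn + c.fp)


def accuracy(c: ConfusionCounts):
    """Pixel accuracy = (TP+TN)/total."""
    return _ratio(c.tp + c.tn, c.total)


def hausdorff(pred, gt, percentile: float = 95, pixel_spacing=(1.0, 1.0)):
    """Symmetric (percentile) Hausdorff distance between foreground pixel sets.

    The directed distance d(A, B) at percentile p is the p-th percentile
    over a in A of min_b ||a - b||_2, with coordinates scaled by
    ``pixel_spacing`` (mm).  Returns max(d(pred, gt), d(gt, pred)), or
    None (undefined) when either mask is empty.  percentile=100 is the
    classic Hausdorff distance.
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch {pred.shape} vs {gt.shape}")
    if not pred.any() or not gt.any():
        return None
    d_pg = _directed_percentile(pred, gt, percentile, pixel_spacing)
    d_gp = _directed_percentile(gt, pred, percentile, pixel_spacing)
    return float(max(d_pg, d_gp))


def _directed_percentile(a, b, percentile, spacing):
    # Exact Euclidean distance-to-B sampled at the pixels of A.
    dist_to_b = ndimage.distance_transform_edt(~b, sampling=spacing)
    return float(np.percentile(dist_to_b[a], percentile))


# ---------------------------------------------------------------------------
# model comparison


def _slice_metrics(pred, gt, spacing):
    c = confusion_counts(pred, gt)
    return {
        "Acc": accuracy(c),
        "Dice": dice_score(c),
        "Sensitivity": sensitivity(c),
        "Specificity": specificity(c),
        "Hausdorff95": hausdorff(pred, gt, 95, spacing),
    }


@dataclass
class MetricsReport:
    """Aggregated comparison table plus per-patient breakdown.

    ``table`` has one row per model with the slice-mean of each metric;
    ``per_patient`` holds patient-level means; ``undefined_counts`` logs how
    many slices were excluded per (model, metric)."""

    table: pd.DataFrame
    per_patient: pd.DataFrame
    undefined_counts: pd.DataFrame
    aggregation: str = "mean over test slices with defined values"


def evaluate(models: dict, dataset: SliceArrayDataset,
             pixel_spacing=(1.0, 1.0)) -> MetricsReport:
    """Compare trained models on a test dataset.

    ``models`` maps a display name (e.g. SUNet / MUNet / Ours) to a
    :class:`SegModel`; rows appear in dict order.
    """
    metric_names = REPORT_COLUMNS[1:]
    rows = []
    per_patient_rows = []
    undef_rows = []
    for name, model in models.items():
        if model.config.n_modalities != dataset.stacks[0].shape[0]:
            raise ValidationError(
                f"model {name} expects {model.config.n_modalities} modalities, "
                f"dataset has {dataset.stacks[0].shape[0]}"
            )
        per_slice = []
        for stack, mask in zip(dataset.stacks, dataset.masks):
            _, pred = forward_segment(model, stack)
            per_slice.append(_slice_metrics(pred, mask.astype(np.uint8), pixel_spacing))
        frame = pd.DataFrame.from_records(per_slice)
        frame["patient"] = dataset.patients
        agg = {m: frame[m].dropna().mean() for m in metric_names}
        rows.append({"Model": name, **agg})
        undef_rows.append(
            {"Model": name, **{m: int(frame[m].isna().sum()) for m in metric_names}}
        )
        pp = frame.groupby("patient")[metric_names].mean().reset_index()
        pp.insert(0, "Model", name)
        per_patient_rows.append(pp)
    table = pd.DataFrame.from_records(rows, columns=REPORT_COLUMNS)
    return MetricsReport(
        table=table,
        per_patient=pd.concat(per_patient_rows, ignore_index=True),
        undefined_counts=pd.DataFrame.from_records(undef_rows),
    )
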