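"""Slice-level preprocessing and dataset assembly.

The pipeline turns raw per-patient modality volumes plus rectangular tumor
annotations into aligned training stacks, in the fixed order

    resample -> normalize -> central slices -> crop

Per-slice intensities are normalized with a trimmed max-min rule: the 5th
and 95th percentile of the slice define S_min and S_max, and

    S' = clip((S - S_min) / (S_max - S_min), 0, 1)

so the darkest/brightest 5% of pixels are saturated rather than allowed to
stretch the scale.  Tumor annotations are axis-aligned rectangles shared by
all modalities of a scan plane; the ground-truth mask is the filled
rectangle.  Each retained slice is cropped to a fixed window centered on
the box (translated the minimum distance needed to stay inside the image),
and the central ``n_slices`` scan planes of each sequence are kept so the
three modalities of a patient stay aligned plane by plane.

Box coordinate dialect (recorded in the manifest sidecar): 0-based,
half-open, x = column and y = row, on the resampled plane.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import AnnotationError, DegenerateInputError, InsufficientSlicesError, ValidationError
from .imaging_io import VolumeGrid, resample_volume
from .networks import MODALITIES

__all__ = [
    "BoxAnnotation",
    "NormalizationRecord",
    "DatasetParams",
    "PatientInput",
    "trimmed_minmax_normalize",
    "box_to_mask",
    "crop_around_box",
    "central_slices",
    "boxes_from_mask_slice",
    "load_box_csv",
    "build_dataset",
    "load_manifest",
    "save_manifest",
]

TRIM_PERCENT = 5.0  # trimmed tail mass per side, percent


@dataclass(frozen=True)
class BoxAnnotation:
    """Axis-aligned rectangle [x_min, x_max) x [y_min, y_max), 0-based pixels."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int
    applies_to: str = ""

    def __post_init__(self):
        if not (0 <= self.x_min < self.x_max and 0 <= self.y_min < self.y_max):
            raise ValidationError(f"degenerate box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def shifted(self, dx: int, dy: int) -> "BoxAnnotation":
        return BoxAnnotation(
            self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy,
            self.applies_to,
        )

    def check_inside(self, shape) -> None:
        rows, cols = shape
        if self.x_max > cols or self.y_max > rows:
            raise ValidationError(
                f"box {self} exceeds image shape {rows}x{cols}"
            )


@dataclass(frozen=True)
class NormalizationRecord:
    """The trimmed intensity range used to normalize one slice."""

    s_min: float
    s_max: float

    def __post_init__(self):
        if self.s_min > self.s_max:
            raise ValidationError("s_min must not exceed s_max")


def trimmed_minmax_normalize(slice_2d) -> tuple[np.ndarray, NormalizationRecord]:
    """Normalize one slice to [0, 1] using the 5th-95th percentile range.

    Percentiles use numpy's linear-interpolation convention.  Values below
    S_min / above S_max clip to 0 / 1.  A constant slice has no usable
    range and raises :class:`DegenerateInputError`.
    """
    s = np.asarray(slice_2d, dtype=np.float64)
    if s.ndim != 2:
        raise ValidationError(f"expected a 2D slice, got shape {s.shape}")
    if not np.isfinite(s).all():
        raise ValidationError("slice contains non-finite values")
    s_min = float(np.percentile(s, TRIM_PERCENT))
    s_max = float(np.percentile(s, 100.0 - TRIM_PERCENT))
    if s_max == s_min:
        raise DegenerateInputError(
            "slice trimmed intensity range is empty (constant slice?)"
        )
    out = np.clip((s - s_min) / (s_max - s_min), 0.0, 1.0)
    return out, NormalizationRecord(s_min=s_min, s_max=s_max)


def box_to_mask(box: BoxAnnotation, shape) -> np.ndarray:
    """Binary mask that is 1 exactly on the box rectangle."""
    box.check_inside(shape)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[box.y_min : box.y_max, box.x_min : box.x_max] = 1
    return mask


def crop_around_box(
    image, box: BoxAnnotation, crop: int = 256, context: str = ""
) -> tuple[np.ndarray, BoxAnnotation]:
    """Extract a crop x crop window containing the whole box.

    The window is centered on the box center and translated the minimum
    distance needed to lie fully inside the image; the returned box is
    re-expressed in crop-local coordinates.
    """
    image = np.asarray(image)
    rows, cols = image.shape
    where = f" ({context})" if context else ""
    if box.width > crop or box.height > crop:
        raise AnnotationError(
            f"box {box.width}x{box.height} does not fit in a {crop}x{crop} crop{where}"
        )
    if rows < crop or cols < crop:
        raise ValidationError(f"image {rows}x{cols} smaller than crop {crop}{where}")
    box.check_inside(image.shape)
    y0 = (box.y_min + box.y_max - crop) // 2
    x0 = (box.x_min + box.x_max - crop) // 2
    y0 = min(max(y0, 0), rows - crop)
    x0 = min(max(x0, 0), cols - crop)
    return image[y0 : y0 + crop, x0 : x0 + crop], box.shifted(-x0, -y0)


def central_slices(volume, n: int = 64) -> np.ndarray:
    """Return the n central slices [floor((L-n)/2), floor((L-n)/2)+n)."""
    volume = np.asarray(volume)
    length = volume.shape[0]
    if length < n:
        raise InsufficientSlicesError(
            f"volume has {length} slices, need at least {n}"
        )
    start = (length - n) // 2
    return volume[start : start + n]


def central_slice_range(length: int, n: int) -> tuple[int, int]:
    if length < n:
        raise InsufficientSlicesError(f"volume has {length} slices, need at least {n}")
    start = (length - n) // 2
    return start, start + n


def boxes_from_mask_slice(mask_2d, applies_to: str = "") -> BoxAnnotation | None:
    """Tight bounding rectangle of a binary mask slice (None if empty)."""
    ys, xs = np.nonzero(np.asarray(mask_2d))
    if ys.size == 0:
        return None
    return BoxAnnotation(
        x_min=int(xs.min()), y_min=int(ys.min()),
        x_max=int(xs.max()) + 1, y_max=int(ys.max()) + 1,
        applies_to=applies_to,
    )


def load_box_csv(path) -> dict:
    """Read clinician box annotations from CSV.

    Expected columns: patient, slice, x_min, y_min, x_max, y_max, with
    coordinates on the resampled plane.  Returns
    {patient_id: {slice_index: BoxAnnotation}} for use as
    :attr:`PatientInput.boxes`.
    """
    table = pd.read_csv(path)
    required = {"patient", "slice", "x_min", "y_min", "x_max", "y_max"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"box CSV missing columns: {sorted(missing)}")
    boxes: dict = {}
    for _, row in table.iterrows():
        boxes.setdefault(str(row["patient"]), {})[int(row["slice"])] = BoxAnnotation(
            int(row["x_min"]), int(row["y_min"]), int(row["x_max"]), int(row["y_max"]),
            applies_to=f"{row['patient']}/slice{int(row['slice'])}",
        )
    return boxes


# ---------------------------------------------------------------------------
# dataset assembly


@dataclass
class DatasetParams:
    """Geometry of the standardized dataset.

    Defaults match the clinical protocol (1 mm grid, 512 x 512 plane,
    256 x 256 crops, 64 central slices); smaller values are used for
    fast synthetic runs.
    """

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    plane_size: tuple[int, int] = (512, 512)
    crop: int = 256
    n_slices: int = 64
    orientation: str = "COR"

    def to_json(self) -> dict:
        d = asdict(self)
        d["box_dialect"] = "0-based, half-open, x=col, y=row, resampled plane"
        d["modalities"] = list(MODALITIES)
        return d


@dataclass
class PatientInput:
    """Raw input for one patient: three modality volumes + tumor annotation.

    ``mask`` is a ground-truth tumor mask volume on the same raw grid as
    the modality volumes; per-slice boxes on the resampled grid are derived
    from it.  Alternatively ``boxes`` may carry explicit per-resampled-slice
    annotations (index -> BoxAnnotation), as produced by clinician marking.
    """

    patient_id: str
    volumes: dict
    mask: VolumeGrid | None = None
    boxes: dict | None = None

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.volumes]
        if missing:
            raise ValidationError(
                f"patient {self.patient_id} is missing modalities: {missing}"
            )
        if self.mask is None and self.boxes is None:
            raise ValidationError(
                f"patient {self.patient_id} has neither a mask volume nor boxes"
            )


def _resampled_boxes(patient: PatientInput, params: DatasetParams) -> dict:
    """Per-slice boxes on the resampled grid, from explicit boxes or the mask."""
    if patient.boxes is not None:
        return dict(patient.boxes)
    mask_rs = resample_volume(
        patient.mask, params.target_spacing, params.plane_size, interp="nearest"
    )
    boxes = {}
    for idx in range(mask_rs.shape[0]):
        box = boxes_from_mask_slice(
            mask_rs.data[idx], applies_to=f"{patient.patient_id}/slice{idx}"
        )
        if box is not None:
            boxes[idx] = box
    return boxes


def build_dataset(patients, out_dir, params: DatasetParams | None = None,
                  strict: bool = True) -> pd.DataFrame:
    """Run the full preprocessing pipeline and write per-slice arrays.

    For each patient: resample the three modality volumes to the target
    grid, normalize every retained slice, select the central ``n_slices``
    planes, crop each plane around its tumor box (image-centered when the
    tumor has no cross-section on that plane) and write one ``.npy`` file
    per modality slice plus the ground-truth mask (the filled box
    rectangle).  Returns the manifest; also writes ``manifest.csv`` and a
    ``params.json`` sidecar into ``out_dir``.

    With ``strict`` (default) any per-patient failure aborts; otherwise the
    offending patient is skipped with a warning entry in the sidecar.
    """
    params = params or DatasetParams()
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    records = []
    skipped = []
    for patient in patients:
        try:
            records.extend(_process_patient(patient, out_dir, params))
        except Exception as exc:  # noqa: BLE001 - context added, re-raised if strict
            if strict:
                raise type(exc)(f"patient {patient.patient_id}: {exc}") from exc
            skipped.append({"patient": patient.patient_id, "error": str(exc)})
    manifest = pd.DataFrame.from_records(records)
    save_manifest(manifest, out_dir, params, skipped=skipped)
    return manifest


def _process_patient(patient: PatientInput, out_dir: str, params: DatasetParams):
    pid = patient.patient_id
    boxes = _resampled_boxes(patient, params)
    resampled = {
        mod: resample_volume(
            patient.volumes[mod], params.target_spacing, params.plane_size, "linear"
        )
        for mod in MODALITIES
    }
    lengths = {mod: v.shape[0] for mod, v in resampled.items()}
    if len(set(lengths.values())) != 1:
        raise ValidationError(f"modalities disagree on slice count: {lengths}")
    length = next(iter(lengths.values()))
    lo, hi = central_slice_range(length, params.n_slices)

    pdir = os.path.join(out_dir, pid)
    os.makedirs(pdir, exist_ok=True)
    rows = []
    for idx in range(lo, hi):
        box = boxes.get(idx)
        row = {"patient": pid, "slice_index": idx, "split": "unassigned"}
        crop_origin = None
        for mod in MODALITIES:
            plane = resampled[mod].data[idx]
            norm, rec = trimmed_minmax_normalize(plane)
            if box is not None:
                cropped, local_box = crop_around_box(
                    norm, box, params.crop, context=f"{pid}/slice{idx}/{mod}"
                )
            else:
                cropped, local_box = _center_crop(norm, params.crop), None
            path = os.path.join(pdir, f"{mod}_{idx:04d}.npy")
            np.save(path, cropped.astype(np.float32))
            row[f"path_{mod}"] = os.path.relpath(path, out_dir)
            row[f"smin_{mod}"] = rec.s_min
            row[f"smax_{mod}"] = rec.s_max
            if crop_origin is None:
                crop_origin = local_box
        if crop_origin is not None:
            gt = box_to_mask(crop_origin, (params.crop, params.crop))
            row.update(
                x_min=crop_origin.x_min, y_min=crop_origin.y_min,
                x_max=crop_origin.x_max, y_max=crop_origin.y_max,
            )
        else:
            gt = np.zeros((params.crop, params.crop), dtype=np.uint8)
            row.update(x_min=-1, y_min=-1, x_max=-1, y_max=-1)
        mask_path = os.path.join(pdir, f"mask_{idx:04d}.npy")
        np.save(mask_path, gt)
        row["path_mask"] = os.path.relpath(mask_path, out_dir)
        rows.append(row)
    return rows


def _center_crop(image: np.ndarray, crop: int) -> np.ndarray:
    rows, cols = image.shape
    y0 = (rows - crop) // 2
    x0 = (cols - crop) // 2
    return image[y0 : y0 + crop, x0 : x0 + crop]


def save_manifest(manifest: pd.DataFrame, out_dir, params: DatasetParams,
                  skipped=None) -> None:
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    sidecar = {"params": params.to_json(), "skipped": skipped or []}
    with open(os.path.join(out_dir, "params.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_manifest(dataset_dir) -> tuple[pd.DataFrame, dict]:
    dataset_dir = os.fspath(dataset_dir)
    manifest = pd.read_csv(os.path.join(dataset_dir, "manifest.csv"))
    with open(os.path.join(dataset_dir, "params.json")) as fh:
        sidecar = json.load(fh)
    return manifest, sidecar


def load_slice_stack(dataset_dir, row) -> tuple[np.ndarray, np.ndarray]:
    """Load one manifest row as ((M, H, W) float32 stack, (H, W) uint8 mask)."""
    stack = np.stack(
        [np.load(os.path.join(dataset_dir, row[f"path_{mod}"])) for mod in MODALITIES]
    ).astype(np.float32)
    mask = np.load(os.path.join(dataset_dir, row["path_mask"])).astype(np.uint8)
    return stack, mask
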