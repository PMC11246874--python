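"""Seeded synthetic multi-modal thigh MRI cohorts with exact ground truth.

Each subject is a cylindrical "thigh" (muscle) containing a small cortical
"bone" cylinder and a single ellipsoidal tumor, rendered into three
co-registered modality volumes with anisotropic voxel spacing.  Modality
contrast follows the clinical appearance of soft-tissue sarcoma: the tumor
is hypointense relative to muscle on the T1-weighted volume and
hyperintense on the T2-weighted and STIR volumes; cortical bone is dark on
all three.  Gaussian noise with a per-modality standard deviation is added
on top.

Geometry is analytic: the tumor voxel mask is exactly the set of voxel
centers inside the ellipsoid, so per-slice bounding boxes and masks are
exact by construction and noise never perturbs them.  Everything is
deterministic given the master seed; per-subject seeds are derived from it
with a seed sequence and recorded in the cohort manifest.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .imaging_io import VolumeGrid, read_volume, write_volume
from .networks import MODALITIES
from .preprocess import PatientInput, boxes_from_mask_slice

__all__ = [
    "ModalityContrast",
    "PhantomParams",
    "generate_subject",
    "generate_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class ModalityContrast:
    """Mean tissue intensities (arbitrary units) and noise level for one modality."""

    background: float
    muscle: float
    tumor: float
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def default_contrast() -> dict:
    """Clinical-appearance defaults: tumor dark on T1WI, bright on T2WI/STIR."""
    return {
        "T1WI": ModalityContrast(background=5.0, muscle=100.0, tumor=55.0, noise_sd=5.0),
        "T2WI": ModalityContrast(background=5.0, muscle=80.0, tumor=150.0, noise_sd=5.0),
        "STIR": ModalityContrast(background=5.0, muscle=60.0, tumor=165.0, noise_sd=5.0),
    }


@dataclass
class PhantomParams:
    """Cohort-level generation parameters.

    The defaults emulate the study conditions: 45 subjects, three modality
    volumes per subject, a strongly anisotropic raw grid (9 mm slice gap vs
    1.5 mm in-plane) and a single large thigh tumor per subject.
    ``tumor_radius_range`` bounds the ellipsoid semi-axes in mm.
    """

    n_subjects: int = 45
    volume_shape: tuple[int, int, int] = (20, 256, 256)
    spacing: tuple[float, float, float] = (9.0, 1.5, 1.5)
    tumor_radius_range: tuple[float, float] = (15.0, 45.0)
    contrast: dict = field(default_factory=default_contrast)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValidationError("n_subjects must be >= 0")
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("spacing must be positive")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValidationError("tumor_radius_range must satisfy 0 < lo <= hi")
        missing = [m for m in MODALITIES if m not in self.contrast]
        if missing:
            raise ValidationError(f"contrast table missing modalities: {missing}")
        t1 = self.contrast["T1WI"]
        if not t1.tumor < t1.muscle:
            raise ValidationError(
                "T1WI tumor mean must be below muscle mean (tumor is hypointense on T1)"
            )
        for mod in ("T2WI", "STIR"):
            c = self.contrast[mod]
            if not c.tumor > c.muscle:
                raise ValidationError(
                    f"{mod} tumor mean must exceed muscle mean (tumor is hyperintense)"
                )


def _physical_axes(shape, spacing):
    return [np.arange(n) * s for n, s in zip(shape, spacing)]


def generate_subject(params: PhantomParams, subject_seed: int):
    """Render one subject.

    Returns ``(volumes, boxes, masks)``: a modality -> VolumeGrid dict, a
    slice-index -> BoxAnnotation dict (tight bounding rectangles of the
    tumor cross-sections; slices without tumor carry no box), and the
    binary tumor mask volume as a (slices, rows, cols) uint8 array.
    """
    rng = np.random.default_rng(subject_seed)
    S, R, C = params.volume_shape
    sz, sy, sx = params.spacing
    z, y, x = np.meshgrid(*_physical_axes(params.volume_shape, params.spacing),
                          indexing="ij", sparse=True)
    cy, cx = (R - 1) * sy / 2.0, (C - 1) * sx / 2.0
    extent_y, extent_x = (R - 1) * sy, (C - 1) * sx

    thigh_r = 0.44 * min(extent_y, extent_x)
    r2_plane = (y - cy) ** 2 + (x - cx) ** 2
    thigh = np.broadcast_to(r2_plane <= thigh_r**2, (S, R, C))

    bone_r = 0.12 * thigh_r
    bone_cy, bone_cx = cy + 0.45 * thigh_r, cx
    bone = np.broadcast_to(
        (y - bone_cy) ** 2 + (x - bone_cx) ** 2 <= bone_r**2, (S, R, C)
    )

    # Tumor: ellipsoid fully inside the muscle ring, avoiding the bone,
    # with its center constrained to the central third of the slice axis.
    lo, hi = params.tumor_radius_range
    extent_z = (S - 1) * sz
    for _ in range(200):
        semi = rng.uniform(lo, hi, size=3)
        semi[1:] = np.minimum(semi[1:], 0.6 * thigh_r)
        tz = rng.uniform(extent_z / 3.0, 2.0 * extent_z / 3.0)
        # uniform direction/offset inside the allowed in-plane disc
        max_off = thigh_r - max(semi[1], semi[2]) - 2.0
        if max_off <= 0:
            continue
        ang = rng.uniform(0, 2 * np.pi)
        rad = max_off * np.sqrt(rng.uniform())
        ty, tx = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
        d_bone = np.hypot(ty - bone_cy, tx - bone_cx)
        if d_bone < bone_r + max(semi[1], semi[2]) + 2.0:
            continue
        break
    else:
        raise ValidationError("could not place a tumor satisfying the constraints")

    tumor = (
        ((z - tz) / semi[0]) ** 2
        + ((y - ty) / semi[1]) ** 2
        + ((x - tx) / semi[2]) ** 2
    ) <= 1.0
    tumor &= thigh
    mask = tumor.astype(np.uint8)

    volumes = {}
    for mod in MODALITIES:
        c = params.contrast[mod]
        vol = np.full((S, R, C), c.background, dtype=np.float64)
        vol[thigh & ~bone] = c.muscle
        vol[bone & thigh] = c.background
        vol[tumor] = c.tumor
        if c.noise_sd > 0:
            vol += rng.normal(0.0, c.noise_sd, size=vol.shape)
        volumes[mod] = VolumeGrid(
            vol, params.spacing, origin_note=f"phantom seed={subject_seed} {mod}"
        )

    boxes = {}
    for idx in range(S):
        box = boxes_from_mask_slice(mask[idx], applies_to=f"slice{idx}")
        if box is not None:
            boxes[idx] = box
    return volumes, boxes, mask


def generate_cohort(params: PhantomParams, out_dir) -> pd.DataFrame:
    """Write ``n_subjects`` independent subjects to disk.

    Each subject directory holds the three modality volumes plus the
    ground-truth tumor mask volume as NIfTI, and a ``boxes.csv`` with the
    per-raw-slice bounding rectangles.  Returns the cohort manifest (also
    written as ``cohort.csv``) with one row per subject including the
    derived per-subject seed.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    seeds = np.random.SeedSequence(params.seed).generate_state(max(params.n_subjects, 1))
    for i in range(params.n_subjects):
        subject_seed = int(seeds[i] % (2**31 - 1))
        sid = f"subject{i:03d}"
        sdir = os.path.join(out_dir, sid)
        os.makedirs(sdir, exist_ok=True)
        volumes, boxes, mask = generate_subject(params, subject_seed)
        for mod, vol in volumes.items():
            write_volume(vol, os.path.join(sdir, f"{mod}.nii.gz"))
        write_volume(
            VolumeGrid(mask, params.spacing, origin_note="phantom mask"),
            os.path.join(sdir, "mask.nii.gz"),
        )
        box_rows = [
            {"patient": sid, "slice": idx, "x_min": b.x_min, "y_min": b.y_min,
             "x_max": b.x_max, "y_max": b.y_max}
            for idx, b in sorted(boxes.items())
        ]
        pd.DataFrame.from_records(
            box_rows, columns=["patient", "slice", "x_min", "y_min", "x_max", "y_max"]
        ).to_csv(os.path.join(sdir, "boxes.csv"), index=False)
        rows.append({"patient": sid, "seed": subject_seed, "dir": sid,
                     "n_tumor_slices": len(boxes)})
    manifest = pd.DataFrame.from_records(
        rows, columns=["patient", "seed", "dir", "n_tumor_slices"]
    )
    manifest.to_csv(os.path.join(out_dir, "cohort.csv"), index=False)
    with open(os.path.join(out_dir, "phantom_params.json"), "w") as fh:
        json.dump(
            {
                "n_subjects": params.n_subjects,
                "volume_shape": list(params.volume_shape),
                "spacing": list(params.spacing),
                "tumor_radius_range": list(params.tumor_radius_range),
                "contrast": {m: asdict(c) for m, c in params.contrast.items()},
                "seed": params.seed,
            },
            fh,
            indent=2,
        )
    return manifest


def load_cohort(cohort_dir):
    """Yield :class:`PatientInput` objects for a cohort written to disk.

    Volumes are loaded lazily, one patient at a time, so arbitrarily large
    cohorts can be streamed into ``preprocess.build_dataset``.
    """
    cohort_dir = os.fspath(cohort_dir)
    manifest = pd.read_csv(os.path.join(cohort_dir, "cohort.csv"))
    for _, row in manifest.iterrows():
        sdir = os.path.join(cohort_dir, row["dir"])
        volumes = {
            mod: read_volume(os.path.join(sdir, f"{mod}.nii.gz")) for mod in MODALITIES
        }
        mask = read_volume(os.path.join(sdir, "mask.nii.gz"))
        yield PatientInput(patient_id=row["patient"], volumes=volumes, mask=mask)
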