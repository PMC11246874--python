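"""Shared fixtures: a small deterministic phantom cohort and dataset.

All fixtures are generated programmatically at session scope so the heavy
pipeline stages (cohort rendering, resampling) run once per test session.
The reduced geometry — 12 raw slices at 6 mm gap, 96 x 96 plane at 2 mm,
resampled to a (1, 2, 2) mm grid with 96 x 96 crops and 64 central
slices — exercises every pipeline stage at a size where tests stay fast.
"""

import numpy as np
import pandas as pd
import pytest

from sarcoseg import phantom as ph
from sarcoseg import preprocess as pp
from sarcoseg.train_eval import SliceArrayDataset

SMALL_SHAPE = (12, 96, 96)
SMALL_SPACING = (6.0, 2.0, 2.0)
SMALL_DATASET = pp.DatasetParams(
    target_spacing=(1.0, 2.0, 2.0), plane_size=(96, 96), crop=96, n_slices=64
)


def small_phantom_params(n_subjects=3, seed=7, noise_sd=None):
    contrast = ph.default_contrast()
    if noise_sd is not None:
        contrast = {
            m: ph.ModalityContrast(c.background, c.muscle, c.tumor, noise_sd)
            for m, c in contrast.items()
        }
    return ph.PhantomParams(
        n_subjects=n_subjects,
        volume_shape=SMALL_SHAPE,
        spacing=SMALL_SPACING,
        tumor_radius_range=(10.0, 18.0),
        contrast=contrast,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    ph.generate_cohort(small_phantom_params(), out)
    return out


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, cohort_dir):
    out = tmp_path_factory.mktemp("dataset")
    pp.build_dataset(ph.load_cohort(cohort_dir), out, SMALL_DATASET)
    return out


@pytest.fixture(scope="session")
def dataset_manifest(dataset_dir) -> pd.DataFrame:
    manifest, _ = pp.load_manifest(dataset_dir)
    return manifest


@pytest.fixture(scope="session")
def tumor_slices(dataset_dir, dataset_manifest) -> SliceArrayDataset:
    """Eight tumor-bearing slices spread across the cohort.

    Slices are drawn from the planes where the tumor has a substantial
    cross-section (box area >= 36 px), mirroring the clinically marked
    planes; grazing cross-sections of one or two pixels are not
    representative annotation targets.
    """
    rows = dataset_manifest[dataset_manifest["x_min"] >= 0]
    area = (rows["x_max"] - rows["x_min"]) * (rows["y_max"] - rows["y_min"])
    rows = rows[area >= 36]
    sel = rows.iloc[np.linspace(0, len(rows) - 1, 8).astype(int)]
    return SliceArrayDataset.from_manifest(dataset_dir, sel)
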