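"""Shared fixtures.

The staging benchmark dataset (~1000 nucleus crops from 100 synthetic
fields, 5 differentiation stages) is expensive to build, so it is
session-scoped and shared between the model tests and the acceptance
checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from mscstage.segment import FieldImage, segment_dataset
from mscstage.splits import make_splits
from mscstage.synthetic import StageParams, generate_stage_dataset


@pytest.fixture(scope="session")
def staging_dataset():
    """(crops, split) for the synthetic staging benchmark: 5 stages x 20
    fields x 10 nuclei, one field-grouped 75/25 division."""
    fields, truth = generate_stage_dataset(
        n_fields_per_stage=20, base_params=StageParams(n_nuclei=10), seed=101
    )
    crops = segment_dataset(fields)
    split = make_splits(crops, n_splits=1, test_fraction=0.25, seed=101)[0]
    return crops, split


@pytest.fixture(scope="session")
def small_field_dataset():
    """5 small default fields with ground truth, for segmentation recall."""
    fields, truth = generate_stage_dataset(
        n_fields_per_stage=1,
        base_params=StageParams(n_nuclei=6, field_shape=(512, 512)),
        seed=11,
    )
    return fields, truth


def make_disk_field(centers, radii, shape=(800, 800), value=30000) -> FieldImage:
    """Hand-built field of filled circles at given centers/radii."""
    canvas = np.zeros(shape, dtype=np.uint16)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (r, c), rad in zip(centers, radii):
        canvas[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = value
    return FieldImage(field_id="manual", timepoint_h=0.0, channels={"nucleus": canvas})
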