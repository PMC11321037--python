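"""Right-angle rotation augmentation and field-grouped train/test splits.

Crops from one microscope field are highly correlated (shared
illumination, focus, staining batch), so train/test partitioning happens
at the field level and every augmented copy stays in the same fold as
its source crop. This leakage guard is the module's reason to exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .segment import NucleusCrop


@dataclass
class AugmentedCrop:
    """A crop plus its rotation tag (0, 90, 180, 270 degrees CCW)."""

    crop: NucleusCrop
    rotation_deg: int
    source_crop_id: str

    @property
    def is_original(self) -> bool:
        return self.rotation_deg == 0


def _pad_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape
    if h == w:
        return arr
    side = max(h, w)
    out = np.zeros((side, side), dtype=arr.dtype)
    r0 = (side - h) // 2
    c0 = (side - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = arr
    return out


def augment_rotations(crop: NucleusCrop) -> list[AugmentedCrop]:
    """Original plus 90/180/270-degree rotated copies (exactly 4 outputs).

    Non-square frames are zero-padded to square first, so right-angle
    rotation is a pure pixel permutation (bit-exact, no resampling).
    """
    h, w = crop.frame_size
    side = max(h, w)
    out = []
    for k, deg in enumerate((0, 90, 180, 270)):
        channels = {
            name: np.rot90(_pad_square(arr), k=k).copy() for name, arr in crop.channels.items()
        }
        out.append(
            AugmentedCrop(
                crop=NucleusCrop(
                    field_id=crop.field_id,
                    label=crop.label,
                    timepoint_h=crop.timepoint_h,
                    channels=channels,
                    frame_size=(side, side),
                    centroid=crop.centroid,
                ),
                rotation_deg=deg,
                source_crop_id=crop.crop_id,
            )
        )
    return out


def augment_dataset(crops: Sequence[NucleusCrop]) -> list[AugmentedCrop]:
    """4x expansion of a crop list; order groups copies with their source."""
    out: list[AugmentedCrop] = []
    for c in crops:
        out.extend(augment_rotations(c))
    return out


@dataclass
class FoldSplit:
    """One random field-grouped division into train and test."""

    split_id: int
    train_field_ids: frozenset[str]
    test_field_ids: frozenset[str]
    train_idx: np.ndarray  # indices into the crop list handed to make_splits
    test_idx: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = self.train_field_ids & self.test_field_ids
        if overlap:
            raise ValueError(f"train/test field overlap: {sorted(overlap)}")


def make_splits(
    crops: Sequence[NucleusCrop],
    n_splits: int = 100,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> list[FoldSplit]:
    """Repeated random field-grouped divisions, stratified by timepoint.

    Whole fields (never individual crops) are assigned to train or test;
    within each timepoint at least one field goes to each fold, so every
    class is present on both sides. Reproducible from ``seed``.

    Raises
    ------
    ValueError
        If some timepoint has fewer than two fields.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    field_tp: dict[str, float] = {}
    for c in crops:
        field_tp.setdefault(c.field_id, c.timepoint_h)
    if len(field_tp) < 2:
        raise ValueError("need at least two distinct field_ids")
    by_tp: dict[float, list[str]] = {}
    for fid, tp in field_tp.items():
        by_tp.setdefault(tp, []).append(fid)
    for tp, fids in by_tp.items():
        if len(fids) < 2:
            raise ValueError(
                f"timepoint {tp} h has only {len(fids)} field(s); "
                "need >= 2 so it can appear in both folds"
            )
        fids.sort()

    rng = np.random.default_rng(seed)
    splits = []
    for s in range(n_splits):
        test_fields: set[str] = set()
        for tp in sorted(by_tp):
            fids = by_tp[tp]
            n_test = min(len(fids) - 1, max(1, round(test_fraction * len(fids))))
            chosen = rng.choice(len(fids), size=n_test, replace=False)
            test_fields.update(fids[i] for i in chosen)
        train_fields = set(field_tp) - test_fields
        test_idx = np.array([i for i, c in enumerate(crops) if c.field_id in test_fields], dtype=int)
        train_idx = np.array([i for i, c in enumerate(crops) if c.field_id in train_fields], dtype=int)
        splits.append(
            FoldSplit(
                split_id=s,
                train_field_ids=frozenset(train_fields),
                test_field_ids=frozenset(test_fields),
                train_idx=train_idx,
                test_idx=test_idx,
                seed=seed,
            )
        )
    return splits


def shuffle_batches(n_items: int, seed: int = 0, epoch: int = 0) -> np.ndarray:
    """Epoch-varying permutation of 0..n-1, reproducible from (seed, epoch)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(epoch,)))
    return rng.permutation(n_items)
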