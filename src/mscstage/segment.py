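"""Field preprocessing and nucleus segmentation.

Raw 16-bit widefield channels are rescaled to 8-bit with a per-image
min-max scaler (which also normalizes away exposure-time differences),
nuclei are segmented on the DNA-stain channel by Otsu thresholding,
regions whose bounding-box height or width falls outside [50, 100] px
are discarded, and fixed-size multi-channel frames are cut around each
surviving nucleus.

Conventions: 0-based row-major coordinates; bounding boxes are half-open
``(row_min, col_min, row_max, col_max)``; 8-bit conversion uses
round-half-to-even for bit-exact reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from skimage import measure

ALLOWED_TIMEPOINTS_H = (0.0, 6.0, 24.0, 48.0, 72.0)
DEFAULT_MIN_SIZE = 50
DEFAULT_MAX_SIZE = 100
DEFAULT_PIXEL_SIZE_UM = 0.293


@dataclass
class FieldImage:
    """One multi-channel widefield field.

    ``channels`` maps role names (``nucleus``, ``actin``, ``immuno``,
    ``brightfield``) to 2D arrays sharing one shape; ``nucleus`` is
    required for segmentation.
    """

    field_id: str
    timepoint_h: float
    channels: dict[str, np.ndarray]
    bit_depth: int = 16
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    exposure_s: float | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels of field {self.field_id} differ in shape: {shapes}")
        if float(self.timepoint_h) not in ALLOWED_TIMEPOINTS_H:
            raise ValueError(
                f"timepoint_h must be one of {ALLOWED_TIMEPOINTS_H}, got {self.timepoint_h}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class NucleusRegion:
    """A connected component of the thresholded nucleus channel."""

    label: int
    bbox: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max), half-open
    area_px: int
    centroid: tuple[float, float]  # (row, col)
    touches_border: bool = False

    @property
    def height(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def width(self) -> int:
        return self.bbox[3] - self.bbox[1]


@dataclass
class NucleusCrop:
    """Fixed-size multi-channel cutout centered on one nucleus."""

    field_id: str
    label: int
    timepoint_h: float
    channels: dict[str, np.ndarray]
    frame_size: tuple[int, int]
    centroid: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            if ch.shape != tuple(self.frame_size):
                raise ValueError(f"channel {name} shape {ch.shape} != frame_size {self.frame_size}")

    @property
    def crop_id(self) -> str:
        return f"{self.field_id}:{self.label}"


def to_uint8_minmax(channel: np.ndarray) -> np.ndarray:
    """Min-max rescale one channel to 8-bit.

    ``v -> round(255 (v - min) / (max - min))`` with round-half-to-even;
    a constant image maps to all zeros. The output is invariant to any
    positive affine transform of the input, which is what makes images
    acquired at different exposure times comparable.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    lo = float(channel.min())
    hi = float(channel.max())
    if hi == lo:
        return np.zeros(channel.shape, dtype=np.uint8)
    scaled = 255.0 * (channel.astype(np.float64) - lo) / (hi - lo)
    return np.rint(scaled).astype(np.uint8)


def otsu_threshold(channel: np.ndarray) -> int:
    """Otsu threshold of an 8-bit image over the 256-bin histogram.

    Returns the gray level t maximizing the between-class variance of the
    split ``{v <= t} / {v > t}``; ties break toward the smallest t.
    """
    channel = np.asarray(channel)
    hist = np.bincount(channel.ravel().astype(np.int64), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than two distinct values")
    p = hist / hist.sum()
    omega = np.cumsum(p)  # P(class0) for t = 0..255
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b))  # argmax returns the first (smallest) maximizer


def segment_nuclei(
    image: np.ndarray, *, is_mask: bool | None = None, connectivity: int = 2
) -> list[NucleusRegion]:
    """Segment nuclei as 8-connected components above the Otsu threshold.

    Accepts either a binary mask or a raw 8-bit channel (thresholded
    internally). Regions touching the image border are flagged, not
    dropped. An empty foreground yields an empty list.
    """
    image = np.asarray(image)
    if is_mask is None:
        is_mask = image.dtype == bool
    if is_mask:
        mask = image.astype(bool)
    else:
        t = otsu_threshold(image)
        mask = image > t
    if not mask.any():
        return []
    labeled = measure.label(mask, connectivity=connectivity)
    regions = []
    h, w = mask.shape
    for rp in measure.regionprops(labeled):
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        regions.append(
            NucleusRegion(
                label=int(rp.label),
                bbox=(r0, c0, r1, c1),
                area_px=int(rp.area),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                touches_border=touches,
            )
        )
    return regions


def size_filter(
    regions: Iterable[NucleusRegion],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[NucleusRegion]:
    """Keep regions whose bbox height AND width lie in [min_size, max_size].

    Boundary values are kept: only regions strictly larger than
    ``max_size`` or strictly smaller than ``min_size`` in either
    dimension are removed. Idempotent and order-preserving.
    """
    return [
        r
        for r in regions
        if min_size <= r.height <= max_size and min_size <= r.width <= max_size
    ]


def max_frame_size(regions: Iterable[NucleusRegion]) -> tuple[int, int]:
    """Elementwise max bbox (height, width) over the whole surviving dataset."""
    regions = list(regions)
    if not regions:
        raise ValueError("no regions: cannot determine frame size")
    return (max(r.height for r in regions), max(r.width for r in regions))


def crop_frames(
    fimg: FieldImage,
    regions: Iterable[NucleusRegion],
    frame_size: tuple[int, int],
    channels: Iterable[str] | None = None,
) -> list[NucleusCrop]:
    """Cut one fixed-size frame per region from every requested channel.

    Frames are centered on the (rounded) region centroid; parts extending
    past the field boundary are zero-padded. Each crop inherits the field
    id and timepoint label.
    """
    fh, fw = frame_size
    regions = list(regions)
    for r in regions:
        if r.height > fh or r.width > fw:
            raise ValueError(
                f"frame_size {frame_size} smaller than bbox of region {r.label} "
                f"({r.height}x{r.width})"
            )
    names = list(channels) if channels is not None else list(fimg.channels)
    H, W = fimg.shape
    crops = []
    for r in regions:
        cr = int(round(r.centroid[0]))
        cc = int(round(r.centroid[1]))
        r0 = cr - fh // 2
        c0 = cc - fw // 2
        out_channels = {}
        for name in names:
            src = fimg.channels[name]
            dst = np.zeros((fh, fw), dtype=src.dtype)
            sr0, sr1 = max(r0, 0), min(r0 + fh, H)
            sc0, sc1 = max(c0, 0), min(c0 + fw, W)
            if sr0 < sr1 and sc0 < sc1:
                dst[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = src[sr0:sr1, sc0:sc1]
            out_channels[name] = dst
        crops.append(
            NucleusCrop(
                field_id=fimg.field_id,
                label=r.label,
                timepoint_h=fimg.timepoint_h,
                channels=out_channels,
                frame_size=(fh, fw),
                centroid=r.centroid,
            )
        )
    return crops


def segment_field(
    fimg: FieldImage,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    drop_border: bool = False,
) -> list[NucleusRegion]:
    """8-bit conversion + Otsu + components + size filter for one field."""
    nuc8 = to_uint8_minmax(fimg.channels["nucleus"])
    regions = segment_nuclei(nuc8)
    if drop_border:
        regions = [r for r in regions if not r.touches_border]
    return size_filter(regions, min_size, max_size)


def segment_dataset(
    fields: Iterable[FieldImage],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    channels: Iterable[str] | None = None,
    drop_border: bool = False,
    to_8bit: bool = True,
) -> list[NucleusCrop]:
    """Full preprocessing across fields with one global frame size.

    The frame size is the max bbox over *all* surviving regions, not per
    field, so every crop in the dataset shares one shape.
    """
    fields = list(fields)
    per_field: list[tuple[FieldImage, list[NucleusRegion]]] = [
        (f, segment_field(f, min_size, max_size, drop_border)) for f in fields
    ]
    all_regions = [r for _, regs in per_field for r in regs]
    if not all_regions:
        return []
    fsize = max_frame_size(all_regions)
    crops: list[NucleusCrop] = []
    for fimg, regs in per_field:
        if to_8bit:
            conv = {k: to_uint8_minmax(v) for k, v in fimg.channels.items()}
            fimg = FieldImage(
                field_id=fimg.field_id,
                timepoint_h=fimg.timepoint_h,
                channels=conv,
                bit_depth=8,
                pixel_size_um=fimg.pixel_size_um,
                exposure_s=fimg.exposure_s,
            )
        crops.extend(crop_frames(fimg, regs, fsize, channels))
    return crops
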