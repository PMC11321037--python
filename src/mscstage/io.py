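"""Reading and writing the pipeline's on-disk formats.

Fields and crops are multi-page TIFFs (one page per channel, page order
given by an accompanying channel map); ground truth, crop manifests,
split manifests and trajectories are plain CSV. All coordinates are
0-based row-major; bounding boxes are half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segment import FieldImage, NucleusCrop
from .splits import FoldSplit
from .synthetic import NucleusRecord, Trajectory


def write_field(fimg: FieldImage, out_dir: Path) -> Path:
    """Multi-page TIFF (one page per channel) + sidecar channel map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{fimg.field_id}.tif"
    names = list(fimg.channels)
    tifffile.imwrite(path, np.stack([fimg.channels[n] for n in names]), photometric="minisblack")
    with open(path.with_suffix(".channels.yaml"), "w") as fh:
        yaml.safe_dump({i: n for i, n in enumerate(names)}, fh)
    return path


def read_field(
    path: Path, channel_map: dict[int, str] | None = None,
    timepoint_h: float = 0.0, pixel_size_um: float = 0.293,
) -> FieldImage:
    """Read a single- or multi-page TIFF into a FieldImage."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if channel_map is None:
        sidecar = path.with_suffix(".channels.yaml")
        if sidecar.exists():
            with open(sidecar) as fh:
                channel_map = {int(k): v for k, v in yaml.safe_load(fh).items()}
        else:
            channel_map = {i: f"ch{i}" for i in range(stack.shape[0])}
    channels = {channel_map[i]: stack[i] for i in range(stack.shape[0])}
    bit_depth = 16 if stack.dtype == np.uint16 else 8
    return FieldImage(
        field_id=path.stem, timepoint_h=timepoint_h, channels=channels,
        bit_depth=bit_depth, pixel_size_um=pixel_size_um,
    )


def write_ground_truth(records: list[tuple[str, NucleusRecord]], path: Path) -> None:
    rows = [
        {
            "field_id": fid,
            "nucleus_id": r.nucleus_id,
            "cy": r.center[0],
            "cx": r.center[1],
            "bbox_row_min": r.bbox[0],
            "bbox_col_min": r.bbox[1],
            "bbox_row_max": r.bbox[2],
            "bbox_col_max": r.bbox[3],
            "stage_hours": r.stage_hours,
        }
        for fid, r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_crops(crops: list[NucleusCrop], out_dir: Path) -> Path:
    """Per-crop multi-page TIFFs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in crops:
        names = list(c.channels)
        fname = f"{c.field_id}_n{c.label}.tif"
        tifffile.imwrite(out_dir / fname, np.stack([c.channels[n] for n in names]), photometric="minisblack")
        rows.append(
            {
                "crop_path": fname,
                "crop_id": c.crop_id,
                "field_id": c.field_id,
                "label": c.label,
                "timepoint_h": c.timepoint_h,
                "centroid_row": c.centroid[0],
                "centroid_col": c.centroid[1],
                "frame_h": c.frame_size[0],
                "frame_w": c.frame_size[1],
                "channels": "|".join(names),
            }
        )
    manifest = out_dir / "crops.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_crops(manifest: Path) -> list[NucleusCrop]:
    manifest = Path(manifest)
    df = pd.read_csv(manifest)
    crops = []
    for _, row in df.iterrows():
        stack = tifffile.imread(manifest.parent / row["crop_path"])
        if stack.ndim == 2:
            stack = stack[None]
        names = str(row["channels"]).split("|")
        crops.append(
            NucleusCrop(
                field_id=row["field_id"],
                label=int(row["label"]),
                timepoint_h=float(row["timepoint_h"]),
                channels={n: stack[i] for i, n in enumerate(names)},
                frame_size=(int(row["frame_h"]), int(row["frame_w"])),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
            )
        )
    return crops


def write_splits(splits: list[FoldSplit], crops: list[NucleusCrop], path: Path) -> None:
    rows = []
    for s in splits:
        for fold, idx in (("train", s.train_idx), ("test", s.test_idx)):
            for i in idx:
                rows.append(
                    {
                        "split_id": s.split_id,
                        "fold": fold,
                        "field_id": crops[i].field_id,
                        "crop_id": crops[i].crop_id,
                        "crop_index": int(i),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_splits(path: Path) -> list[FoldSplit]:
    df = pd.read_csv(path)
    splits = []
    for sid, g in df.groupby("split_id"):
        tr = g[g["fold"] == "train"]
        te = g[g["fold"] == "test"]
        splits.append(
            FoldSplit(
                split_id=int(sid),
                train_field_ids=frozenset(tr["field_id"]),
                test_field_ids=frozenset(te["field_id"]),
                train_idx=tr["crop_index"].to_numpy(),
                test_idx=te["crop_index"].to_numpy(),
            )
        )
    return splits


def write_trajectories(trajs: list[Trajectory], path: Path, pixel_size_um: float = 0.293) -> None:
    """Trajectory CSV: id, frame, t_seconds, x/y in px and um."""
    rows = []
    for tr in trajs:
        for i, f in enumerate(tr.frames):
            x_um, y_um = tr.positions[i]
            rows.append(
                {
                    "trajectory_id": tr.trajectory_id,
                    "frame": int(f),
                    "t_seconds": float(tr.t_seconds[i]),
                    "x_px": x_um / pixel_size_um,
                    "y_px": y_um / pixel_size_um,
                    "x_um": x_um,
                    "y_um": y_um,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectories(path: Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    trajs = []
    for tid, g in df.groupby("trajectory_id"):
        g = g.sort_values("frame")
        trajs.append(
            Trajectory(
                trajectory_id=int(tid),
                frames=g["frame"].to_numpy(),
                t_seconds=g["t_seconds"].to_numpy(),
                positions=g[["x_um", "y_um"]].to_numpy(),
            )
        )
    return trajs


def write_json(obj, path: Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
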