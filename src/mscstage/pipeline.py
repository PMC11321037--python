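"""End-to-end pipeline wiring with one configuration and one seed.

``run_pipeline`` executes simulate (optional) -> segment -> split ->
train/evaluate on the four channel collections (nucleus, actin,
nucleus+actin, brightfield) and writes every artifact, the serialized
config, and a config hash into the run directory, so a rerun with the
same config reproduces identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from . import io as mio
from .models import ModelSpec, build_model, evaluate_on_split, summarize_reports
from .segment import DEFAULT_MAX_SIZE, DEFAULT_MIN_SIZE, segment_dataset
from .splits import make_splits
from .synthetic import DEFAULT_STAGES_H, StageParams, generate_stage_dataset

logger = logging.getLogger("mscstage")

CHANNEL_COLLECTIONS: dict[str, tuple[str, ...]] = {
    "nucleus": ("nucleus",),
    "actin": ("actin",),
    "nucleus_actin": ("nucleus", "actin"),
    "brightfield": ("brightfield",),
}


@dataclass
class RunConfig:
    out_dir: str = "run"
    input_dir: str | None = None  # None -> simulate
    n_fields_per_stage: int = 4
    n_nuclei_per_field: int = 8
    stages_h: tuple[float, ...] = DEFAULT_STAGES_H
    min_size: int = DEFAULT_MIN_SIZE
    max_size: int = DEFAULT_MAX_SIZE
    pixel_size_um: float = 0.293
    augment: bool = True
    n_splits: int = 100
    n_eval_splits: int = 1  # how many of the splits to actually train on
    test_fraction: float = 0.25
    epochs: int = 25
    input_side: int = 32
    seed: int = 0

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages_h" in raw:
            raw["stages_h"] = tuple(raw["stages_h"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full staging pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({**asdict(config), "config_hash": config.config_hash()}, fh)

    if config.input_dir is None:
        logger.info("simulating %d fields per stage", config.n_fields_per_stage)
        base = StageParams(n_nuclei=config.n_nuclei_per_field)
        fields, truth = generate_stage_dataset(
            stages_h=config.stages_h,
            n_fields_per_stage=config.n_fields_per_stage,
            base_params=base,
            seed=config.seed,
        )
        mio.write_ground_truth(truth, out / "ground_truth.csv")
    else:
        raise NotImplementedError(
            "reading external field directories goes through the `segment` "
            "subcommand; run-all currently drives the synthetic generator"
        )

    logger.info("segmenting %d fields", len(fields))
    crops = segment_dataset(fields, config.min_size, config.max_size)
    if not crops:
        raise RuntimeError("segmentation produced no crops; upstream stage empty")
    manifest = mio.write_crops(crops, out / "crops")
    logger.info("wrote %d crops to %s", len(crops), manifest)

    splits = make_splits(crops, n_splits=config.n_splits,
                         test_fraction=config.test_fraction, seed=config.seed)
    mio.write_splits(splits, crops, out / "splits.csv")

    results = {}
    for coll_name, channels in CHANNEL_COLLECTIONS.items():
        spec = ModelSpec(task="classification", input_channels=channels,
                         epochs=config.epochs, seed=config.seed)
        reports = []
        for split in splits[: config.n_eval_splits]:
            model = build_model(spec, input_side=config.input_side)
            reports.append(evaluate_on_split(model, crops, split, spec, augment=config.augment))
        summary = summarize_reports(reports)
        summary["reports"] = [r.to_dict() for r in reports]
        results[coll_name] = summary
        mio.write_json(summary, out / f"eval_{coll_name}.json")
        logger.info("%s: accuracy %.3f", coll_name, summary["accuracy_mean"])

    mio.write_json(
        {"config_hash": config.config_hash(), "seed": config.seed,
         "n_crops": len(crops), "collections": {k: v["accuracy_mean"] for k, v in results.items()}},
        out / "summary.json",
    )
    return out
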