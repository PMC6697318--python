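"""End-to-end orchestration: phantoms -> masks -> augment -> split -> train
-> benchmark -> agreement scores -> statistical comparison table.

All randomness is funnelled through named per-stage seeds derived from one
master seed, so a rerun with the same config reproduces every output file
byte for byte (on one device).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import agreement, io as oio
from .augment import SplitSpec, augment_dataset, split_dataset
from .compartments import lines_to_mask
from .phantom import PhantomConfig, build_benchmark_fixture, generate_phantoms
from .segnet import NetConfig, TrainConfig, UNetSegmenter, train as train_net
from .stats_tests import StatsConfig, comparison_table
from .types import ValidationError

__all__ = ["RunConfig", "run_end_to_end"]

log = logging.getLogger("octoseg")


def _stage_seed(master: int, stage: str) -> int:
    import zlib

    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """One document describing a full run (YAML-serializable)."""

    out_dir: str = "octoseg_run"
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    stats: StatsConfig = field(default_factory=StatsConfig)
    benchmark_n_per_device: int = 30
    rotation_range_deg: tuple[float, float] = (-8.0, 8.0)
    benchmark_sd_size: tuple[int, int] = (384, 496)
    benchmark_ss_size: tuple[int, int] = (512, 992)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        names = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(doc) - names
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(doc)
        # nested dataclasses come in as dicts
        for name, cls in (
            ("phantom", PhantomConfig),
            ("net", NetConfig),
            ("train", TrainConfig),
            ("split", SplitSpec),
            ("stats", StatsConfig),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = cls(**kwargs[name])
        for name in ("rotation_range_deg", "benchmark_sd_size", "benchmark_ss_size"):
            if name in kwargs:
                kwargs[name] = tuple(kwargs[name])
        return RunConfig(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["phantom"]["device_kind"] = self.phantom.device_kind.value
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def run_end_to_end(config: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``config.out_dir``.

    Returns a result bundle with per-stage counts, the trained model, the
    score sets and the statistics table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    bundle: dict = {}

    # stage 1: phantoms + rasterized masks
    ph_cfg = dataclasses.replace(config.phantom, seed=_stage_seed(config.seed, "phantom"))
    pairs = generate_phantoms(ph_cfg)
    labeled = [
        (scan, lines_to_mask(bnd, scan.height_px, scan.width_px))
        for scan, bnd in pairs
    ]
    log.info("generate: %d phantoms", len(labeled))

    # stage 2: augmentation (3n)
    augmented = augment_dataset(
        labeled, rotation_range_deg=config.rotation_range_deg,
        seed=_stage_seed(config.seed, "augment"),
    )
    log.info("augment: %d labeled images", len(augmented))

    # stage 3: grouped split
    split_spec = dataclasses.replace(
        config.split, seed=_stage_seed(config.seed, "split")
    )
    train_pairs, val_pairs = split_dataset(augmented, split_spec)
    log.info("split: %d train / %d validation", len(train_pairs), len(val_pairs))

    # stage 4: training
    tr_cfg = dataclasses.replace(config.train, seed=_stage_seed(config.seed, "train"))
    model, history = train_net(config.net, train_pairs, val_pairs, tr_cfg)
    model.save(out / "model.pkl")
    log.info("train: %d epochs run", model.n_epochs_run_)

    # stage 5: benchmark fixture + predictions
    fixture = build_benchmark_fixture(
        _stage_seed(config.seed, "benchmark"),
        out_dir=out / "benchmark",
        n_per_device=config.benchmark_n_per_device,
        sd_size=config.benchmark_sd_size,
        ss_size=config.benchmark_ss_size,
    )
    predictions = {
        scan.id: model.predict([scan])[0] for scan in fixture.scans
    }
    log.info(
        "benchmark: %d images, %d graders, %d annotations",
        len(fixture.scans), len(fixture.profiles), len(fixture.annotations),
    )

    # stage 6: agreement scores
    score_sets = []
    for profile in fixture.profiles:
        runs = {
            r: {i: fixture.annotations[(profile.name, r, i)] for i in fixture.image_ids}
            for r in (1, 2, 3)
        }
        score_sets.extend(agreement.intra_grader_scores(runs, profile.name))
    inter_by_group: dict[str, list] = {}
    cnn_by_group: dict[str, list] = {}
    for group in ("L", "EO", "RC"):
        first_runs = {
            g: {i: fixture.annotations[(g, 1, i)] for i in fixture.image_ids}
            for g in fixture.graders_in_group(group)
        }
        inter = agreement.inter_grader_scores(first_runs, group)
        cnn = agreement.cnn_vs_group_scores(predictions, first_runs, group)
        inter_by_group[group] = inter
        cnn_by_group[group] = cnn
        score_sets.extend(inter)
        score_sets.extend(cnn)
    score_sets.extend(agreement.cnn_vs_gt_scores(predictions, fixture.ground_truth))
    oio.write_score_table(score_sets, out / "scores.csv")
    agreement.summary_table(score_sets).to_csv(out / "summary.csv", index=False)
    log.info("agreement: %d score sets", len(score_sets))

    # stage 7: statistics (inter-grader vs CNN-vs-group, per group x compartment)
    stat_pairs = []
    for group in ("L", "EO", "RC"):
        for k in range(4):
            stat_pairs.append((group, inter_by_group[group][k], cnn_by_group[group][k]))
    table = comparison_table(stat_pairs, config=config.stats)
    table.to_csv(out / "stats.csv", index=False)
    log.info("stats: %d comparisons", len(table))

    bundle.update(
        model=model,
        history=history,
        fixture=fixture,
        predictions=predictions,
        score_sets=score_sets,
        stats_table=table,
        counts={
            "phantoms": len(labeled),
            "augmented": len(augmented),
            "train": len(train_pairs),
            "validation": len(val_pairs),
            "benchmark_images": len(fixture.scans),
            "benchmark_annotations": len(fixture.annotations),
        },
    )
    return bundle
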