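"""Seeded phantom-scale experiments: end-to-end recovery and the
dependent (two-stage) vs independent (one-stage) comparison.

These drive the acceptance-style checks: a desk-profile cohort is
generated, both pipelines are trained at a matched budget and evaluated
on held-out phantoms with stone-size-aware metrics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from renalseg.config import RunConfig
from renalseg.evaluation import KIDNEY, STONE, dice_score
from renalseg.models import save_checkpoint
from renalseg.phantom import CohortSpec, generate_cohort
from renalseg.pipeline import (
    PipelineBundle,
    segment_case_one_stage,
    segment_case_two_stage,
)
from renalseg.trainer import (
    TrainResult,
    build_stage1_cubes_3class,
    split_cases,
    train_model,
    train_stage,
)
from renalseg.volume import CtVolume, LabelVolume


@dataclass
class ExperimentResult:
    kidney_dice: list[float]
    stone_dice: list[float]
    failures: int
    histories: dict[str, object]

    @property
    def mean_kidney_dice(self) -> float:
        return float(np.mean(self.kidney_dice))

    @property
    def mean_stone_dice(self) -> float:
        return float(np.mean(self.stone_dice))


def make_cohort(cfg: RunConfig, n_cases: int, seed: int, cohort: CohortSpec | None = None):
    dist = cohort if cohort is not None else cfg.cohort
    return generate_cohort(n_cases, dist, seed=seed)


def train_two_stage_bundle(
    cases: list[tuple[CtVolume, LabelVolume]],
    train_ids: list[str],
    val_ids: list[str],
    cfg: RunConfig,
) -> tuple[PipelineBundle, dict[str, TrainResult]]:
    """Train stage-1 (binary) and stage-2 (3-class) backbones and bundle them."""
    b1 = dataclasses.replace(cfg.backbone, out_classes=2, seed=cfg.train.seed)
    b2 = dataclasses.replace(cfg.backbone, out_classes=3, seed=cfg.train.seed + 1)
    policy = cfg.augment if cfg.train.augment else None
    r1 = train_stage(1, cases, train_ids, val_ids, b1, cfg.train, cfg.preprocess, cfg.stage1_patch, policy)
    r2 = train_stage(2, cases, train_ids, val_ids, b2, cfg.train, cfg.preprocess, cfg.stage2_patch, policy)
    bundle = PipelineBundle(
        stage1_model=r1.model,
        stage2_model=r2.model,
        preproc=cfg.preprocess,
        stage1_spec=cfg.stage1_patch,
        stage2_spec=cfg.stage2_patch,
        stage1_cfg=b1,
        stage2_cfg=b2,
    )
    return bundle, {"stage1": r1, "stage2": r2}


def train_one_stage_model(
    cases: list[tuple[CtVolume, LabelVolume]],
    train_ids: list[str],
    val_ids: list[str],
    cfg: RunConfig,
) -> TrainResult:
    """Independent baseline: direct 3-class segmentation on stage-1 geometry."""
    bcfg = dataclasses.replace(cfg.backbone, out_classes=3, seed=cfg.train.seed + 2)
    cubes = build_stage1_cubes_3class(cases, cfg.preprocess, cfg.stage1_patch)
    policy = cfg.augment if cfg.train.augment else None
    return train_model(cubes, train_ids, val_ids, bcfg, cfg.train, policy)


def evaluate_pipeline(
    segment_fn,
    test_cases: list[tuple[CtVolume, LabelVolume]],
) -> tuple[list[float], list[float], int]:
    """Per-case kidney and stone Dice of any case-level segmentation function."""
    kidney, stone, failures = [], [], 0
    for ct, lab in test_cases:
        pred, report = segment_fn(ct)
        failures += int(report.failed)
        kidney.append(dice_score(pred.voxels, lab.voxels, KIDNEY))
        stone.append(dice_score(pred.voxels, lab.voxels, STONE))
    return kidney, stone, failures


def phantom_recovery(
    cfg: RunConfig,
    n_cases: int = 20,
    n_test: int = 5,
    seed: int = 0,
    cohort: CohortSpec | None = None,
) -> ExperimentResult:
    """Train the two-stage pipeline on a phantom cohort, evaluate held out.

    The last ``n_test`` cases of a seeded permutation are held out; the
    remainder splits ~80/20 into train/val at case level.
    """
    cases_truth, _ = make_cohort(cfg, n_cases, seed, cohort)
    cases = [(ct, lab) for ct, lab, _ in cases_truth]
    ids = [ct.case_id for ct, _ in cases]
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_ids = sorted(order[:n_test])
    pool = order[n_test:]
    n_val = max(1, len(pool) // 5)
    val_ids = sorted(pool[:n_val])
    train_ids = sorted(pool[n_val:])

    bundle, results = train_two_stage_bundle(cases, train_ids, val_ids, cfg)
    test_cases = [(ct, lab) for ct, lab in cases if ct.case_id in test_ids]
    kidney, stone, failures = evaluate_pipeline(
        lambda ct: segment_case_two_stage(ct, bundle), test_cases
    )
    return ExperimentResult(kidney_dice=kidney, stone_dice=stone, failures=failures, histories=results)


def dependent_vs_independent(
    cfg: RunConfig,
    n_cases: int = 12,
    n_test: int = 4,
    seed: int = 0,
    cohort: CohortSpec | None = None,
) -> dict[str, float]:
    """One seeded run of the two-stage vs one-stage comparison at matched budget."""
    cfg = dataclasses.replace(cfg, train=dataclasses.replace(cfg.train, seed=seed))
    cases_truth, _ = make_cohort(cfg, n_cases, seed, cohort)
    cases = [(ct, lab) for ct, lab, _ in cases_truth]
    ids = [ct.case_id for ct, _ in cases]
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test_ids = sorted(order[:n_test])
    pool = order[n_test:]
    n_val = max(1, len(pool) // 5)
    val_ids = sorted(pool[:n_val])
    train_ids = sorted(pool[n_val:])
    test_cases = [(ct, lab) for ct, lab in cases if ct.case_id in test_ids]

    bundle, _ = train_two_stage_bundle(cases, train_ids, val_ids, cfg)
    _, stone_two, _ = evaluate_pipeline(
        lambda ct: segment_case_two_stage(ct, bundle), test_cases
    )

    one = train_one_stage_model(cases, train_ids, val_ids, cfg)
    _, stone_one, _ = evaluate_pipeline(
        lambda ct: segment_case_one_stage(ct, one.model, cfg.preprocess, cfg.stage1_patch),
        test_cases,
    )
    return {
        "seed": seed,
        "two_stage_stone_dice": float(np.mean(stone_two)),
        "one_stage_stone_dice": float(np.mean(stone_one)),
    }


def save_bundle(bundle: PipelineBundle, results: dict[str, TrainResult], out_dir) -> None:
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_checkpoint(bundle.stage1_model, bundle.stage1_cfg, out_dir / "stage1.npz")
    save_checkpoint(bundle.stage2_model, bundle.stage2_cfg, out_dir / "stage2.npz")
    for name, res in results.items():
        res.history.to_csv(out_dir / f"{name}_loss.csv", index=False)
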