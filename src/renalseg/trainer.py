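"""Training recipe: case-level splits, Dice + cross-entropy loss, AdamW
with reduce-on-plateau, best-checkpoint selection on validation loss.

Splits are always at case level — no case ever contributes cubes to both
the training and the validation/test side.  Stage-2 training crops come
from ground-truth kidney ROIs; only inference uses stage-1 predictions.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from renalseg.augment import AugmentPolicy, make_augmented_set
from renalseg.models import BackboneConfig, build_backbone
from renalseg.nn import AdamW, ReduceLROnPlateau, combined_loss_and_grad, softmax
from renalseg.nn.losses import combined_loss
from renalseg.patchwork import PatchSpec, center_crop_xy, clip_z_cubes, crop_roi, find_kidney_rois
from renalseg.preprocess import PreprocessConfig, merge_kidney_labels, preprocess_volume
from renalseg.volume import CtVolume, LabelVolume


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    initial_lr: float = 1e-3
    weight_decay: float = 1e-3
    scheduler_factor: float = 0.1
    scheduler_patience: int = 10
    folds: int = 5
    test_fraction: float = 0.3  # the 7:3 train/test split
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class FoldSplit:
    folds: list[tuple[list[str], list[str]]]  # (train_ids, val_ids) per fold
    test_ids: list[str]

    def all_ids(self) -> set[str]:
        ids = set(self.test_ids)
        for tr, va in self.folds:
            ids |= set(tr) | set(va)
        return ids


def split_cases(
    case_ids: list[str],
    test_fraction: float = 0.3,
    folds: int = 5,
    seed: int = 0,
) -> FoldSplit:
    """Held-out test set of round(test_fraction * n) cases; the remainder is
    partitioned into ``folds`` validation folds.  Deterministic per seed."""
    n = len(case_ids)
    if n < folds + 1:
        raise ValueError(f"need at least folds+1 = {folds + 1} cases, got {n}")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(n)]
    n_test = int(round(test_fraction * n))
    if n - n_test < folds:
        raise ValueError("not enough cases left for the requested fold count")
    test_ids = sorted(order[:n_test])
    pool = order[n_test:]
    fold_sets = [sorted(pool[k::folds]) for k in range(folds)]
    out = []
    for k in range(folds):
        val = fold_sets[k]
        train = sorted(cid for j, s in enumerate(fold_sets) if j != k for cid in s)
        out.append((train, val))
    return FoldSplit(folds=out, test_ids=test_ids)


CubeSet = dict[str, list[tuple[np.ndarray, np.ndarray]]]  # case_id -> (image, label) cubes


def build_stage1_cubes(
    cases: list[tuple[CtVolume, LabelVolume]],
    preproc: PreprocessConfig,
    spec: PatchSpec,
) -> CubeSet:
    """Preprocess + merge labels + center-crop + z-clip each case into cubes."""
    out: CubeSet = {}
    for ct, lab in cases:
        img = preprocess_volume(ct, preproc, stage1_resize=True)
        target = preprocess_volume(merge_kidney_labels(lab), preproc, stage1_resize=True)
        img_c, _ = center_crop_xy(img.voxels, spec.crop_xy)
        lab_c, _ = center_crop_xy(target.voxels, spec.crop_xy)
        grid_i = clip_z_cubes(img_c.astype(np.float32), spec)
        grid_l = clip_z_cubes(lab_c, spec)
        out[ct.case_id] = list(zip(grid_i.cubes, [c.astype(np.int64) for c in grid_l.cubes]))
    return out


def build_stage1_cubes_3class(
    cases: list[tuple[CtVolume, LabelVolume]],
    preproc: PreprocessConfig,
    spec: PatchSpec,
) -> CubeSet:
    """Stage-1 geometry but 3-class targets (the one-stage baseline)."""
    out: CubeSet = {}
    for ct, lab in cases:
        img = preprocess_volume(ct, preproc, stage1_resize=True)
        target = preprocess_volume(lab, preproc, stage1_resize=True)
        img_c, _ = center_crop_xy(img.voxels, spec.crop_xy)
        lab_c, _ = center_crop_xy(target.voxels, spec.crop_xy)
        grid_i = clip_z_cubes(img_c.astype(np.float32), spec)
        grid_l = clip_z_cubes(lab_c, spec)
        out[ct.case_id] = list(zip(grid_i.cubes, [c.astype(np.int64) for c in grid_l.cubes]))
    return out


def build_stage2_cubes(
    cases: list[tuple[CtVolume, LabelVolume]],
    preproc: PreprocessConfig,
    spec: PatchSpec,
    min_roi_volume_mm3: float = 2000.0,
) -> CubeSet:
    """Ground-truth kidney ROIs, cropped at original in-plane resolution."""
    out: CubeSet = {}
    for ct, lab in cases:
        img = preprocess_volume(ct, preproc, stage1_resize=False)
        target = preprocess_volume(lab, preproc, stage1_resize=False)
        rois = find_kidney_rois(
            (target.voxels > 0).astype(np.int16),
            img.spacing,
            crop_yx=spec.crop_xy,
            min_volume_mm3=min_roi_volume_mm3,
        )
        cubes = []
        for box in rois:
            sub_i = crop_roi(img.voxels, box).astype(np.float32)
            sub_l = crop_roi(target.voxels, box)
            grid_i = clip_z_cubes(sub_i, spec)
            grid_l = clip_z_cubes(sub_l, spec)
            cubes += list(zip(grid_i.cubes, [c.astype(np.int64) for c in grid_l.cubes]))
        out[ct.case_id] = cubes
    return out


@dataclass
class TrainResult:
    model: object
    backbone_cfg: BackboneConfig
    history: pd.DataFrame
    best_epoch: int

    @property
    def best_val_loss(self) -> float:
        return float(self.history["val_loss"].iloc[self.best_epoch])


def train_model(
    cubes: CubeSet,
    train_ids: list[str],
    val_ids: list[str],
    backbone_cfg: BackboneConfig,
    cfg: TrainConfig,
    augment_policy: AugmentPolicy | None = None,
) -> TrainResult:
    """Train one backbone on the cube sets of ``train_ids``.

    Per-epoch train/val losses are recorded; the parameters achieving the
    minimal validation loss are restored before returning.  Fully
    deterministic given the config seed.
    """
    leak = set(train_ids) & set(val_ids)
    if leak:
        raise ValueError(f"case(s) in both train and val: {sorted(leak)}")
    train_set = [pair for cid in train_ids for pair in cubes.get(cid, [])]
    val_set = [pair for cid in val_ids for pair in cubes.get(cid, [])]
    if not train_set:
        raise ValueError("empty training set")
    if cfg.augment and augment_policy is not None:
        train_set = make_augmented_set(train_set, augment_policy)

    rng = np.random.default_rng(cfg.seed)
    model = build_backbone(backbone_cfg)
    opt = AdamW(model.params(), lr=cfg.initial_lr, weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=cfg.scheduler_factor, patience=cfg.scheduler_patience)

    history = []
    best_val = np.inf
    best_epoch = -1
    best_state: dict[str, np.ndarray] | None = None
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        train_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_set[i] for i in order[start : start + cfg.batch_size]]
            x = np.stack([b[0] for b in batch])[:, None].astype(np.float32)
            y = np.stack([b[1] for b in batch])
            opt.zero_grad()
            logits = model.forward(x, train=True)
            loss, glogits = combined_loss_and_grad(logits, y)
            model.backward(glogits)
            opt.step()
            train_losses.append(loss)
        val_loss = evaluate_loss(model, val_set, cfg.batch_size) if val_set else float("nan")
        sched.step(val_loss if np.isfinite(val_loss) else float(np.mean(train_losses)))
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(train_losses)),
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        select = val_loss if np.isfinite(val_loss) else history[-1]["train_loss"]
        if select < best_val:
            best_val = select
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(
        model=model,
        backbone_cfg=backbone_cfg,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
    )


def evaluate_loss(model, cube_set: list[tuple[np.ndarray, np.ndarray]], batch_size: int) -> float:
    """Combined loss on a cube list in eval mode (running BN statistics)."""
    losses = []
    weights = []
    for start in range(0, len(cube_set), batch_size):
        batch = cube_set[start : start + batch_size]
        x = np.stack([b[0] for b in batch])[:, None].astype(np.float32)
        y = np.stack([b[1] for b in batch])
        logits = model.forward(x, train=False)
        probs = softmax(logits, axis=1)
        losses.append(combined_loss(probs, y))
        weights.append(len(batch))
    return float(np.average(losses, weights=weights))


def train_stage(
    stage: int,
    cases: list[tuple[CtVolume, LabelVolume]],
    train_ids: list[str],
    val_ids: list[str],
    backbone_cfg: BackboneConfig,
    train_cfg: TrainConfig,
    preproc: PreprocessConfig,
    spec: PatchSpec,
    augment_policy: AugmentPolicy | None = None,
) -> TrainResult:
    """Build the stage-appropriate cube dataset and train on it.

    Stage 1 merges kidney + stone into one foreground class (2 outputs);
    stage 2 trains 3-class on ground-truth kidney ROIs.
    """
    if stage == 1:
        cubes = build_stage1_cubes(cases, preproc, spec)
    elif stage == 2:
        cubes = build_stage2_cubes(cases, preproc, spec)
    else:
        raise ValueError(f"stage must be 1 or 2, got {stage}")
    return train_model(cubes, train_ids, val_ids, backbone_cfg, train_cfg, augment_policy)
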