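"""Two-stage ("dependent") inference and the one-stage baseline.

Stage 1 segments kidney-vs-background on a downsized volume; its mask is
restored to working resolution, per-kidney ROIs are derived by component
analysis, and stage 2 segments kidney + stone inside each ROI at full
in-plane resolution.  ROI predictions are overlaid with label precedence
stone > kidney > background, then mapped back to the original grid.

A case where stage 1 finds no kidney yields an all-background output and
a machine-readable failure flag — never an exception.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from renalseg.models import BackboneConfig, predict_cube
from renalseg.patchwork import (
    PatchSpec,
    RoiBox,
    center_crop_xy,
    clip_z_cubes,
    crop_roi,
    find_kidney_rois,
    restore_roi,
    stitch_cubes,
    uncrop_xy,
)
from renalseg.preprocess import (
    PreprocessConfig,
    preprocess_volume,
    resample_z_to_count,
    resize_xy_to_shape,
)
from renalseg.volume import CtVolume, LabelVolume


@dataclass
class PipelineBundle:
    """Everything needed to run inference: two models + their geometry."""

    stage1_model: object
    stage2_model: object
    preproc: PreprocessConfig
    stage1_spec: PatchSpec
    stage2_spec: PatchSpec
    stage1_cfg: BackboneConfig | None = None
    stage2_cfg: BackboneConfig | None = None
    min_roi_volume_mm3: float = 2000.0
    union_stage1_kidney: bool = False  # optionally fold the coarse mask back in
    version: str = "0.1.0"

    def __post_init__(self) -> None:
        if self.stage1_cfg is not None and self.stage1_cfg.out_classes != 2:
            raise ValueError("stage-1 backbone must have 2 output classes")
        if self.stage2_cfg is not None and self.stage2_cfg.out_classes != 3:
            raise ValueError("stage-2 backbone must have 3 output classes")


@dataclass
class CaseReport:
    case_id: str
    failed: bool = False
    rois: list[RoiBox] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)


def _sliding_window_scores(arr: np.ndarray, model, spec: PatchSpec) -> np.ndarray:
    """Tile along z, score each cube, average scores in overlaps."""
    grid = clip_z_cubes(arr, spec)
    scores = [predict_cube(model, cube[None], normalize=True) for cube in grid.cubes]
    return stitch_cubes(grid, scores)


def segment_case_two_stage(
    v: CtVolume, bundle: PipelineBundle
) -> tuple[LabelVolume, CaseReport]:
    """Full coarse-to-fine pipeline on one raw HU volume.

    Output labels {0, 1, 2} on the original grid (same shape and spacing
    as the input).
    """
    report = CaseReport(case_id=v.case_id)
    t0 = time.perf_counter()
    orig_shape = v.shape
    orig_spacing = v.spacing

    # stage 1: downsized frame
    pre1 = preprocess_volume(v, bundle.preproc, stage1_resize=True)
    cropped, offsets = center_crop_xy(pre1.voxels, bundle.stage1_spec.crop_xy)
    scores1 = _sliding_window_scores(cropped.astype(np.float32), bundle.stage1_model, bundle.stage1_spec)
    scores1 = uncrop_xy(scores1, offsets, pre1.shape[1:])
    mask1 = scores1.argmax(axis=0).astype(np.int16)
    report.timings_s["stage1"] = time.perf_counter() - t0

    # restore coarse mask to the stage-2 working frame (full xy, harmonized z)
    t1 = time.perf_counter()
    pre2 = preprocess_volume(v, bundle.preproc, stage1_resize=False)
    mask1_vol = LabelVolume(voxels=mask1, spacing=pre1.spacing, case_id=v.case_id)
    mask1_full = resize_xy_to_shape(mask1_vol, pre2.shape[1:], pre2.spacing[1:])

    rois = find_kidney_rois(
        mask1_full.voxels,
        pre2.spacing,
        crop_yx=bundle.stage2_spec.crop_xy,
        min_volume_mm3=bundle.min_roi_volume_mm3,
    )
    report.rois = rois
    if not rois:
        report.failed = True
        empty = np.zeros(orig_shape, dtype=np.int16)
        out = LabelVolume(voxels=empty, spacing=orig_spacing, case_id=v.case_id, affine=v.affine)
        report.timings_s["total"] = time.perf_counter() - t0
        return out, report

    # stage 2: per-ROI fine segmentation at full in-plane resolution
    preds = []
    for box in rois:
        sub = crop_roi(pre2.voxels, box).astype(np.float32)
        scores2 = _sliding_window_scores(sub, bundle.stage2_model, bundle.stage2_spec)
        preds.append(scores2.argmax(axis=0).astype(np.int16))
    overlay = restore_roi(preds, rois, pre2.shape)
    if bundle.union_stage1_kidney:
        overlay = np.maximum(overlay, (mask1_full.voxels > 0).astype(np.int16))
    report.timings_s["stage2"] = time.perf_counter() - t1

    out_vol = LabelVolume(voxels=overlay, spacing=pre2.spacing, case_id=v.case_id)
    out_vol = resample_z_to_count(out_vol, orig_shape[0], orig_spacing[0])
    out = LabelVolume(
        voxels=out_vol.voxels.astype(np.int16),
        spacing=orig_spacing,
        case_id=v.case_id,
        affine=v.affine,
    )
    report.timings_s["total"] = time.perf_counter() - t0
    return out, report


def segment_case_one_stage(
    v: CtVolume,
    model,
    preproc: PreprocessConfig,
    spec: PatchSpec,
) -> tuple[LabelVolume, CaseReport]:
    """One-step direct 3-class segmentation on stage-1 geometry."""
    report = CaseReport(case_id=v.case_id)
    t0 = time.perf_counter()
    orig_shape = v.shape
    orig_spacing = v.spacing

    pre1 = preprocess_volume(v, preproc, stage1_resize=True)
    cropped, offsets = center_crop_xy(pre1.voxels, spec.crop_xy)
    scores = _sliding_window_scores(cropped.astype(np.float32), model, spec)
    scores = uncrop_xy(scores, offsets, pre1.shape[1:])
    mask = scores.argmax(axis=0).astype(np.int16)
    if not mask.any():
        report.failed = True

    mask_vol = LabelVolume(voxels=mask, spacing=pre1.spacing, case_id=v.case_id)
    mask_vol = resize_xy_to_shape(mask_vol, orig_shape[1:], orig_spacing[1:])
    mask_vol = resample_z_to_count(mask_vol, orig_shape[0], orig_spacing[0])
    out = LabelVolume(
        voxels=mask_vol.voxels.astype(np.int16),
        spacing=orig_spacing,
        case_id=v.case_id,
        affine=v.affine,
    )
    report.timings_s["total"] = time.perf_counter() - t0
    return out, report
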