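"""Intensity and geometry preprocessing.

Order of operations for stage 1:
``window_hu -> resample_z -> minmax_normalize -> resize_xy``; stage 2 uses
the same chain without the in-plane resize.  Windowing happens before any
interpolation so normalized outputs stay in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from renalseg.volume import CtVolume, GeometryOp, LabelVolume

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults are the unenhanced-CT kidney window and harmonized z-spacing."""

    hu_low: float = -135.0
    hu_high: float = 215.0
    target_z_spacing: float = 1.25
    stage1_xy: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if not self.hu_low < self.hu_high:
            raise ValueError("hu_low must be < hu_high")
        if self.target_z_spacing <= 0:
            raise ValueError("target_z_spacing must be positive")


def window_hu(v: CtVolume, cfg: PreprocessConfig = PreprocessConfig()) -> CtVolume:
    """Clamp every voxel to [hu_low, hu_high].  Idempotent; shape unchanged."""
    clipped = np.clip(v.voxels.astype(np.float32), cfg.hu_low, cfg.hu_high)
    return v.with_voxels(clipped)


def minmax_normalize(v: CtVolume) -> CtVolume:
    """Per-volume (x - min) / (max - min); constant volumes map to all zeros."""
    x = v.voxels.astype(np.float32)
    lo = float(x.min())
    hi = float(x.max())
    if hi == lo:
        log.warning("constant volume %s: min == max == %s, normalizing to zeros", v.case_id, lo)
        return v.with_voxels(np.zeros_like(x))
    return v.with_voxels((x - lo) / (hi - lo))


def resample_z(v: CtVolume, cfg: PreprocessConfig = PreprocessConfig()) -> CtVolume:
    """Resample along z to ``cfg.target_z_spacing`` mm.

    New slice count = round(n * spacing_z / target).  Images are linearly
    interpolated, labels nearest-neighbor (value set preserved).
    """
    sz = v.spacing[0]
    if sz <= 0:
        raise ValueError(f"non-positive z spacing: {sz}")
    n_old = v.shape[0]
    n_new = int(round(n_old * sz / cfg.target_z_spacing))
    n_new = max(n_new, 1)
    if n_new == n_old and abs(sz - cfg.target_z_spacing) < 1e-9:
        return v.with_voxels(v.voxels.copy())
    out = _zoom_axis(v, n_new, axis=0)
    out.spacing = (cfg.target_z_spacing, v.spacing[1], v.spacing[2])
    out.geometry_log.append(
        GeometryOp("resample_z", {"n_old": n_old, "n_new": n_new, "spacing_old": sz})
    )
    return out


def resize_xy(v: CtVolume, target: tuple[int, int] = (256, 256)) -> CtVolume:
    """Resize the in-plane axes to ``target`` (y, x); z untouched."""
    ny, nx = v.shape[1], v.shape[2]
    ty, tx = target
    if (ny, nx) == (ty, tx):
        return v.with_voxels(v.voxels.copy())
    out = _zoom_axis(v, ty, axis=1)
    out = _zoom_axis(out, tx, axis=2)
    out.spacing = (v.spacing[0], v.spacing[1] * ny / ty, v.spacing[2] * nx / tx)
    out.geometry_log.append(
        GeometryOp("resize_xy", {"shape_old": (ny, nx), "shape_new": (ty, tx)})
    )
    return out


def resample_z_to_count(v: CtVolume, n_slices: int, spacing_z: float) -> CtVolume:
    """Inverse helper: force the z axis to ``n_slices`` (nearest for labels)."""
    out = _zoom_axis(v, n_slices, axis=0)
    out.spacing = (spacing_z, v.spacing[1], v.spacing[2])
    return out


def resize_xy_to_shape(v: CtVolume, shape_yx: tuple[int, int], spacing_yx: tuple[float, float]) -> CtVolume:
    """Inverse helper: force the in-plane shape (nearest for labels)."""
    out = _zoom_axis(v, shape_yx[0], axis=1)
    out = _zoom_axis(out, shape_yx[1], axis=2)
    out.spacing = (v.spacing[0], spacing_yx[0], spacing_yx[1])
    return out


def merge_kidney_labels(l: LabelVolume) -> LabelVolume:
    """Collapse kidney + stone into a single foreground class (stage-1 target)."""
    l.validate_labels()
    merged = (l.voxels > 0).astype(l.voxels.dtype)
    return l.with_voxels(merged)


def preprocess_volume(
    v: CtVolume,
    cfg: PreprocessConfig = PreprocessConfig(),
    *,
    stage1_resize: bool = False,
) -> CtVolume:
    """Full intensity/geometry chain for one volume (image or label).

    Labels skip windowing/normalization and use nearest-neighbor resampling.
    """
    is_label = isinstance(v, LabelVolume)
    out = v if is_label else minmax_normalize(resample_z(window_hu(v, cfg), cfg))
    if is_label:
        out = resample_z(v, cfg)
    if stage1_resize:
        out = resize_xy(out, cfg.stage1_xy)
    return out


def _zoom_axis(v: CtVolume, n_target: int, axis: int) -> CtVolume:
    """Zoom one axis to an exact output length; dtype-appropriate order."""
    is_label = isinstance(v, LabelVolume)
    n_old = v.shape[axis]
    if n_target == n_old:
        return v.with_voxels(v.voxels.copy())
    factors = [1.0, 1.0, 1.0]
    factors[axis] = n_target / n_old
    order = 0 if is_label else 1
    data = v.voxels if is_label else v.voxels.astype(np.float32)
    zoomed = ndimage.zoom(data, factors, order=order, mode="nearest", grid_mode=True)
    zoomed = _fix_length(zoomed, n_target, axis)
    return v.with_voxels(zoomed)


def _fix_length(arr: np.ndarray, n: int, axis: int) -> np.ndarray:
    # scipy rounds the output length; guarantee the exact requested count
    if arr.shape[axis] == n:
        return arr
    if arr.shape[axis] > n:
        sl = [slice(None)] * 3
        sl[axis] = slice(0, n)
        return arr[tuple(sl)]
    pad = [(0, 0)] * 3
    pad[axis] = (0, n - arr.shape[axis])
    return np.pad(arr, pad, mode="edge")
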