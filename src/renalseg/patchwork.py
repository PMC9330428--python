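"""Crop / clip / stitch geometry.

Everything here operates on plain ``(z, y, x)`` arrays plus explicit
offset records, so each operation is exactly invertible and testable in
isolation.  Scores tiled along z are fused by averaging over all cubes
covering a voxel before any argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

#: 26-connectivity structuring element for component analysis.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PatchSpec:
    crop_xy: tuple[int, int]
    cube_len: int
    stride: int

    def __post_init__(self) -> None:
        if not (0 < self.stride <= self.cube_len):
            raise ValueError(f"need 0 < stride <= cube_len, got {self.stride}, {self.cube_len}")
        if any(c <= 0 for c in self.crop_xy):
            raise ValueError(f"crop_xy must be positive, got {self.crop_xy}")


#: Paper-scale geometry: stage 1 tiles (96, 192, 192) cubes, stage 2 (64, 160, 160).
STAGE1_SPEC = PatchSpec(crop_xy=(192, 192), cube_len=96, stride=48)
STAGE2_SPEC = PatchSpec(crop_xy=(160, 160), cube_len=64, stride=32)


@dataclass
class PatchGrid:
    """Fixed-shape z-cubes of a source volume plus their start offsets."""

    cubes: list[np.ndarray]
    offsets: list[int]
    source_shape: tuple[int, int, int]
    cube_len: int

    def __len__(self) -> int:
        return len(self.cubes)


@dataclass(frozen=True)
class RoiBox:
    """Per-kidney crop window; in-plane starts may be negative (padding)."""

    z0: int
    z1: int  # exclusive
    y0: int
    x0: int
    size_yx: tuple[int, int]
    component_id: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.z1 - self.z0, self.size_yx[0], self.size_yx[1])


def center_crop_xy(arr: np.ndarray, size: tuple[int, int]) -> tuple[np.ndarray, tuple[int, int]]:
    """Center-crop the in-plane axes to ``size``; z untouched.

    Inputs smaller than ``size`` are symmetrically zero-padded; the returned
    offset is then negative, so ``uncrop_xy`` can re-place voxels exactly.
    Offsets follow ``floor((dim - size) / 2)``.
    """
    _, ny, nx = arr.shape
    ty, tx = size
    off_y = (ny - ty) // 2
    off_x = (nx - tx) // 2
    out = _crop_or_pad(arr, (0, off_y, off_x), (arr.shape[0], ty, tx))
    return out, (off_y, off_x)


def uncrop_xy(
    arr: np.ndarray,
    offsets: tuple[int, int],
    target_yx: tuple[int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Inverse of :func:`center_crop_xy`: re-place a crop into the full plane."""
    lead = arr.shape[:-2]
    ty, tx = target_yx
    out = np.full(lead + (ty, tx), fill, dtype=arr.dtype)
    off_y, off_x = offsets
    # region of the crop that falls inside the target frame
    sy0, sx0 = max(0, -off_y), max(0, -off_x)
    dy0, dx0 = max(0, off_y), max(0, off_x)
    h = min(arr.shape[-2] - sy0, ty - dy0)
    w = min(arr.shape[-1] - sx0, tx - dx0)
    if h > 0 and w > 0:
        out[..., dy0 : dy0 + h, dx0 : dx0 + w] = arr[..., sy0 : sy0 + h, sx0 : sx0 + w]
    return out


def z_cube_offsets(n_slices: int, cube_len: int, stride: int) -> list[int]:
    """Start offsets tiling ``n_slices`` with full coverage.

    Regular starts 0, stride, 2*stride, ... while the cube fits; if slices
    remain uncovered, one end-aligned cube at ``n_slices - cube_len`` is
    appended.  Volumes shorter than ``cube_len`` get a single padded cube.
    """
    if n_slices <= cube_len:
        return [0]
    offsets = []
    start = 0
    while start + cube_len <= n_slices:
        offsets.append(start)
        start += stride
    if offsets[-1] + cube_len < n_slices:
        offsets.append(n_slices - cube_len)
    return offsets


def clip_z_cubes(arr: np.ndarray, spec: PatchSpec) -> PatchGrid:
    """Tile a ``(z, y, x)`` array into overlapping fixed-length z-cubes."""
    nz = arr.shape[0]
    offsets = z_cube_offsets(nz, spec.cube_len, spec.stride)
    cubes = []
    for off in offsets:
        if off + spec.cube_len <= nz:
            cube = arr[off : off + spec.cube_len].copy()
        else:  # single short-volume cube, zero-padded at the end
            pad = spec.cube_len - (nz - off)
            cube = np.pad(arr[off:], ((0, pad), (0, 0), (0, 0)))
        cubes.append(cube)
    return PatchGrid(cubes=cubes, offsets=offsets, source_shape=tuple(arr.shape), cube_len=spec.cube_len)


def stitch_cubes(grid: PatchGrid, score_cubes: list[np.ndarray] | None = None) -> np.ndarray:
    """Reassemble per-cube scores ``(C, cube_len, y, x)`` into the source frame.

    Each voxel's score is the mean over all cubes covering it.  Slices that
    only exist as zero-padding (short volumes) are dropped.
    """
    cubes = grid.cubes if score_cubes is None else score_cubes
    if len(cubes) != len(grid.offsets):
        raise ValueError("score cube count does not match grid offsets")
    nz, ny, nx = grid.source_shape
    lead = cubes[0].shape[:-3]
    acc = np.zeros(lead + (nz, ny, nx), dtype=np.float64)
    cover = np.zeros(nz, dtype=np.int64)
    for cube, off in zip(cubes, grid.offsets):
        n = min(grid.cube_len, nz - off)
        acc[..., off : off + n, :, :] += cube[..., :n, :, :]
        cover[off : off + n] += 1
    assert (cover > 0).all(), "clip_z_cubes guarantees full z coverage"
    acc /= cover[:, None, None]
    return acc.astype(cubes[0].dtype) if np.issubdtype(cubes[0].dtype, np.floating) else acc


def find_kidney_rois(
    coarse_mask: np.ndarray,
    spacing: tuple[float, float, float],
    *,
    crop_yx: tuple[int, int] = (160, 160),
    min_volume_mm3: float = 2000.0,
    max_components: int = 2,
) -> list[RoiBox]:
    """Derive per-kidney crop windows from a binary coarse mask.

    Connected components (26-connectivity) below ``min_volume_mm3`` are
    discarded; the ``max_components`` largest survivors each yield one
    :class:`RoiBox` centered in-plane on the component centroid with the
    component's full z-extent.  Empty result = stage-1 failure.
    """
    labeled, n = ndimage.label(coarse_mask > 0, structure=STRUCT_26)
    if n == 0:
        return []
    voxel_vol = float(np.prod(spacing))
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    keep = [i + 1 for i in range(n) if sizes[i] * voxel_vol >= min_volume_mm3]
    keep.sort(key=lambda cid: -sizes[cid - 1])
    keep = keep[:max_components]
    if not keep:
        return []

    boxes = []
    nz, ny, nx = coarse_mask.shape
    h, w = crop_yx
    centroids = ndimage.center_of_mass(coarse_mask > 0, labeled, index=keep)
    slices = ndimage.find_objects(labeled)
    for cid, (cz, cy, cx) in zip(keep, centroids):
        sl = slices[cid - 1]
        y0 = _clamped_start(cy, h, ny)
        x0 = _clamped_start(cx, w, nx)
        boxes.append(
            RoiBox(z0=sl[0].start, z1=sl[0].stop, y0=y0, x0=x0, size_yx=(h, w), component_id=cid)
        )
    boxes.sort(key=lambda b: b.x0)  # stable left-to-right order
    return boxes


def crop_roi(arr: np.ndarray, box: RoiBox) -> np.ndarray:
    """Extract ``box`` from a ``(z, y, x)`` array, zero-padding outside the image."""
    return _crop_or_pad(arr, (box.z0, box.y0, box.x0), box.shape)


def restore_roi(
    preds: list[np.ndarray],
    boxes: list[RoiBox],
    full_shape: tuple[int, int, int],
) -> np.ndarray:
    """Place per-ROI label predictions back on the original frame.

    Voxels outside every ROI are background; overlaps resolve by label
    precedence stone > kidney > background (elementwise maximum).
    """
    out = np.zeros(full_shape, dtype=np.int16)
    for pred, box in zip(preds, boxes):
        if pred.shape != box.shape:
            raise ValueError(f"prediction shape {pred.shape} != box shape {box.shape}")
        if box.z0 < 0 or box.z1 > full_shape[0]:
            raise ValueError(f"box z-extent [{box.z0}, {box.z1}) outside volume of {full_shape[0]} slices")
        starts = (box.z0, box.y0, box.x0)
        # region of the ROI that falls inside the image
        src0 = [max(0, -s) for s in starts]
        dst0 = [max(0, s) for s in starts]
        n = [
            min(pred.shape[i] - src0[i], full_shape[i] - dst0[i])
            for i in range(3)
        ]
        if any(k <= 0 for k in n):
            continue
        dst = tuple(slice(dst0[i], dst0[i] + n[i]) for i in range(3))
        src = tuple(slice(src0[i], src0[i] + n[i]) for i in range(3))
        out[dst] = np.maximum(out[dst], pred[src].astype(np.int16))
    return out


def _clamped_start(center: float, size: int, dim: int) -> int:
    """Centroid-centered start, clamped inside the image when it fits."""
    start = int(round(center - size / 2))
    if dim >= size:
        return min(max(start, 0), dim - size)
    return (dim - size) // 2  # negative: symmetric padding


def _crop_or_pad(arr: np.ndarray, starts: tuple[int, int, int], shape: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=arr.dtype)
    src0 = [max(0, s) for s in starts]
    dst0 = [max(0, -s) for s in starts]
    n = [min(arr.shape[i] - src0[i], shape[i] - dst0[i]) for i in range(3)]
    if all(k > 0 for k in n):
        dst = tuple(slice(dst0[i], dst0[i] + n[i]) for i in range(3))
        src = tuple(slice(src0[i], src0[i] + n[i]) for i in range(3))
        out[dst] = arr[src]
    return out
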