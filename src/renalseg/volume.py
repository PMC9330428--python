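"""Core volume containers.

All arrays use the internal axis order ``(z, y, x)``.  Geometry-changing
operations (crop, pad, resample, resize) append a record to
``geometry_log`` so that any internal voxel coordinate can be mapped back
to the original frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

VALID_LABELS = (0, 1, 2)  # background, kidney, stone


@dataclass
class GeometryOp:
    """One geometry edit: ``kind`` plus enough parameters to invert it."""

    kind: str  # "resample_z" | "resize_xy" | "crop" | "pad"
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class CtVolume:
    """3D scalar image in HU (or normalized units after preprocessing)."""

    voxels: np.ndarray  # (z, y, x)
    spacing: tuple[float, float, float]  # mm per axis, (z, y, x)
    case_id: str = ""
    geometry_log: list[GeometryOp] = field(default_factory=list)
    affine: np.ndarray | None = None  # source NIfTI affine, if file-backed

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.voxels.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def with_voxels(self, voxels: np.ndarray, **changes: Any) -> "CtVolume":
        """Copy carrying new voxel data; geometry log is shared-copied."""
        out = replace(self, voxels=voxels, **changes)
        out.geometry_log = list(self.geometry_log)
        return out

    def copy(self) -> "CtVolume":
        return self.with_voxels(self.voxels.copy())


@dataclass
class LabelVolume(CtVolume):
    """Integer mask over {0 background, 1 kidney, 2 stone}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError(f"label volume must be integer, got {self.voxels.dtype}")

    def validate_labels(self) -> None:
        present = np.unique(self.voxels)
        bad = set(present.tolist()) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"label values outside {VALID_LABELS}: {sorted(bad)}")


def check_aligned(a: CtVolume, b: CtVolume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"volume shapes differ: {a.shape} vs {b.shape}")
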