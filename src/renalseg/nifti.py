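"""NIfTI read/write — the pipeline's only filesystem boundary.

Volumes are reoriented to canonical RAS+ on read and transposed into the
internal ``(z, y, x)`` axis order.  The canonical affine is kept on the
volume so files written back carry geometry identical (in world space)
to the source, regardless of the source array layout.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np

from renalseg.volume import CtVolume, GeometryOp, LabelVolume


def read_volume(path: str | os.PathLike, *, as_label: bool = False) -> CtVolume:
    """Read a NIfTI-1/2 file into a :class:`CtVolume` (or :class:`LabelVolume`).

    The image is reoriented to canonical RAS+ and stored as ``(z, y, x)``;
    spacing is taken from the header.  ``geometry_log`` starts empty — the
    reorientation is world-space neutral and recorded on the affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for corrupt files
        raise IOError(f"cannot parse NIfTI file {path}: {exc}") from exc

    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got shape {tuple(img.shape)}"
        )

    canonical = nib.as_closest_canonical(img)
    data = np.asanyarray(canonical.dataobj)
    voxels = np.ascontiguousarray(data.transpose(2, 1, 0))  # (x,y,z) -> (z,y,x)
    zx, zy, zz = canonical.header.get_zooms()[:3]
    spacing = (float(zz), float(zy), float(zx))

    cls = LabelVolume if as_label else CtVolume
    if as_label:
        voxels = np.rint(voxels).astype(np.int16)
    return cls(
        voxels=voxels,
        spacing=spacing,
        case_id=_case_id_from_path(path),
        affine=np.array(canonical.affine),
    )


def write_volume(
    volume: CtVolume,
    path: str | os.PathLike,
    dtype_policy: str = "auto",
) -> Path:
    """Write a volume as NIfTI-1.

    dtype_policy: ``"auto"`` (labels/integer data as int16, else float32),
    ``"int16"`` or ``"float32"``.  Label volumes are validated against the
    {0, 1, 2} value set before writing.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    is_label = isinstance(volume, LabelVolume)
    if is_label:
        volume.validate_labels()

    if dtype_policy == "auto":
        dtype = np.int16 if (is_label or np.issubdtype(volume.voxels.dtype, np.integer)) else np.float32
    elif dtype_policy == "int16":
        dtype = np.int16
    elif dtype_policy == "float32":
        dtype = np.float32
    else:
        raise ValueError(f"unknown dtype_policy {dtype_policy!r}")
    if is_label and not np.issubdtype(dtype, np.integer):
        raise ValueError("labels must be written with an integer dtype")

    data = np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)).astype(dtype)
    affine = volume.affine
    if affine is None:
        sz, sy, sx = volume.spacing
        affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((volume.spacing[2], volume.spacing[1], volume.spacing[0]))
    nib.save(img, str(path))
    return path


def _case_id_from_path(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem
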