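"""Cube-level data augmentation, applied to labeled cubes only.

Three modes: random in-plane affine rotation (angle drawn in ±10 deg),
horizontal inversion (always applied within its mode), and the two
composed.  Image and label always receive the identical spatial
transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

MODES = ("affine", "hflip", "hflip+affine")


@dataclass(frozen=True)
class AugmentPolicy:
    modes: tuple[str, ...] = MODES
    affine_angle_deg: float = 10.0  # rotation drawn uniformly in +/- this
    hflip_probability: float = 1.0
    flip_axis: int = 2  # internal x axis
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.modes) - set(MODES)
        if unknown:
            raise ValueError(f"unknown augmentation modes: {sorted(unknown)}")
        if self.affine_angle_deg < 0:
            raise ValueError("affine_angle_deg must be >= 0")


def hflip(
    image: np.ndarray, label: np.ndarray, axis: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror both cubes along the given axis (default: internal x)."""
    return np.flip(image, axis=axis).copy(), np.flip(label, axis=axis).copy()


def random_affine(
    image: np.ndarray,
    label: np.ndarray,
    rng: np.random.Generator,
    max_angle_deg: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """In-plane rotation by an angle drawn uniformly in ±max_angle_deg.

    Image linear, label nearest-neighbor; shape preserved, edges zero-filled.
    """
    angle = float(rng.uniform(-max_angle_deg, max_angle_deg))
    return affine_rotate(image, label, angle)


def affine_rotate(
    image: np.ndarray, label: np.ndarray, angle_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane rotation of an (image, label) cube pair."""
    if angle_deg == 0.0:
        return image.copy(), label.copy()
    img = ndimage.rotate(
        image, angle_deg, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
    )
    lab = ndimage.rotate(
        label, angle_deg, axes=(1, 2), reshape=False, order=0, mode="constant", cval=0
    )
    return img.astype(image.dtype), lab.astype(label.dtype)


def is_labeled(label: np.ndarray) -> bool:
    """A cube counts as labeled iff it contains any foreground voxel."""
    return bool((label > 0).any())


def make_augmented_set(
    cubes: list[tuple[np.ndarray, np.ndarray]],
    policy: AugmentPolicy = AugmentPolicy(),
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Expand labeled cubes: original + one variant per mode.

    Unlabeled cubes pass through untouched, so the output size is
    ``n_labeled * (1 + len(modes)) + n_unlabeled``.
    """
    rng = np.random.default_rng(policy.seed)
    out: list[tuple[np.ndarray, np.ndarray]] = []
    for image, label in cubes:
        out.append((image, label))
        if not is_labeled(label):
            continue
        for mode in policy.modes:
            img, lab = image, label
            if "hflip" in mode:
                img, lab = hflip(img, lab, axis=policy.flip_axis)
            if "affine" in mode:
                img, lab = random_affine(img, lab, rng, policy.affine_angle_deg)
            out.append((img, lab))
    return out
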