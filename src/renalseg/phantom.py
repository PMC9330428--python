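"""Seeded synthetic abdominal-CT-like phantoms with voxel-exact ground truth.

Each phantom contains two disjoint kidney-shaped soft-tissue ellipsoids
on a uniform tissue background, with hyperdense spherical stones carved
strictly inside the kidneys.  Identical spec + seed gives bit-identical
output, and the generator returns per-stone truth records (rasterized
volume, not analytic sphere volume) so downstream inventories can be
checked with zero tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from renalseg.evaluation import classify_stone_size
from renalseg.nifti import write_volume
from renalseg.volume import CtVolume, LabelVolume


@dataclass(frozen=True)
class PhantomSpec:
    shape_zyx: tuple[int, int, int] = (40, 96, 96)
    spacing_mm: tuple[float, float, float] = (2.0, 1.0, 1.0)
    kidney_axes_mm: tuple[tuple[float, float], ...] = ((18.0, 22.0), (10.0, 13.0), (10.0, 13.0))
    kidney_hu: float = 35.0
    background_hu: float = -60.0
    stone_hu: float = 600.0
    stone_diameters_mm: tuple[float, ...] = (8.0, 5.0)
    noise_sd_hu: float = 10.0
    n_distractors: int = 0  # optional background clutter blobs
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 16 for s in self.shape_zyx):
            raise ValueError(f"each shape component must be >= 16, got {self.shape_zyx}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if any(d <= 0 for d in self.stone_diameters_mm):
            raise ValueError(f"stone diameters must be positive, got {self.stone_diameters_mm}")
        if self.stone_hu <= self.kidney_hu:
            raise ValueError("stones must be hyperdense: stone_hu > kidney_hu")
        for lo, hi in self.kidney_axes_mm:
            if not 0 < lo <= hi:
                raise ValueError(f"bad kidney axis range ({lo}, {hi})")


@dataclass
class StoneTruth:
    stone_id: int
    kidney_index: int  # 0 = left, 1 = right
    center_voxel: tuple[int, int, int]
    diameter_mm: float
    voxel_count: int
    volume_mm3: float
    size_class: str


@dataclass
class KidneyTruth:
    kidney_index: int
    centroid_voxel: tuple[float, float, float]
    voxel_count: int


@dataclass
class PhantomTruth:
    case_id: str
    stones: list[StoneTruth] = field(default_factory=list)
    kidneys: list[KidneyTruth] = field(default_factory=list)


def generate_phantom(spec: PhantomSpec, case_id: str = "phantom") -> tuple[CtVolume, LabelVolume, PhantomTruth]:
    """Rasterize one phantom. Deterministic for a given (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape_zyx
    sz, sy, sx = spec.spacing_mm

    labels = np.zeros(spec.shape_zyx, dtype=np.int16)
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=np.float64) * sz,
        np.arange(ny, dtype=np.float64) * sy,
        np.arange(nx, dtype=np.float64) * sx,
        indexing="ij",
    )

    kidneys = _place_kidneys(spec, rng)
    kidney_masks = []
    for center_mm, axes_mm in kidneys:
        cz, cy, cx = center_mm
        az, ay, ax = axes_mm
        mask = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        kidney_masks.append(mask)
        labels[mask] = 1

    truth = PhantomTruth(case_id=case_id)
    for k, mask in enumerate(kidney_masks):
        idx = np.argwhere(mask)
        truth.kidneys.append(
            KidneyTruth(kidney_index=k, centroid_voxel=tuple(idx.mean(axis=0)), voxel_count=len(idx))
        )

    stone_centers: list[tuple[np.ndarray, float]] = []  # (center_mm, radius_mm)
    for i, diameter in enumerate(spec.stone_diameters_mm):
        k = i % 2
        try:
            center_mm = _place_stone(spec, kidneys[k], diameter, stone_centers, rng, stone_id=i)
        except ValueError:
            # crowded kidney: try the contralateral one before giving up
            k = 1 - k
            center_mm = _place_stone(spec, kidneys[k], diameter, stone_centers, rng, stone_id=i)
        r = diameter / 2.0
        mask = (zz - center_mm[0]) ** 2 + (yy - center_mm[1]) ** 2 + (xx - center_mm[2]) ** 2 <= r**2
        if not mask.any():  # sub-voxel stone: keep at least its center voxel
            cv = _nearest_voxel(center_mm, spec.spacing_mm)
            mask[cv] = True
        mask &= kidney_masks[k]
        labels[mask] = 2
        count = int(np.count_nonzero(mask))
        vol = count * float(np.prod(spec.spacing_mm))
        truth.stones.append(
            StoneTruth(
                stone_id=i,
                kidney_index=k,
                center_voxel=_nearest_voxel(center_mm, spec.spacing_mm),
                diameter_mm=diameter,
                voxel_count=count,
                volume_mm3=vol,
                size_class=classify_stone_size(vol),
            )
        )
        stone_centers.append((center_mm, r))

    image = np.full(spec.shape_zyx, spec.background_hu, dtype=np.float64)
    for mask in kidney_masks:
        image[mask] = spec.kidney_hu
    if spec.n_distractors:
        _add_distractors(image, labels, spec, rng, zz, yy, xx)
    image[labels == 2] = spec.stone_hu
    if spec.noise_sd_hu > 0:
        image += rng.normal(0.0, spec.noise_sd_hu, size=image.shape)
    image = np.rint(np.clip(image, -1024, 3071)).astype(np.int16)

    ct = CtVolume(voxels=image, spacing=spec.spacing_mm, case_id=case_id)
    lab = LabelVolume(voxels=labels, spacing=spec.spacing_mm, case_id=case_id)
    return ct, lab, truth


@dataclass(frozen=True)
class CohortSpec:
    """Ranges over phantom parameters for cohort generation."""

    base: PhantomSpec = PhantomSpec()
    stone_count_range: tuple[int, int] = (1, 3)  # inclusive, for stone-bearing cases
    stone_diameter_range_mm: tuple[float, float] = (3.0, 10.0)
    stone_free_fraction: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.stone_count_range
        if not (0 <= lo <= hi):
            raise ValueError(f"bad stone count range {self.stone_count_range}")
        dlo, dhi = self.stone_diameter_range_mm
        if not (0 < dlo <= dhi):
            raise ValueError(f"bad diameter range {self.stone_diameter_range_mm}")
        if not 0.0 <= self.stone_free_fraction <= 1.0:
            raise ValueError("stone_free_fraction must be in [0, 1]")


def generate_cohort(
    n_cases: int, dist: CohortSpec = CohortSpec(), seed: int = 0
) -> tuple[list[tuple[CtVolume, LabelVolume, PhantomTruth]], pd.DataFrame]:
    """Generate ``n_cases`` independent phantoms plus a stone truth table.

    Exactly ``round(stone_free_fraction * n_cases)`` cases carry no stones;
    which cases are stone-free is a seeded permutation (deterministic).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    n_free = int(round(dist.stone_free_fraction * n_cases))
    free = np.zeros(n_cases, dtype=bool)
    free[rng.permutation(n_cases)[:n_free]] = True

    cases = []
    rows = []
    for i in range(n_cases):
        case_id = f"case{i:04d}"
        if free[i]:
            diameters: tuple[float, ...] = ()
        else:
            lo, hi = dist.stone_count_range
            # with an explicit stone-free quota, stone-bearing cases draw >= 1
            if dist.stone_free_fraction > 0:
                lo = max(lo, 1)
            count = int(rng.integers(lo, hi + 1))
            diameters = tuple(
                float(rng.uniform(*dist.stone_diameter_range_mm)) for _ in range(count)
            )
        case_seed = int(rng.integers(0, 2**31 - 1))
        # an infeasible draw (stones too big/crowded for the sampled kidney)
        # is deterministically shrunk rather than aborting the whole cohort
        for attempt in range(6):
            spec = dataclasses.replace(
                dist.base, stone_diameters_mm=diameters, seed=case_seed
            )
            try:
                ct, lab, truth = generate_phantom(spec, case_id=case_id)
                break
            except ValueError:
                if attempt == 5:
                    raise
                diameters = tuple(max(d * 0.85, dist.stone_diameter_range_mm[0] * 0.5)
                                  for d in diameters)
        cases.append((ct, lab, truth))
        for s in truth.stones:
            rows.append(
                {
                    "case_id": case_id,
                    "stone_id": s.stone_id,
                    "center_z": s.center_voxel[0],
                    "center_y": s.center_voxel[1],
                    "center_x": s.center_voxel[2],
                    "diameter_mm": s.diameter_mm,
                    "volume_mm3": s.volume_mm3,
                    "size_class": s.size_class,
                }
            )
    columns = [
        "case_id", "stone_id", "center_z", "center_y", "center_x",
        "diameter_mm", "volume_mm3", "size_class",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return cases, table


def write_cohort(
    cases: list[tuple[CtVolume, LabelVolume, PhantomTruth]],
    table: pd.DataFrame,
    out_dir: str | Path,
) -> Path:
    """Write image/label NIfTI pairs plus the stone truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ct, lab, truth in cases:
        write_volume(ct, out_dir / f"{truth.case_id}_image.nii.gz")
        write_volume(lab, out_dir / f"{truth.case_id}_label.nii.gz")
    csv_path = out_dir / "stones.csv"
    table.to_csv(csv_path, index=False)
    return csv_path


def _place_kidneys(spec: PhantomSpec, rng: np.random.Generator):
    """Two axis-aligned ellipsoids at lateral offsets; guaranteed disjoint."""
    nz, ny, nx = spec.shape_zyx
    sz, sy, sx = spec.spacing_mm
    extent = (nz * sz, ny * sy, nx * sx)
    kidneys = []
    for k, x_frac in enumerate((0.31, 0.69)):
        axes = tuple(float(rng.uniform(lo, hi)) for lo, hi in spec.kidney_axes_mm)
        jitter = rng.uniform(-0.02, 0.02, size=3)
        center = (
            extent[0] * (0.5 + jitter[0]),
            extent[1] * (0.5 + jitter[1]),
            extent[2] * (x_frac + jitter[2]),
        )
        # shrink any axis that would leave the volume or cross the midline
        axes = _fit_axes(center, axes, extent, x_frac)
        kidneys.append((np.array(center), np.array(axes)))
    return kidneys


def _fit_axes(center, axes, extent, x_frac):
    az, ay, ax = axes
    margin = 2.0  # mm clearance from volume border and midline
    az = min(az, center[0] - margin, extent[0] - center[0] - margin)
    ay = min(ay, center[1] - margin, extent[1] - center[1] - margin)
    half = extent[2] / 2.0
    if x_frac < 0.5:
        ax = min(ax, center[2] - margin, half - center[2] - margin)
    else:
        ax = min(ax, center[2] - half - margin, extent[2] - center[2] - margin)
    if min(az, ay, ax) <= 0:
        raise ValueError("phantom volume too small for the requested kidney axes")
    return (az, ay, ax)


def _place_stone(
    spec: PhantomSpec,
    kidney: tuple[np.ndarray, np.ndarray],
    diameter_mm: float,
    existing: list[tuple[np.ndarray, float]],
    rng: np.random.Generator,
    stone_id: int,
) -> np.ndarray:
    """Sample a center such that the stone fits strictly inside the kidney
    and stays clear of previously placed stones."""
    center_k, axes = kidney
    r = diameter_mm / 2.0
    # the sphere fits iff its center lies in the ellipsoid shrunk by r + margin
    margin = max(spec.spacing_mm)
    room = axes - r - margin
    if np.any(room <= 0):
        raise ValueError(
            f"stone {stone_id} (diameter {diameter_mm} mm) too large to fit inside "
            f"a kidney with semi-axes {tuple(round(a, 1) for a in axes)} mm"
        )
    clearance = max(spec.spacing_mm) * 1.5
    for _ in range(500):
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u**2).sum() > 1.0:
            continue
        center = center_k + u * room
        if all(
            np.linalg.norm(center - c) > r + r_other + clearance for c, r_other in existing
        ):
            return center
    raise ValueError(f"could not place stone {stone_id} without overlap after 500 attempts")


def _add_distractors(image, labels, spec, rng, zz, yy, xx):
    extent = np.array(spec.shape_zyx) * np.array(spec.spacing_mm)
    for _ in range(spec.n_distractors):
        center = rng.uniform(0.15, 0.85, size=3) * extent
        radius = rng.uniform(3.0, 8.0)
        mask = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= radius**2
        mask &= labels == 0
        image[mask] = spec.kidney_hu + rng.uniform(-15.0, 15.0)


def _nearest_voxel(center_mm: np.ndarray, spacing: tuple[float, float, float]) -> tuple[int, int, int]:
    return tuple(int(round(c / s)) for c, s in zip(center_mm, spacing))
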