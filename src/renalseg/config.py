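"""Run configuration: named profiles, YAML overrides, validation.

Two profiles ship with the package: ``paper`` carries the full-scale
defaults (200 epochs, batch 8, 96/48 and 64/32 cube geometry on 512x512
volumes) and ``desk`` a CPU-sized variant used by the test-suite and the
phantom experiments.  Every run directory receives the resolved config
verbatim.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from renalseg.augment import AugmentPolicy
from renalseg.models import BackboneConfig
from renalseg.patchwork import PatchSpec
from renalseg.phantom import CohortSpec, PhantomSpec
from renalseg.preprocess import PreprocessConfig
from renalseg.trainer import TrainConfig

PROFILES: dict[str, dict[str, Any]] = {
    "paper": {
        "preprocess": {},  # PreprocessConfig defaults are the paper-scale values
        "stage1_patch": {"crop_xy": (192, 192), "cube_len": 96, "stride": 48},
        "stage2_patch": {"crop_xy": (160, 160), "cube_len": 64, "stride": 32},
        "backbone": {"depth": 3, "base_channels": 8},
        "train": {"epochs": 200, "batch_size": 8, "augment": True},
        "phantom": {
            "shape_zyx": (160, 512, 512),
            "spacing_mm": (2.0, 0.75, 0.75),
            "kidney_axes_mm": ((45.0, 60.0), (25.0, 35.0), (25.0, 35.0)),
        },
        "cohort": {},
    },
    "desk": {
        "preprocess": {"stage1_xy": (96, 96)},
        "stage1_patch": {"crop_xy": (64, 64), "cube_len": 32, "stride": 32},
        "stage2_patch": {"crop_xy": (32, 32), "cube_len": 32, "stride": 16},
        "backbone": {"depth": 2, "base_channels": 8},
        # lr raised vs the 200-epoch recipe: 20 epochs on one CPU need the
        # rare stone class to move within the budget
        "train": {"epochs": 20, "batch_size": 2, "augment": False, "initial_lr": 3e-3},
        "phantom": {
            "shape_zyx": (40, 96, 96),
            "spacing_mm": (2.0, 1.0, 1.0),
        },
        "cohort": {
            "stone_count_range": (1, 2),
            "stone_diameter_range_mm": (5.0, 9.0),
        },
    },
}

_SECTION_TYPES = {
    "preprocess": PreprocessConfig,
    "stage1_patch": PatchSpec,
    "stage2_patch": PatchSpec,
    "backbone": BackboneConfig,
    "train": TrainConfig,
    "phantom": PhantomSpec,
    "augment": AugmentPolicy,
}


@dataclasses.dataclass
class RunConfig:
    profile: str
    seed: int
    preprocess: PreprocessConfig
    stage1_patch: PatchSpec
    stage2_patch: PatchSpec
    backbone: BackboneConfig
    train: TrainConfig
    phantom: PhantomSpec
    augment: AugmentPolicy
    cohort: CohortSpec

    def to_dict(self) -> dict[str, Any]:
        return _plain(dataclasses.asdict(self) | {"profile": self.profile, "seed": self.seed})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def resolve_config(
    profile: str = "desk",
    overrides: dict[str, Any] | None = None,
    seed: int = 0,
) -> RunConfig:
    """Merge profile defaults with explicit overrides into a RunConfig.

    Unknown sections or keys raise with the offending name.
    """
    if profile not in PROFILES:
        raise KeyError(f"unknown profile {profile!r}; available: {sorted(PROFILES)}")
    merged = copy.deepcopy(PROFILES[profile])
    for section, values in (overrides or {}).items():
        if section in ("profile", "seed"):
            continue
        if section not in merged and section != "augment":
            raise KeyError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise TypeError(f"config section {section!r} must be a mapping")
        merged.setdefault(section, {}).update(values)

    sections: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        values = dict(merged.get(name, {}))
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - valid
        if unknown:
            raise KeyError(f"unknown key(s) {sorted(unknown)} in config section {name!r}")
        values = {k: _as_field_type(cls, k, v) for k, v in values.items()}
        if name == "train":
            values.setdefault("seed", seed)
        sections[name] = cls(**values)

    cohort_values = {
        k: _as_field_type(CohortSpec, k, v)
        for k, v in merged.get("cohort", {}).items()
        if k != "base"  # the base phantom is always the resolved phantom section
    }
    valid = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(cohort_values) - valid
    if unknown:
        raise KeyError(f"unknown key(s) {sorted(unknown)} in config section 'cohort'")
    cohort = CohortSpec(base=sections["phantom"], **cohort_values)
    return RunConfig(profile=profile, seed=seed, cohort=cohort, **sections)


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    profile = raw.pop("profile", "desk")
    file_seed = raw.pop("seed", 0)
    return resolve_config(profile, raw, seed=seed if seed is not None else file_seed)


def _as_field_type(cls, key: str, value: Any) -> Any:
    # YAML gives lists where dataclasses expect tuples
    if isinstance(value, list):
        return tuple(tuple(v) if isinstance(v, list) else v for v in value)
    return value


def _plain(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
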