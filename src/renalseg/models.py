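"""Replaceable segmentation backbones.

Every backbone satisfies one contract: it maps a ``(1, D, H, W)`` cube to
``(out_classes, D, H, W)`` per-class scores with the spatial shape
preserved.  Reference implementations: a compact 3D U-Net
(encoder-decoder with skip connections and batch normalization) and a
Res U-Net variant built from residual units.  Additional backbones can
be registered programmatically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from renalseg.nn import (
    BatchNorm3d,
    Conv3d,
    MaxPool3d,
    Module,
    Param,
    ReLU,
    Sequential,
    Upsample3d,
    softmax,
)


@dataclass(frozen=True)
class BackboneConfig:
    name: str = "unet3d"
    out_classes: int = 2
    depth: int = 3  # resolution levels
    base_channels: int = 8
    in_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.out_classes not in (2, 3):
            raise ValueError(f"out_classes must be 2 or 3, got {self.out_classes}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")


def check_divisible(shape_dhw: tuple[int, int, int], depth: int) -> None:
    div = 2 ** (depth - 1)
    for axis, n in zip("zyx", shape_dhw):
        if n % div:
            raise ValueError(
                f"spatial axis {axis} has length {n}, not divisible by 2^(depth-1) = {div}"
            )


def _double_conv(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv3d(cin, cout, 3, rng), BatchNorm3d(cout), ReLU(),
        Conv3d(cout, cout, 3, rng), BatchNorm3d(cout), ReLU(),
    )


class _ResBlock(Module):
    """conv-bn-relu-conv-bn with a (projected) identity shortcut."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.main = Sequential(
            Conv3d(cin, cout, 3, rng), BatchNorm3d(cout), ReLU(),
            Conv3d(cout, cout, 3, rng), BatchNorm3d(cout),
        )
        self.proj = (
            Sequential(Conv3d(cin, cout, 1, rng, bias=False), BatchNorm3d(cout))
            if cin != cout
            else None
        )
        self.relu = ReLU()

    def params(self) -> list[Param]:
        p = self.main.params()
        if self.proj is not None:
            p += self.proj.params()
        return p

    def buffers(self):
        b = self.main.buffers()
        if self.proj is not None:
            b += self.proj.buffers()
        return b

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.main.forward(x, train=train)
        s = self.proj.forward(x, train=train) if self.proj is not None else x
        return self.relu.forward(h + s, train=train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu.backward(gy)
        gs = self.proj.backward(g) if self.proj is not None else g
        gx = self.main.backward(g)
        return gx + gs


class _UNetBase(Module):
    """Shared U-shape: encoder blocks + pools, bottleneck, upsample + concat decoder."""

    def __init__(self, cfg: BackboneConfig, block: Callable[[int, int, np.random.Generator], Module]):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        ch = [cfg.base_channels * 2**i for i in range(cfg.depth)]
        self.ch = ch
        self.encs = [
            block(cfg.in_channels if i == 0 else ch[i - 1], ch[i], rng)
            for i in range(cfg.depth - 1)
        ]
        self.pools = [MaxPool3d() for _ in range(cfg.depth - 1)]
        self.bottleneck = block(ch[-2], ch[-1], rng)
        self.ups = [
            Sequential(Upsample3d(), Conv3d(ch[i + 1], ch[i], 1, rng))
            for i in range(cfg.depth - 1)
        ]
        self.decs = [block(2 * ch[i], ch[i], rng) for i in range(cfg.depth - 1)]
        self.head = Conv3d(ch[0], cfg.out_classes, 1, rng)
        self._grad_skips: list[np.ndarray | None] = [None] * (cfg.depth - 1)

    def params(self) -> list[Param]:
        out = []
        for m in [*self.encs, self.bottleneck, *self.ups, *self.decs, self.head]:
            out += m.params()
        return out

    def buffers(self):
        out = []
        for m in [*self.encs, self.bottleneck, *self.ups, *self.decs, self.head]:
            out += m.buffers()
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        check_divisible(x.shape[2:], self.cfg.depth)
        skips = []
        for enc, pool in zip(self.encs, self.pools):
            x = enc.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bottleneck.forward(x, train=train)
        for i in reversed(range(self.cfg.depth - 1)):
            x = self.ups[i].forward(x, train=train)
            x = np.concatenate([skips[i], x], axis=1)
            x = self.decs[i].forward(x, train=train)
        return self.head.forward(x, train=train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.head.backward(gy)
        for i in range(self.cfg.depth - 1):
            g = self.decs[i].backward(g)
            self._grad_skips[i] = g[:, : self.ch[i]]
            g = self.ups[i].backward(np.ascontiguousarray(g[:, self.ch[i] :]))
        g = self.bottleneck.backward(g)
        for i in reversed(range(self.cfg.depth - 1)):
            g = self.pools[i].backward(g)
            g = g + self._grad_skips[i]
            self._grad_skips[i] = None
            g = self.encs[i].backward(g)
        return g

    # --- scoring contract -------------------------------------------------
    def score_cube(self, cube: np.ndarray) -> np.ndarray:
        """(1, D, H, W) -> (out_classes, D, H, W) raw scores, eval mode."""
        if cube.ndim != 4 or cube.shape[0] != 1:
            raise ValueError(f"expected a (1, D, H, W) cube, got {cube.shape}")
        return self.forward(cube[None].astype(np.float32), train=False)[0]


class UNet3d(_UNetBase):
    def __init__(self, cfg: BackboneConfig):
        super().__init__(cfg, _double_conv)


class ResUNet3d(_UNetBase):
    def __init__(self, cfg: BackboneConfig):
        super().__init__(cfg, _ResBlock)


class ConstantScorer:
    """Trivial registered backbone: constant per-class scores (contract tests)."""

    def __init__(self, cfg: BackboneConfig, scores: tuple[float, ...] | None = None):
        self.cfg = cfg
        self.scores = scores if scores is not None else tuple(
            1.0 if c == 0 else 0.0 for c in range(cfg.out_classes)
        )
        if len(self.scores) != cfg.out_classes:
            raise ValueError("one score per class required")

    def params(self) -> list[Param]:
        return []

    def buffers(self):
        return []

    def score_cube(self, cube: np.ndarray) -> np.ndarray:
        c = self.cfg.out_classes
        out = np.empty((c,) + cube.shape[1:], dtype=np.float32)
        for i, s in enumerate(self.scores):
            out[i] = s
        return out


BACKBONES: dict[str, Callable[[BackboneConfig], object]] = {
    "unet3d": UNet3d,
    "resunet3d": ResUNet3d,
    "constant": ConstantScorer,
}


def register_backbone(name: str, factory: Callable[[BackboneConfig], object]) -> None:
    BACKBONES[name] = factory


def build_backbone(cfg: BackboneConfig):
    try:
        factory = BACKBONES[cfg.name]
    except KeyError:
        raise KeyError(
            f"unknown backbone {cfg.name!r}; registered: {sorted(BACKBONES)}"
        ) from None
    return factory(cfg)


def predict_cube(model, cube: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Per-class score (or probability) cube for one (1, D, H, W) input."""
    scores = model.score_cube(cube.astype(np.float32))
    if normalize:
        return softmax(scores, axis=0)
    return scores


def save_checkpoint(model, cfg: BackboneConfig, path: str | Path) -> Path:
    """Weights as .npz with a JSON sidecar of the backbone config."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict() if hasattr(model, "state_dict") else {}
    np.savez(path, **state)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(asdict(cfg), indent=2))
    return path


def load_checkpoint(path: str | Path):
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = BackboneConfig(**json.loads(sidecar.read_text()))
    model = build_backbone(cfg)
    if hasattr(model, "load_state_dict"):
        with np.load(path) as data:
            model.load_state_dict({k: data[k] for k in data.files})
    return model, cfg
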