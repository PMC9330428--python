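"""Layers with explicit forward/backward on (N, C, D, H, W) float32 arrays.

Convolutions are lowered to GEMM via im2col built from 27 shifted views,
which keeps both directions vectorized.  Every layer caches exactly what
its backward pass needs and releases it afterwards.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad", "no_decay", "name")

    def __init__(self, value: np.ndarray, *, no_decay: bool = False, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.no_decay = no_decay
        self.name = name


class Module:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, p in enumerate(self.params()):
            out[f"p{i:03d}_{p.name}"] = p.value
        for i, (name, buf) in enumerate(self.buffers()):
            out[f"b{i:03d}_{name}"] = buf
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        keys = sorted(state.keys())
        pkeys = [k for k in keys if k.startswith("p")]
        bkeys = [k for k in keys if k.startswith("b")]
        params = self.params()
        if len(pkeys) != len(params):
            raise ValueError(f"checkpoint has {len(pkeys)} params, model expects {len(params)}")
        for k, p in zip(pkeys, params):
            if state[k].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {k}: {state[k].shape} vs {p.value.shape}")
            p.value[...] = state[k]
        bufs = self.buffers()
        if len(bkeys) != len(bufs):
            raise ValueError(f"checkpoint has {len(bkeys)} buffers, model expects {len(bufs)}")
        for k, (_, buf) in zip(bkeys, bufs):
            buf[...] = state[k]

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []


_OFFSETS3 = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


class Conv3d(Module):
    """3x3x3 (pad 1) or 1x1x1 convolution, stride 1, He-initialized.

    The 3x3x3 case is evaluated as 27 shifted (cout x cin) GEMMs instead
    of one big im2col matrix: identical arithmetic, but the working set
    stays at the size of one feature map, which matters on small-memory
    CPU nodes.
    """

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, bias: bool = True):
        if ksize not in (1, 3):
            raise ValueError("only 1x1x1 and 3x3x3 kernels are supported")
        self.cin, self.cout, self.ksize = cin, cout, ksize
        fan_in = cin * ksize**3
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, ksize, ksize, ksize))
        self.weight = Param(w, name=f"conv{ksize}_w")
        self.bias = Param(np.zeros(cout), no_decay=True, name=f"conv{ksize}_b") if bias else None
        self._xp: np.ndarray | None = None  # cached padded input (train mode)
        self._x1: np.ndarray | None = None  # cached input for 1x1 kernels
        self._xshape: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        v = d * h * w
        self._xshape = x.shape
        if self.ksize == 1:
            x2 = x.reshape(n, c, v)
            w2d = self.weight.value.reshape(self.cout, c)
            y = np.matmul(w2d[None], x2)
            if train:
                self._x1 = x2
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
            y = np.zeros((n, self.cout, v), dtype=np.float32)
            wk = self.weight.value  # (cout, cin, 3, 3, 3)
            for dz, dy, dx in _OFFSETS3:
                xs = xp[:, :, dz : dz + d, dy : dy + h, dx : dx + w].reshape(n, c, v)
                y += np.matmul(wk[:, :, dz, dy, dx][None], xs)
            if train:
                self._xp = xp
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        return np.ascontiguousarray(y.reshape(n, self.cout, d, h, w))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._xshape
        v = d * h * w
        gy2 = np.ascontiguousarray(gy.reshape(n, self.cout, v))
        if self.bias is not None:
            self.bias.grad += gy2.sum(axis=(0, 2))
        if self.ksize == 1:
            assert self._x1 is not None, "backward requires a train-mode forward"
            w2d = self.weight.value.reshape(self.cout, c)
            self.weight.grad += np.matmul(gy2, self._x1.transpose(0, 2, 1)).sum(axis=0).reshape(
                self.weight.value.shape
            )
            gx = np.matmul(w2d.T[None], gy2)
            self._x1 = None
            return gx.reshape(n, c, d, h, w)
        assert self._xp is not None, "backward requires a train-mode forward"
        xp = self._xp
        wk = self.weight.value
        gxp = np.zeros_like(xp)
        for dz, dy, dx in _OFFSETS3:
            xs = xp[:, :, dz : dz + d, dy : dy + h, dx : dx + w].reshape(n, c, v)
            self.weight.grad[:, :, dz, dy, dx] += np.matmul(gy2, xs.transpose(0, 2, 1)).sum(axis=0)
            gxs = np.matmul(wk[:, :, dz, dy, dx].T[None], gy2)
            gxp[:, :, dz : dz + d, dy : dy + h, dx : dx + w] += gxs.reshape(n, c, d, h, w)
        self._xp = None
        return np.ascontiguousarray(gxp[:, :, 1:-1, 1:-1, 1:-1])


class BatchNorm3d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(channels), no_decay=True, name="bn_gamma")
        self.beta = Param(np.zeros(channels), no_decay=True, name="bn_beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return [("bn_running_mean", self.running_mean), ("bn_running_var", self.running_var)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        shape = (1, self.channels, 1, 1, 1)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(shape)) * invstd.reshape(shape)
            self._cache = (xhat, invstd)
        else:
            invstd = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(shape)) * invstd.reshape(shape)
        return (self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, invstd = self._cache
        self._cache = None
        axes = (0, 2, 3, 4)
        shape = (1, self.channels, 1, 1, 1)
        m = gy.shape[0] * gy.shape[2] * gy.shape[3] * gy.shape[4]
        g_xhat = gy * self.gamma.value.reshape(shape)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        s1 = g_xhat.sum(axis=axes).reshape(shape)
        s2 = (g_xhat * xhat).sum(axis=axes).reshape(shape)
        gx = (invstd.reshape(shape) / m) * (m * g_xhat - s1 - xhat * s2)
        return gx.astype(np.float32)


class ReLU(Module):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
            return np.where(self._mask, x, 0.0).astype(np.float32)
        return np.maximum(x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        gx = np.where(self._mask, gy, 0.0).astype(np.float32)
        self._mask = None
        return gx


class MaxPool3d(Module):
    """Non-overlapping 2x2x2 max pooling (requires even spatial dims)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"MaxPool3d needs even spatial dims, got {(d, h, w)}")
        r = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        idx = r.argmax(axis=-1)
        y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return np.ascontiguousarray(y)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        idx, xshape = self._cache
        self._cache = None
        n, c, d, h, w = xshape
        flat = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=np.float32)
        np.put_along_axis(flat, idx[..., None], gy[..., None], axis=-1)
        flat = flat.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return np.ascontiguousarray(
            flat.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        )


class Upsample3d(Module):
    """Nearest-neighbor x2 upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, d, h, w = gy.shape
        r = gy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        return np.ascontiguousarray(r.sum(axis=(3, 5, 7)))


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return [b for layer in self.layers for b in layer.buffers()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy
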