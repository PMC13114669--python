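"""Neural-network layers built on the autodiff Tensor.

Modules own ``Tensor`` parameters and recurse through attributes, mirroring
the familiar module-tree convention (named parameters, train/eval mode,
state dicts of plain numpy arrays).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

from .tensor import Tensor, concat, conv2d, depthwise_conv2d, dropout, softmax

# Global generator used for parameter initialization and dropout sampling.
# ``seed_all`` pins it; every entry point that owns randomness reseeds it.
_RNG = np.random.default_rng(0)


def seed_all(seed: int):
    global _RNG
    _RNG = np.random.default_rng(int(seed))


def get_rng() -> np.random.Generator:
    return _RNG


@contextmanager
def rng_seed(seed: int):
    """Temporarily reseed the global generator (restores the previous one)."""
    global _RNG
    prev = _RNG
    _RNG = np.random.default_rng(int(seed))
    try:
        yield
    finally:
        _RNG = prev


def kaiming(shape, fan_in, dtype=np.float32):
    std = np.sqrt(2.0 / fan_in)
    return Tensor((_RNG.standard_normal(shape) * std).astype(dtype), requires_grad=True)


def zeros(shape, dtype=np.float32):
    return Tensor(np.zeros(shape, dtype=dtype), requires_grad=True)


def ones(shape, dtype=np.float32):
    return Tensor(np.ones(shape, dtype=dtype), requires_grad=True)


class Module:
    def __init__(self):
        self.training = True

    # -------------------------------------------------------------- traversal
    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{prefix}{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    # ------------------------------------------------------------------ state
    def named_buffers(self, prefix=""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_buffers(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    def state_dict(self) -> dict:
        out = {k: v.data.copy() for k, v in self.named_parameters()}
        out.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k.startswith("buffer:"):
                name = k[len("buffer:") :]
                obj, attr = self._resolve(name)
                setattr(obj, attr, np.array(v))
            else:
                params[k].data = np.array(v, dtype=params[k].data.dtype)

    def _resolve(self, dotted: str):
        parts = dotted.split(".")
        obj = self
        for p in parts[:-1]:
            obj = obj[int(p)] if p.isdigit() else getattr(obj, p)
        return obj, parts[-1]

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def astype(self, dtype):
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for name, val in vars(m).items():
                if isinstance(val, np.ndarray) and np.issubdtype(val.dtype, np.floating):
                    setattr(m, name, val.astype(dtype))
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.mods = list(mods)

    def append(self, m):
        self.mods.append(m)

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]

    def __len__(self):
        return len(self.mods)

    def forward(self, *a, **k):  # pragma: no cover - containers are not called
        raise NotImplementedError


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, bias: bool = True):
        super().__init__()
        self.w = kaiming((d_in, d_out), fan_in=d_in)
        self.b = zeros((d_out,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.w
        return y + self.b if self.b is not None else y


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.w = kaiming((c_out, c_in, kernel, kernel), fan_in=c_in * kernel * kernel)
        self.b = zeros((c_out,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, padding: int = 0, bias: bool = True):
        super().__init__()
        self.padding = padding
        self.w = kaiming((channels, kernel, kernel), fan_in=kernel * kernel)
        self.b = zeros((channels,)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.w, self.b, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization over (B,H,W) per channel, with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = ones((channels,))
        self.beta = zeros((channels,))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self.running_mean = ((1 - m) * self.running_mean + m * mu.data.ravel()).astype(self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var.data.ravel() * unbias).astype(self.running_var.dtype)
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            mu = self.running_mean[None, :, None, None]
            var = self.running_var[None, :, None, None]
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = ones((dim,))
        self.beta = zeros((dim,))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, _RNG, self.training)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float32) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
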