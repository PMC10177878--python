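"""Layers and optimisation on top of the autograd core.

Weight initialisation is He-style for convolutions and ReLU MLPs; the SGD
optimiser carries momentum and decoupled-from-nothing classic L2 weight decay
(gradient += wd * w), matching the usual detectron-era recipes.
"""

from __future__ import annotations

import numpy as np

from .grad import Tensor, conv2d


class Module:
    """Minimal container: tracks parameters and sub-modules by attribute."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            self._collect(v, params, seen)
        return params

    @staticmethod
    def _collect(v, params, seen):
        if isinstance(v, Tensor) and v.requires_grad:
            if id(v) not in seen:
                seen.add(id(v))
                params.append(v)
        elif isinstance(v, Module):
            for p in v.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        elif isinstance(v, (list, tuple)):
            for item in v:
                Module._collect(item, params, seen)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, s in zip(params, state):
            if p.data.shape != s.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {s.shape}")
            p.data[...] = s

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None,
                 zero_init: bool = False, std: float | None = None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            std = np.sqrt(2.0 / (cin * k * k)) if std is None else std
            w = rng.normal(0.0, std, size=(cout, cin, k, k))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False, std: float | None = None):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((cin, cout))
        else:
            std = np.sqrt(2.0 / cin) if std is None else std
            w = rng.normal(0.0, std, size=(cin, cout))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class GroupNorm(Module):
    """Group normalization over (C/G, H, W) per sample; batch-size free."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.data.shape
        G = self.groups
        g = x.reshape(N, G, (C // G) * H * W)
        mu = g.mean(axis=2, keepdims=True)
        centered = g - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        normed = centered * (var + self.eps) ** -0.5
        out = normed.reshape(N, C, H, W)
        return out * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class ConvNorm(Module):
    """Conv2d -> GroupNorm (-> ReLU by the caller)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None, groups: int = 8):
        self.conv = Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng)
        self.norm = GroupNorm(cout, groups)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SGD:
    """Stochastic gradient descent with momentum and L2 weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self):
        scale = 1.0
        if self.clip_norm is not None:
            sq = sum(float((p.grad ** 2).sum())
                     for p in self.params if p.grad is not None)
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                scale = self.clip_norm / norm
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad * scale
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
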