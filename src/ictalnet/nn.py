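"""Neural-network layers built on :mod:`ictalnet.autodiff`.

Layers follow the familiar module pattern: parameters are ``Tensor`` objects
with ``requires_grad=True``, ``parameters()`` yields them for the optimizer,
and ``train()`` / ``eval()`` toggle dropout and batch-norm behaviour.  Layout
is NCHW for feature maps.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import truncnorm

from .autodiff import Tensor, conv2d


def trunc_normal(shape, std: float, rng: np.random.Generator) -> np.ndarray:
    """Truncated normal at +-2 std, the initialisation used for every weight."""
    return truncnorm.rvs(-2.0, 2.0, scale=std, size=shape, random_state=rng)


class Module:
    training: bool = True

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                out.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                state[key] = value.data.copy()
            elif isinstance(value, Module):
                state.update(value.state_dict(prefix=key + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(prefix=f"{key}.{i}."))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                value.data = np.asarray(state[key], dtype=value.data.dtype).reshape(value.shape)
            elif isinstance(value, Module):
                value.load_state_dict(state, prefix=key + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, prefix=f"{key}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, std: float = 0.02):
        self.weight = Tensor(trunc_normal((d_in, d_out), std, rng), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    """3x3 (or kxk) grouped convolution with 'same' ceil padding by default."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, groups: int = 1, padding: str = "same",
                 bias: bool = True, std: float = 0.02):
        self.stride = stride
        self.groups = groups
        self.padding = padding
        self.weight = Tensor(
            trunc_normal((c_out, c_in // groups, kernel, kernel), std, rng),
            requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class DepthwiseSeparableConv2d(Module):
    """Depthwise kxk followed by pointwise 1x1 channel mixing."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, std: float = 0.02):
        self.depthwise = Conv2d(channels, channels, kernel, rng, stride=stride,
                                groups=channels, std=std)
        self.pointwise = Conv2d(channels, channels, 1, rng, std=std)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class BatchNorm2d(Module):
    """Per-channel batch normalisation; running stats used in eval mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float | None = 0.1):
        self.eps = eps
        self.momentum = momentum  # None -> cumulative average (recalibration mode)
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.num_batches_tracked = 0

    def reset_running_stats(self) -> None:
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.ones_like(self.running_var)
        self.num_batches_tracked = 0

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mean
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            self.num_batches_tracked += 1
            m = (1.0 / self.num_batches_tracked) if self.momentum is None else self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mean.data.reshape(c))
            unbiased = var.data.reshape(c) * n / max(n - 1, 1)
            self.running_var = ((1 - m) * self.running_var
                                + m * unbiased)
            xhat = centered * (var + self.eps) ** -0.5
        else:
            dt = x.data.dtype
            mean = Tensor(self.running_mean.reshape(1, c, 1, 1).astype(dt))
            var = Tensor(self.running_var.reshape(1, c, 1, 1).astype(dt))
            xhat = (x - mean) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state = super().state_dict(prefix)
        state[f"{prefix}running_mean"] = self.running_mean.copy()
        state[f"{prefix}running_var"] = self.running_var.copy()
        return state

    def load_state_dict(self, state, prefix: str = "") -> None:
        super().load_state_dict(state, prefix)
        self.running_mean = np.asarray(state[f"{prefix}running_mean"], dtype=np.float64)
        self.running_var = np.asarray(state[f"{prefix}running_var"], dtype=np.float64)


class LayerNorm2d(Module):
    """Layer normalisation over the channel axis of an NCHW map (per position)."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        mean = x.mean(axis=1, keepdims=True)
        centered = x - mean
        var = (centered * centered).mean(axis=1, keepdims=True)
        xhat = centered * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Dropout(Module):
    """Inverted dropout; the mask stream is seeded once at construction."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = ((self.rng.random(x.shape) < keep) / keep).astype(x.data.dtype)
        return x * Tensor(mask)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.gelu()


class Adam:
    """Adam optimizer with the standard defaults (no weight decay)."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
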