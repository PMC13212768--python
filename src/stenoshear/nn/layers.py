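"""Neural-network modules and the Adam optimizer on top of the tape engine.

Initialization is Glorot-uniform from an explicit ``numpy.random.Generator``
so every model in the package is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base class: recursive parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def _buffers(self):
        """(module, attr) pairs of non-trainable state (batch-norm running
        statistics)."""
        out = []
        for m in self.modules():
            for attr in ("running_mean", "running_var"):
                if hasattr(m, attr):
                    out.append((m, attr))
        return out

    def state_dict(self) -> list[np.ndarray]:
        arrays = [p.data.copy() for p in self.parameters()]
        arrays.extend(getattr(m, a).copy() for m, a in self._buffers())
        return arrays

    def load_state_dict(self, state: list[np.ndarray]):
        params = self.parameters()
        for p, s in zip(params, state[: len(params)], strict=False):
            p.data = np.asarray(s, dtype=np.float64).copy()
        for (m, a), s in zip(self._buffers(), state[len(params):], strict=True):
            setattr(m, a, np.asarray(s, dtype=np.float64).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(glorot(rng, (in_dim, out_dim), in_dim, out_dim))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """3x3 (or kxk) convolution with 'same' spatial size via reflect padding
    axially (H) and wrap padding circumferentially (W)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 pad_mode_h: str = "reflect", pad_mode_w: str = "wrap",
                 bias: bool = True):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        self.weight = Parameter(
            glorot(rng, (out_ch, in_ch, kernel, kernel), fan_in, fan_out)
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.kernel = kernel
        self.stride = stride
        self.pad_mode_h = pad_mode_h
        self.pad_mode_w = pad_mode_w

    def forward(self, x: Tensor) -> Tensor:
        p = self.kernel // 2
        if p:
            x = x.pad_hw(p, p, self.pad_mode_h, self.pad_mode_w)
        return x.conv2d(self.weight, self.bias, stride=self.stride)


class ConvTranspose2d(Module):
    """2x2 stride-2 transpose convolution (exact 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        fan = in_ch * 4
        self.weight = Parameter(glorot(rng, (in_ch, out_ch, 2, 2), fan, out_ch * 4))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2x2(self.weight, self.bias)


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.maxpool2x2()


class BatchNorm2d(Module):
    def __init__(self, n_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, n_ch, 1, 1)))
        self.beta = Parameter(np.zeros((1, n_ch, 1, 1)))
        self.running_mean = np.zeros((1, n_ch, 1, 1))
        self.running_var = np.ones((1, n_ch, 1, 1))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                (Tensor(self.running_var) + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class BatchNorm1d(Module):
    """Feature-wise normalization over the row (node/sample) dimension."""

    def __init__(self, n_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, n_features)))
        self.beta = Parameter(np.zeros((1, n_features)))
        self.running_mean = np.zeros((1, n_features))
        self.running_var = np.ones((1, n_features))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var.data
            )
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                (Tensor(self.running_var) + self.eps) ** -0.5
            )
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout with an explicit generator for reproducibility."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * Tensor(mask)


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
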