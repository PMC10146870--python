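"""Layer modules built on the autodiff engine.

Parameter initialization is deterministic: every module takes a
``numpy.random.Generator`` and draws Kaiming fan-in weights (zero biases),
so two models built from the same seed are bitwise identical.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

DTYPE = np.float32


class Module:
    """Minimal module container with recursive parameter discovery."""

    def __init__(self):
        self.training = True

    # -- traversal -------------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buf:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"checkpoint missing parameter {name!r}")
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, buf in self.named_buffers():
            key = "buf:" + name
            if key in state:
                buf[...] = state[key]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(arr: np.ndarray) -> Tensor:
    return Tensor(arr.astype(DTYPE), requires_grad=True)


def _kaiming(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = _param(_kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = _param(np.zeros(out_ch))

    def forward(self, x):
        return T.conv2d(x, self.weight, self.bias,
                        stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, rng, kernel: int = 2,
                 stride: int = 2):
        super().__init__()
        self.stride = stride
        fan_in = in_ch * kernel * kernel
        self.weight = _param(_kaiming(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.bias = _param(np.zeros(out_ch))

    def forward(self, x):
        return T.conv_transpose2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng):
        super().__init__()
        self.weight = _param(_kaiming(rng, (in_dim, out_dim), in_dim))
        self.bias = _param(np.zeros(out_dim))

    def forward(self, x):
        return T.matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    """Channel-wise batch normalization with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
            xhat = T.normalize(x, axes=(0, 2, 3), eps=self.eps)
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
            xhat = (x - mu) * T.power(var + self.eps, -0.5)
        g = T.reshape(self.gamma, (1, c, 1, 1))
        b = T.reshape(self.beta, (1, c, 1, 1))
        return xhat * g + b


class LayerNorm(Module):
    """Normalization over the trailing feature dimension (token width)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))

    def forward(self, x):
        xhat = T.normalize(x, axes=(-1,), eps=self.eps)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x
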