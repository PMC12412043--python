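"""Layer/module abstractions over the autodiff tensor.

Mirrors the torch.nn idiom at a small scale: modules register parameters and
submodules on attribute assignment, expose ``parameters()`` / ``state_dict()``
and a train/eval flag that switches batch-norm statistics.
Weight initialisation draws from a package-global RNG; call
:func:`manual_seed` for reproducible builds.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor
from . import functional as F

__all__ = [
    "manual_seed", "get_rng", "Parameter", "Module", "Identity", "Conv2d",
    "BatchNorm2d", "LayerNorm", "Linear", "Sequential", "ConvBlock",
    "identity_conv_", "Upsample",
]

_RNG = np.random.default_rng(0)


def manual_seed(seed: int) -> None:
    """Reset the global initialisation RNG (call before building a model)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _RNG


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ------------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation ----------------------------------------------------

    def _buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (overridden by BatchNorm)."""
        return {}

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, p in self._params.items():
            out[f"{prefix}{name}"] = p.data.copy()
        for name, b in self._buffers().items():
            out[f"{prefix}{name}"] = b.copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix=f"{prefix}{name}."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        own = {f"{prefix}{n}": p for n, p in self._params.items()}
        buf = {f"{prefix}{n}": n for n in self._buffers()}
        for key, p in own.items():
            if key not in state:
                raise KeyError(f"missing parameter {key!r} in checkpoint")
            if state[key].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: checkpoint {state[key].shape}, "
                    f"model {p.data.shape}"
                )
            p.data = state[key].astype(np.float32).copy()
        for key, name in buf.items():
            if key not in state:
                raise KeyError(f"missing buffer {key!r} in checkpoint")
            setattr(self, name, state[key].astype(np.float32).copy())
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix=f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """2-D convolution with He-normal initialisation."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int | None = None, dilation: int = 1, bias: bool = True):
        super().__init__()
        if kernel % 2 == 0 and padding is None:
            raise ValueError(f"even kernel {kernel} requires explicit padding")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.dilation = kernel, stride, dilation
        # default padding preserves spatial size at stride 1 for any dilation
        self.padding = (kernel - 1) // 2 * dilation if padding is None else padding
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(_RNG.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                        self.dilation)


def identity_conv_(conv: Conv2d) -> Conv2d:
    """Set a square-channel conv to the identity (centre tap 1, bias 0).

    Used by the equation-fidelity tests to turn learned blocks into exact
    array arithmetic.
    """
    if conv.in_ch != conv.out_ch:
        raise ValueError("identity init needs in_ch == out_ch")
    w = np.zeros_like(conv.weight.data)
    c = conv.kernel // 2
    for i in range(conv.out_ch):
        w[i, i, c, c] = 1.0
    conv.weight.data = w
    if conv.bias is not None:
        conv.bias.data = np.zeros_like(conv.bias.data)
    return conv


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones((1, num_features, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1)))
        self.running_mean = np.zeros((1, num_features, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, num_features, 1, 1), dtype=np.float32)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) / (var + self.eps) ** 0.5
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return self.gamma * xhat + self.beta


class LayerNorm(Module):
    """Normalisation over the trailing feature axis (token layout B, N, C)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return self.gamma * ((x - mu) / (var + self.eps) ** 0.5) + self.beta


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, bias: bool = True):
        super().__init__()
        std = np.sqrt(2.0 / in_dim)
        self.weight = Parameter(_RNG.normal(0.0, std, (in_dim, out_dim)))
        self.bias = Parameter(np.zeros(out_dim)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Upsample(Module):
    def __init__(self, scale: int, mode: str = "bilinear"):
        super().__init__()
        self.scale, self.mode = scale, mode

    def forward(self, x):
        return F.resize2d(x, self.scale, self.mode)


class ConvBlock(Module):
    """Conv -> (BN) -> (ReLU): the Conv(.) unit used throughout the decoder.

    `norm=False, act=False` exposes the raw convolution so the module-level
    equation oracles can run in unit-weight mode.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 dilation: int = 1, norm: bool = True, act: bool = True):
        super().__init__()
        if kernel % 2 == 0:
            from ..errors import ConfigurationError

            raise ConfigurationError(
                f"conv block kernel must be odd to preserve spatial size, got {kernel}"
            )
        self.conv = Conv2d(in_ch, out_ch, kernel, stride=stride, dilation=dilation,
                           bias=not norm)
        self.bn = BatchNorm2d(out_ch) if norm else Identity()
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        return x.relu() if self.act else x
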