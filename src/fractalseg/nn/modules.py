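"""Layer modules: parameter containers over the functional ops."""

from __future__ import annotations

import numpy as np

from . import ops
from .tensor import Parameter, Tensor


class Module:
    """Base class: parameter registry, train/eval mode, named traversal."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self.__dict__.setdefault("_children", {})[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}{name}", p)
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        """Total trainable scalar count."""
        return sum(p.size for p in self.parameters())

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for m_name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                state[f"{m_name}.running_mean"] = m.running_mean.copy()
                state[f"{m_name}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        for m_name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"{m_name}.running_mean"], dtype=np.float64)
                m.running_var = np.asarray(state[f"{m_name}.running_var"], dtype=np.float64)

    def _named_modules(self, prefix: str = ""):
        yield (prefix.rstrip("."), self)
        for cname, child in self._children.items():
            yield from child._named_modules(prefix=f"{prefix}{cname}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator | None, shape, fan_in: int) -> np.ndarray:
    """Variance-scaling (fan-in) normal initialization; zeros when rng is None
    (used for capacity counting where values are irrelevant)."""
    if rng is None:
        return np.zeros(shape, dtype=np.float32)
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    """2D convolution, stride 1.  ``padding`` of k//2 preserves spatial dims
    for odd kernels; 2x2 kernels use asymmetric (0,1) padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator | None = None, bias: bool = True,
                 padding: str = "same"):
        super().__init__()
        if out_channels < 1:
            raise ValueError("out_channels must be positive")
        k = kernel_size
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        if padding == "same":
            lo = (k - 1) // 2
            hi = k - 1 - lo
            self.pad = ((lo, hi), (lo, hi))
        elif padding == "valid":
            self.pad = ((0, 0), (0, 0))
        else:
            self.pad = padding
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, k, k), in_channels * k * k))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, self.bias, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mean, var = ops.batchnorm_train(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
            return out
        return ops.batchnorm_eval(x, self.gamma, self.beta,
                                  self.running_mean, self.running_var, self.eps)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0:
            return x
        return ops.dropout(x, self.p, self.rng)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
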