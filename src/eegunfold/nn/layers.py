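"""Layer/module abstractions on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Parameter",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "ZeroUpsample",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery by attribute walk, train/eval mode."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for mod in self.modules():
            for v in mod.__dict__.values():
                if isinstance(v, Parameter) and id(v) not in seen:
                    seen.add(id(v))
                    params.append(v)
        return params

    def named_parameters(self) -> list[tuple[str, Parameter]]:
        named: list[tuple[str, Parameter]] = []
        seen: set[int] = set()

        def walk(obj: "Module", prefix: str) -> None:
            for name, v in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    if id(v) not in seen:
                        seen.add(id(v))
                        named.append((key, v))
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return named

    def named_state(self) -> list[tuple[str, np.ndarray]]:
        """All learnable parameters and persistent buffers (e.g. BN running
        statistics), with stable attribute-path names, for checkpointing."""
        named: list[tuple[str, np.ndarray]] = []
        seen: set[int] = set()

        def walk(obj: "Module", prefix: str) -> None:
            for name, v in obj.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    if id(v) not in seen:
                        seen.add(id(v))
                        named.append((key, v.data))
                elif isinstance(v, np.ndarray):
                    if id(v) not in seen:
                        seen.add(id(v))
                        named.append((key, v))
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return named

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        """Inverse of :meth:`named_state`; shapes must match exactly."""
        for name, arr in self.named_state():
            if name not in state:
                raise KeyError(f"missing state entry {name!r}")
            src = np.asarray(state[name], dtype=np.float64)
            if src.shape != arr.shape:
                raise ValueError(f"shape mismatch for {name!r}: {src.shape} vs {arr.shape}")
            arr[...] = src

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv1d(Module):
    """'Same'-padded 1-D convolution, Kaiming-uniform initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ):
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel_size))
        else:
            bound = np.sqrt(6.0 / fan_in)
            w = rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel_size))
        self.weight = Parameter(w)
        if bias:
            b_bound = 1.0 / np.sqrt(fan_in)
            self.bias = Parameter(rng.uniform(-b_bound, b_bound, size=out_channels))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ad.batchnorm(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ad.relu(x)


class MaxPool1d(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return ad.maxpool1d(x, self.factor)


class ZeroUpsample(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return ad.zero_upsample(x, self.factor)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
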