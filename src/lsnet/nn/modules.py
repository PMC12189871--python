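"""Layer/module containers over the autodiff primitives."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .autograd import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "SiLU", "Identity",
           "MaxPool2d", "UpsampleNearest", "Sequential"]


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Minimal module base: parameter discovery, train/eval mode, state dict."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -----------------------------------------------------
    def children(self) -> Iterator["Module"]:
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self.children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, v in vars(self).items():
            if isinstance(v, np.ndarray):
                yield f"{prefix}{name}", v
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield from v.buffers(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.buffers(f"{prefix}{name}.{i}.")

    # -- modes ---------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation ----------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b for name, b in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        bufs = dict(self.buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = bufs[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data = value.astype(np.float32, copy=True)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.dilation = dilation
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = in_channels // groups * kernel_size ** 2
        bound = np.sqrt(6.0 / fan_in)  # Kaiming-uniform, gain for linear fan-in
        self.weight = Parameter(rng.uniform(
            -bound, bound, (out_channels, in_channels // groups,
                            kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation,
                        groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, training=self.training,
                              momentum=self.momentum, eps=self.eps)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class UpsampleNearest(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return F.upsample_nearest(x, self.scale)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
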