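"""Layer containers over the autodiff core: Module, Conv2d, BatchNorm2d."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Module", "ModuleList", "Conv2d", "BatchNorm2d"]


class Module:
    """Base class with parameter/buffer registration by attribute scan.

    Subclasses assign ``Tensor`` parameters, ``np.ndarray`` buffers (running
    statistics), sub-``Module``s or ``ModuleList``s as plain attributes;
    ``parameters``/``state_dict`` discover them by walking ``__dict__`` in
    definition order, which keeps state-dict keys stable across rebuilds.
    """

    def __init__(self):
        self.training = True

    # -- mode -------------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    # -- traversal --------------------------------------------------------
    def named_children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in self.__dict__.items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield f"{name}.{i}", sub

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self.named_children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in self.__dict__.items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self.named_children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in self.__dict__.items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self.named_children():
            yield from child.named_buffers(prefix + name + ".")

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_params = dict(self.named_parameters())
        own_bufs = dict(self.named_buffers())
        expected = set(own_params) | set(own_bufs)
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own_params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float32).copy()
        for name, b in own_bufs.items():
            b[...] = state[name]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    """A list of sub-modules that participates in registration."""


class Conv2d(Module):
    """2-D convolution with He-normal initialization.

    ``pad='same'`` keeps spatial dims at stride 1 (odd kernels only).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        pad: int | str = "same",
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        if pad == "same":
            if kernel_size % 2 == 0:
                raise ValueError("'same' padding requires an odd kernel")
            pad = kernel_size // 2
        self.pad = int(pad)
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (out_channels, in_channels, kernel_size, kernel_size)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Per-channel batch norm; identity at initialization in eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return T.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            training=self.training,
            momentum=self.momentum,
            eps=self.eps,
        )
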