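"""Layer abstractions over the autodiff core: modules, parameters, SGD."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "ModuleList", "Conv2d", "ConvTranspose2x", "BatchNorm2d",
           "ConvBNReLU", "SGD", "kaiming_normal"]


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int, dtype=np.float32) -> np.ndarray:
    """He initialisation for layers followed by a rectifier."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Module:
    """Base class with recursive parameter/buffer traversal.

    Attribute assignment registers :class:`Parameter`, sub-``Module`` and
    :class:`ModuleList` objects automatically, in definition order, which
    makes ``state_dict`` naming deterministic.
    """

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, (Module, ModuleList)):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # -- mode / state ------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({"buffer:" + k: b.copy() for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expected = set(params) | {"buffer:" + k for k in buffers}
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state dict mismatch; missing={sorted(missing)[:5]}, "
                             f"unexpected={sorted(extra)[:5]}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]
        for k, b in buffers.items():
            b[...] = state["buffer:" + k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList:
    """An ordered container of sub-modules (indexable, iterable)."""

    def __init__(self, mods=()):
        self._items: list[Module] = list(mods)

    def append(self, m: Module) -> None:
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._items):
            yield from m.named_parameters(f"{prefix}{i}.")

    def named_buffers(self, prefix: str = ""):
        for i, m in enumerate(self._items):
            yield from m.named_buffers(f"{prefix}{i}.")

    def modules(self):
        for m in self._items:
            yield from m.modules()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size, rng: np.random.Generator,
                 padding=0, dilation=1, bias: bool = True):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if np.isscalar(kernel_size) else kernel_size
        self.in_ch, self.out_ch = in_ch, out_ch
        self.padding, self.dilation = padding, dilation
        fan_in = in_ch * kh * kw
        self.weight = Parameter(kaiming_normal(rng, (out_ch, in_ch, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias,
                        padding=self.padding, dilation=self.dilation)


class ConvTranspose2x(Module):
    """Kernel-2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(kaiming_normal(rng, (in_ch, out_ch, 2, 2), in_ch * 4))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d_2x(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float64))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float64))

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, self.training, self.momentum, self.eps)


class ConvBNReLU(Module):
    """The 3x3 convolution -> batch norm -> rectifier unit used throughout."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 kernel_size: int = 3, dilation: int = 1):
        super().__init__()
        pad = dilation * (kernel_size - 1) // 2
        self.conv = Conv2d(in_ch, out_ch, kernel_size, rng, padding=pad,
                           dilation=dilation, bias=False)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        return F.relu(self.bn(self.conv(x)))


class SGD:
    """Plain stochastic gradient descent, optional momentum / weight decay."""

    def __init__(self, params: list[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params] if momentum else None

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            if self._velocity is not None:
                v = self._velocity[i]
                v *= self.momentum
                v += g
                g = v
            p.data -= self.lr * g
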