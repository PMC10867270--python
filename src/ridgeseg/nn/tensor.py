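"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` plus an optional gradient. Operations
build a DAG of tensors; :meth:`Tensor.backward` walks it in reverse
topological order and accumulates gradients into every tensor with
``requires_grad=True``. Only the operations the segmentation network needs
are implemented (see :mod:`ridgeseg.nn.functional`); this is not a general
deep-learning framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor"]


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward  # closure: reads self.grad, accumulates into parents

    # -- graph -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        """Add ``g`` into this tensor's gradient buffer."""
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (scalar, or pass an explicit seed)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (5 encoder + 4 decoder stages)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))

        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar (heavy ops live in functional.py) -------------------
    def __add__(self, other):
        from . import functional as F

        return F.add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        from . import functional as F

        return F.mul(self, as_tensor(np.asarray(-1.0, dtype=self.data.dtype)))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (always ``requires_grad``)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))
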