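"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps a ``float32`` ndarray together with an optional
gradient and a closure that propagates incoming gradients to its parents.
``backward`` runs a topological sweep over the recorded graph.  The engine
is deliberately small: only the operations needed by the segmentation
networks in this package are implemented (see ``anisoseg.nd.functional``).
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np

DTYPE = np.float32


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype != DTYPE:
        arr = arr.astype(DTYPE)
    return arr


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data: np.ndarray = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad: bool = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward_fn: Optional[Callable[[np.ndarray], None]] = None

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray,
              parents: Sequence["Tensor"],
              backward_fn: Callable[[np.ndarray], None]) -> "Tensor":
        """Create a graph node; records the closure only if a parent needs grad."""
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward_fn = backward_fn
        return out

    def accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=DTYPE, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs are deep for long networks)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p._backward_fn is not None:
                    stack.append((p, False))
                elif id(p) not in visited:
                    visited.add(id(p))
                    topo.append(p)
        self.grad = np.array(grad, dtype=DTYPE, copy=True)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    # -- conveniences ------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # arithmetic sugar; implementations live in functional.py
    def __add__(self, other):
        from . import functional as F
        return F.add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        from . import functional as F
        return F.mul(self, _wrap(other))

    __rmul__ = __mul__

    def __neg__(self):
        from . import functional as F
        return F.scale(self, -1.0)

    def __sub__(self, other):
        from . import functional as F
        return F.add(self, F.scale(_wrap(other), -1.0))

    def __rsub__(self, other):
        from . import functional as F
        return F.add(_wrap(other), F.scale(self, -1.0))

    def __matmul__(self, other):
        from . import functional as F
        return F.matmul(self, _wrap(other))

    def reshape(self, *shape):
        from . import functional as F
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return F.reshape(self, shape)

    def transpose(self, *axes):
        from . import functional as F
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return F.transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        from . import functional as F
        return F.sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        from . import functional as F
        return F.mean_(self, axis=axis, keepdims=keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def unbroadcast(g: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` undoing NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def parameters_of(tensors: Iterable[Tensor]) -> list[Tensor]:
    return [t for t in tensors if t.requires_grad]
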