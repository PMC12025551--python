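"""Tensor type with a dynamic tape for reverse-mode differentiation."""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    """An NCHW (or any-shape) float array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this node.

        ``grad`` defaults to ones (use a scalar loss in practice).
        """
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order of the reachable subgraph
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in visited:
                    stack.append((p, False))

        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not (parent.requires_grad or parent._parents):
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.astype(np.float32, copy=True)
                else:
                    parent.grad += pgrad

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor (leaf node)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def make_op(out_data, parents, backward):
    """Create an op output, attaching the tape only when grad is enabled."""
    track = is_grad_enabled() and any(p.requires_grad or p._parents for p in parents)
    if not track:
        return Tensor(out_data)
    return Tensor(out_data, parents=tuple(parents), backward=backward)
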