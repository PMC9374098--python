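"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Each op builds a :class:`Tensor` holding its forward value and a closure that
propagates the upstream gradient to its parents. Gradients are accumulated by
:func:`backward` in reverse topological order. Everything is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "backward", "constant", "parameter"]


class Tensor:
    """A node in the computation graph: value, gradient and backward closure."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self.parents
        )

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=np.float32)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(data) -> Tensor:
    """A leaf tensor that does not require gradients (network input, target)."""
    return Tensor(data)


def parameter(data) -> Tensor:
    """A trainable leaf tensor."""
    return Tensor(data, requires_grad=True)


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def backward(loss: Tensor) -> None:
    """Backpropagate d(loss)/d(node) into every reachable node's ``grad``.

    ``loss`` must be a scalar tensor. Nodes that do not require gradients are
    skipped entirely.
    """
    if loss.data.size != 1:
        raise ValueError(f"backward requires a scalar loss, got shape {loss.shape}")
    if not loss.requires_grad:
        raise ValueError("loss does not depend on any trainable parameter")
    order = _toposort(loss)
    loss.accumulate(np.ones_like(loss.data))
    for node in reversed(order):
        if node.backward_fn is not None and node.grad is not None:
            node.backward_fn(node.grad)
            # activations are no longer needed once their parents have grads
            node.grad = None if node is not loss else node.grad
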