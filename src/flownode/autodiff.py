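"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the sequential autoencoders in this
package: dense layers, GRU recurrences, Euler-unrolled vector fields and
residual flow stacks.  Every operation builds a node in a DAG; calling
:meth:`Tensor.backward` on a scalar loss topologically sorts the graph and
accumulates vector-Jacobian products into ``.grad`` arrays of the leaves.

Only the primitives the models need are implemented (elementwise arithmetic,
matmul, exp/log/tanh/sigmoid/relu, reductions, slicing, concatenation).
Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack", "as_tensor", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            # scalar fast path: no upcast, no extra graph node for the scalar
            def backward(g):
                return (g,)

            return Tensor._from_op(self.data + other, (self,), backward)
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            def backward(g):
                return (g,)

            return Tensor._from_op(self.data - other, (self,), backward)
        other = as_tensor(other)
        out_data = self.data - other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            def backward(g):
                return (-g,)

            return Tensor._from_op(other - self.data, (self,), backward)
        return as_tensor(other) - self

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def backward(g):
                return (g * other,)

            return Tensor._from_op(self.data * other, (self,), backward)
        other = as_tensor(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        def backward(g):
            return (-g,)

        return Tensor._from_op(-self.data, (self,), backward)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            inv = 1.0 / other

            def backward(g):
                return (g * inv,)

            return Tensor._from_op(self.data * inv, (self,), backward)
        other = as_tensor(other)
        out_data = self.data / other.data
        a, b = self, other

        def backward(g):
            return (
                _unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self, other

        def backward(g):
            return (g @ b.data.T, a.data.T @ g)

        return Tensor._from_op(out_data, (self, other), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src = self

        def backward(g):
            full = np.zeros_like(src.data)
            np.add.at(full, idx, g) if isinstance(idx, np.ndarray) else full.__setitem__(idx, g)
            return (full,)

        return Tensor._from_op(out_data, (self,), backward)

    # -- nonlinearities -------------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            return (g * out_data,)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        src = self

        def backward(g):
            return (g / src.data,)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            return (g * (1.0 - out_data * out_data),)

        return Tensor._from_op(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def backward(g):
            return (g * (out_data > 0),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- reductions & shaping -------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        src_shape = self.data.shape

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, src_shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        src_shape = self.data.shape

        def backward(g):
            return (g.reshape(src_shape),)

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    # -- backward pass --------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)

        # topological order via iterative DFS
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))

        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                # leaf: accumulate into .grad
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
        # leaves visited but with pending grads (parents that are also outputs)
        for node_id, g in grads.items():  # pragma: no cover - defensive
            raise RuntimeError("unconsumed gradient in backward pass")

    def zero_grad(self):
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tensors, backward)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._from_op(out_data, tensors, backward)
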