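"""Minimal reverse-mode automatic differentiation over numpy arrays.

Every backward rule is written in terms of the same differentiable
primitives, so :func:`grad` can be applied to expressions that were
themselves produced by :func:`grad`.  This second-order capability is what
the Wasserstein critic's gradient penalty needs: the penalty is a function
of the critic's input gradient, and its own gradient with respect to the
critic parameters must be available.

The engine is intentionally small: float64 only, dense numpy storage, and
just the operations the package's networks use (affine maps, gated
recurrence, sigmoid/tanh/relu, reductions, stable softplus/logsumexp).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

Array = np.ndarray


class Tensor:
    """A node in the computation graph wrapping a float64 numpy array."""

    __slots__ = ("data", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[["Tensor"], tuple] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return mul(self, power(_wrap(other), -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __pow__(self, p):
        return power(self, float(p))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: Array, parents: tuple[Tensor, ...], backward) -> Tensor:
    rg = any(p.requires_grad for p in parents)
    if not rg:
        return Tensor(data)
    return Tensor(data, requires_grad=True, parents=parents, backward=backward)


def _sum_to_shape(g: Tensor, shape: tuple[int, ...]) -> Tensor:
    """Reduce a broadcast gradient back to ``shape`` (differentiable)."""
    if g.shape == shape:
        return g
    # sum away leading extra axes
    extra = len(g.shape) - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)), keepdims=False)
    # sum axes where target dim is 1
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# --- primitives ----------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g: Tensor):
        return _sum_to_shape(g, a.shape), _sum_to_shape(g, b.shape)

    return _make(out_data, (a, b), backward)


def neg(a: Tensor) -> Tensor:
    return _make(-a.data, (a,), lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g: Tensor):
        return _sum_to_shape(mul(g, b), a.shape), _sum_to_shape(mul(g, a), b.shape)

    return _make(out_data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data**p

    def backward(g: Tensor):
        return (mul(g, mul(Tensor(p), power(a, p - 1.0))),)

    return _make(out_data, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g: Tensor):
        return matmul(g, transpose(b)), matmul(transpose(a), g)

    return _make(out_data, (a, b), backward)


def transpose(a: Tensor) -> Tensor:
    return _make(a.data.T, (a,), lambda g: (transpose(g),))


def reshape(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    orig = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (reshape(g, orig),))


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: Tensor):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * a.data.ndim), a.shape),)
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        if not keepdims:
            kshape = list(a.shape)
            for ax in axes:
                kshape[ax % a.data.ndim] = 1
            g = reshape(g, tuple(kshape))
        return (broadcast_to(g, a.shape),)

    return _make(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax % a.data.ndim] for ax in ((axis,) if isinstance(axis, int) else axis)]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / float(n)))


def broadcast_to(a: Tensor, shape: tuple[int, ...]) -> Tensor:
    out_data = np.broadcast_to(a.data, shape).copy()
    return _make(out_data, (a,), lambda g: (_sum_to_shape(g, a.shape),))


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Tensor):
        grads = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.data.ndim
            idx[axis] = slice(int(lo), int(hi))
            grads.append(getitem(g, tuple(idx)))
        return tuple(grads)

    return _make(out_data, tuple(tensors), backward)


def getitem(a: Tensor, idx) -> Tensor:
    out_data = a.data[idx]

    def backward(g: Tensor):
        return (scatter(g, a.shape, idx),)

    return _make(out_data, (a,), backward)


def scatter(g: Tensor, shape: tuple[int, ...], idx) -> Tensor:
    """Place ``g`` into a zero array of ``shape`` at ``idx`` (adjoint of getitem)."""
    out_data = np.zeros(shape)
    parts = idx if isinstance(idx, tuple) else (idx,)
    if all(isinstance(p, (slice, int)) for p in parts):
        out_data[idx] = g.data  # basic indexing never aliases
    else:
        np.add.at(out_data, idx, g.data)

    def backward(gg: Tensor):
        return (getitem(gg, idx),)

    return _make(out_data, (g,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out._backward = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: (mul(g, power(a, -1.0)),))


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out._backward = lambda g: (mul(g, mul(Tensor(0.5), power(a, -0.5))),)
    return out


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out._backward = lambda g: (mul(g, add(Tensor(1.0), neg(mul(out, out)))),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    out_data = 0.5 * (np.tanh(0.5 * a.data) + 1.0)  # stable
    out = _make(out_data, (a,), None)
    if out.requires_grad:
        out._backward = lambda g: (mul(g, mul(out, add(Tensor(1.0), neg(out)))),)
    return out


def relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(np.float64)
    return _make(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(a)), numerically stable; derivative is sigmoid(a)."""
    sign = Tensor(np.where(a.data >= 0, 1.0, -1.0))  # piecewise-constant
    absa = mul(a, sign)
    return add(log(add(Tensor(1.0), exp(neg(absa)))), relu(a))


def logsumexp(a: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(np.max(a.data, axis=axis, keepdims=True))  # constant shift
    shifted = add(a, neg(broadcast_to(m, a.shape)))
    lse = log(tsum(exp(shifted), axis=axis, keepdims=True))
    out = add(lse, m)
    return tsum(out, axis=axis)  # drop the kept dim


# --- gradient driver ------------------------------------------------------


def _topo(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
) -> tuple[Tensor, ...]:
    """Gradients of ``output.sum()`` with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own
    computation graph and can be differentiated again.
    """
    inputs = list(inputs)
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(_topo(output)):
        g = grads.pop(id(node), None)
        if g is None or node._backward is None:
            if g is not None and id(node) not in {id(t) for t in inputs}:
                continue
            if g is not None:
                grads[id(node)] = g
            continue
        # keep the grad available for inputs that are also interior nodes
        if id(node) in {id(t) for t in inputs}:
            grads[id(node)] = g
        parent_grads = node._backward(g)
        for p, pg in zip(node._parents, parent_grads):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg
    out = []
    for t in inputs:
        g = grads.get(id(t))
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        if not create_graph:
            g = g.detach()
        out.append(g)
    return tuple(out)
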