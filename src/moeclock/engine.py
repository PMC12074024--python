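"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-free autodiff core: every operation returns a
:class:`Tensor` carrying its parents and a vector-Jacobian-product closure.
The closures are themselves written in terms of these same operations, so a
gradient produced with ``create_graph=True`` is an ordinary differentiable
node — which is exactly what training through a saliency-dependent penalty
requires (the objective contains gradients of the network output with
respect to its input, and parameter updates need gradients of *that*).

Only the primitives the aging-clock model needs are implemented: affine
maps, elementwise arithmetic, reductions, ReLU/abs/exp/log/sqrt, indexing
with its scatter adjoint, and broadcasting.  Piecewise-constant factors
(ReLU masks, sign of |x|, top-k selections) are treated as constants of the
differentiation, which is the almost-everywhere-correct convention.
"""
from __future__ import annotations

import contextlib

import numpy as np

# Graph recording can be suspended (e.g. during a plain backward pass that
# will not itself be differentiated) to avoid building unused graph nodes.
_GRAPH: list[bool] = [True]


@contextlib.contextmanager
def no_graph():
    """Context manager: operations inside produce constant tensors."""
    _GRAPH.append(False)
    try:
        yield
    finally:
        _GRAPH.pop()


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "parents", "vjp")

    def __init__(self, data, requires_grad=False, parents=(), vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.parents = parents
        self.vjp = vjp

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(astensor(other)))

    def __rsub__(self, other):
        return add(astensor(other), neg(self))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(astensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, key):
        return getitem(self, key)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, vjp) -> Tensor:
    """Create a graph node, or a constant if recording is off / not needed."""
    if _GRAPH[-1] and any(p.requires_grad for p in parents):
        return Tensor(data, True, tuple(parents), vjp)
    return Tensor(data)


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.data.shape == shape:
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(
        i for i, (have, want) in enumerate(zip(g.data.shape, shape)) if want == 1 and have != 1
    )
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.data.shape != shape:
        g = reshape(g, shape)
    return g


# -- primitives ------------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(a.data + b.data, (a, b), vjp)


def neg(a):
    a = astensor(a)

    def vjp(g):
        return (neg(g),)

    return _node(-a.data, (a,), vjp)


def mul(a, b):
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.data.shape), _unbroadcast(mul(g, a), b.data.shape)

    return _node(a.data * b.data, (a, b), vjp)


def div(a, b):
    a, b = astensor(a), astensor(b)

    def vjp(g):
        ga = _unbroadcast(div(g, b), a.data.shape)
        gb = _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.data.shape)
        return ga, gb

    return _node(a.data / b.data, (a, b), vjp)


def matmul(a, b):
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return matmul(g, transpose(b)), matmul(transpose(a), g)

    return _node(a.data @ b.data, (a, b), vjp)


def transpose(a, axes=None):
    a = astensor(a)
    if axes is None:
        axes_eff = tuple(range(a.data.ndim))[::-1]
    else:
        axes_eff = tuple(axes)
    inv = tuple(np.argsort(axes_eff))

    def vjp(g):
        return (transpose(g, inv),)

    return _node(np.transpose(a.data, axes_eff), (a,), vjp)


def reshape(a, shape):
    a = astensor(a)
    old = a.data.shape

    def vjp(g):
        return (reshape(g, old),)

    return _node(a.data.reshape(shape), (a,), vjp)


def broadcast_to(a, shape):
    a = astensor(a)
    old = a.data.shape

    def vjp(g):
        return (_unbroadcast(g, old),)

    return _node(np.broadcast_to(a.data, shape).copy(), (a,), vjp)


def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    old = a.data.shape
    if axis is None:
        ax = tuple(range(a.data.ndim))
    elif isinstance(axis, int):
        ax = (axis % a.data.ndim,)
    else:
        ax = tuple(i % a.data.ndim for i in axis)

    def vjp(g):
        if not keepdims:
            kept = list(old)
            for i in ax:
                kept[i] = 1
            g = reshape(g, tuple(kept))
        return (broadcast_to(g, old),)

    return _node(np.sum(a.data, axis=ax if axis is not None else None, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = astensor(a)
    if axis is None:
        n = a.data.size
    elif isinstance(axis, int):
        n = a.data.shape[axis]
    else:
        n = int(np.prod([a.data.shape[i] for i in axis]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def power(a, p):
    a = astensor(a)
    p = float(p)

    def vjp(g):
        return (mul(g, mul(p, power(a, p - 1.0))),)

    return _node(a.data ** p, (a,), vjp)


def sqrt(a):
    a = astensor(a)
    out_data = np.sqrt(a.data)

    def vjp(g):
        return (div(g, mul(2.0, Tensor(out_data) if not a.requires_grad else sqrt(a))),)

    # Re-deriving sqrt(a) in the closure keeps the node differentiable;
    # cheap relative to the matmuls that dominate.
    return _node(out_data, (a,), vjp)


def texp(a):
    a = astensor(a)

    def vjp(g):
        return (mul(g, texp(a)),)

    return _node(np.exp(a.data), (a,), vjp)


def tlog(a):
    a = astensor(a)

    def vjp(g):
        return (div(g, a),)

    return _node(np.log(a.data), (a,), vjp)


def tabs(a):
    a = astensor(a)
    sign = np.sign(a.data)

    def vjp(g):
        return (mul(g, Tensor(sign)),)

    return _node(np.abs(a.data), (a,), vjp)


def relu(a):
    a = astensor(a)
    mask = (a.data > 0).astype(np.float64)

    def vjp(g):
        return (mul(g, Tensor(mask)),)

    return _node(a.data * mask, (a,), vjp)


def getitem(a, key):
    a = astensor(a)
    shape = a.data.shape

    def vjp(g):
        return (scatter(g, key, shape),)

    return _node(a.data[key], (a,), vjp)


def scatter(g, key, shape):
    """Adjoint of ``getitem``: place ``g`` at ``key`` in a zero array."""
    g = astensor(g)
    z = np.zeros(shape, dtype=np.float64)
    np.add.at(z, key, g.data)

    def vjp(gg):
        return (getitem(gg, key),)

    return _node(z, (g,), vjp)


def softmax(logits, axis=-1):
    """Numerically stable softmax; the max shift is a constant of the graph."""
    logits = astensor(logits)
    shift = Tensor(np.max(logits.data, axis=axis, keepdims=True))
    e = texp(logits - shift)
    return div(e, tsum(e, axis=axis, keepdims=True))


# -- reverse pass ----------------------------------------------------------

def grad(output: Tensor, wrt, create_graph: bool = False):
    """Gradients of scalar ``output`` with respect to each tensor in ``wrt``.

    Returns a list of Tensors aligned with ``wrt``.  With
    ``create_graph=True`` the returned tensors are differentiable graph
    nodes, enabling higher-order derivatives.
    """
    wrt = list(wrt)
    if output.data.size != 1:
        raise ValueError("grad expects a scalar output")

    # Iterative post-order topological sort over requires_grad nodes.
    topo: list[Tensor] = []
    visited = {id(output)}
    stack: list[tuple[Tensor, object]] = [(output, iter(output.parents))]
    while stack:
        node, it = stack[-1]
        advanced = False
        for p in it:
            if p.requires_grad and id(p) not in visited:
                visited.add(id(p))
                stack.append((p, iter(p.parents)))
                advanced = True
                break
        if not advanced:
            topo.append(node)
            stack.pop()

    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    ctx = contextlib.nullcontext() if create_graph else no_graph()
    with ctx:
        for node in reversed(topo):
            g = grads.get(id(node))
            if g is None or node.vjp is None:
                continue
            for parent, pg in zip(node.parents, node.vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = add(grads[id(parent)], pg)
                else:
                    grads[id(parent)] = pg
    return [grads.get(id(w), Tensor(np.zeros_like(w.data))) for w in wrt]
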