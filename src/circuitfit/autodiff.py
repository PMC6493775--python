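"""Minimal reverse-mode automatic differentiation on numpy arrays.

The trainers in this package need three things no pre-installed library
provides together: reverse-mode gradients of scalar losses w.r.t. a handful
of parameter tensors, backpropagation through a few hundred Euler steps of a
rate network, and *second-order* gradients for the WGAN gradient penalty
(gradient of the critic's input-gradient norm w.r.t. the critic weights).

Every primitive's backward rule is itself expressed in terms of the same
primitives, so gradients are graph nodes and can be differentiated again
(``grad(..., create_graph=True)``).  The surface is intentionally small:
only the operations the generators, critics and losses actually use.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "constant",
    "parameter",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "power",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "relu",
    "absolute",
    "where",
    "matmul",
    "tsum",
    "tmean",
    "reshape",
    "swapaxes",
    "broadcast_to",
    "getitem",
    "concatenate",
    "grad",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad=False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    @property
    def T(self):
        return swapaxes(self, -1, -2)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(np.asarray(x, dtype=np.float64))


def parameter(x) -> Tensor:
    """A leaf tensor tracked by ``grad``."""
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def _node(data, parents, vjp):
    parents = tuple(parents)
    if any(p.requires_grad for p in parents):
        return Tensor(data, True, parents, vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers (expressed with graph ops so they stay differentiable)
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a broadcast cotangent back to ``shape``."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(neg(g), b.shape)),
    )


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _node(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(div(g, b), a.shape),
            _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def neg(a):
    a = as_tensor(a)
    return _node(-a.data, (a,), lambda g: (neg(g),))


def power(a, p):
    """Elementwise ``a ** p`` for a *constant* float exponent.

    The backward rule multiplies by ``p * a**(p-1)``; callers are expected to
    keep the base non-negative when ``p`` is fractional (the saturating
    nonlinearity rectifies before exponentiating).
    """
    a = as_tensor(a)
    p = float(p)

    if p < 1:
        # derivative blows up at 0; clamp it there (not twice-differentiable)
        def vjp(g):
            safe = np.where(a.data == 0.0, 1.0, a.data)
            deriv = np.where(a.data == 0.0, 0.0, p * np.power(safe, p - 1.0))
            return (mul(g, Tensor(deriv)),)

        return _node(np.power(a.data, p), (a,), vjp)

    return _node(
        np.power(a.data, p),
        (a,),
        lambda g: (mul(g, mul(constant(p), power(a, p - 1.0))),),
    )


def exp(a):
    a = as_tensor(a)
    out = _node(np.exp(a.data), (a,), None)
    out._vjp = lambda g: (mul(g, out),)
    return out


def log(a):
    a = as_tensor(a)
    return _node(np.log(a.data), (a,), lambda g: (div(g, a),))


def sqrt(a):
    a = as_tensor(a)
    out = _node(np.sqrt(a.data), (a,), None)
    out._vjp = lambda g: (div(g, mul(constant(2.0), out)),)
    return out


def tanh(a):
    a = as_tensor(a)
    out = _node(np.tanh(a.data), (a,), None)
    out._vjp = lambda g: (mul(g, sub(constant(1.0), mul(out, out))),)
    return out


def sigmoid(a):
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        val = np.where(
            a.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(a.data))),
            np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))),
        )
    out = _node(val, (a,), None)
    out._vjp = lambda g: (mul(g, mul(out, sub(constant(1.0), out))),)
    return out


def relu(a):
    a = as_tensor(a)
    mask = (a.data > 0).astype(np.float64)
    return _node(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def absolute(a):
    a = as_tensor(a)
    sign = np.sign(a.data)
    return _node(np.abs(a.data), (a,), lambda g: (mul(g, Tensor(sign)),))


def where(cond, a, b):
    """``cond`` is a plain boolean array, not differentiated."""
    a, b = as_tensor(a), as_tensor(b)
    c = np.asarray(cond, dtype=bool)
    cf = c.astype(np.float64)
    return _node(
        np.where(c, a.data, b.data),
        (a, b),
        lambda g: (
            _unbroadcast(mul(g, Tensor(cf)), a.shape),
            _unbroadcast(mul(g, Tensor(1.0 - cf)), b.shape),
        ),
    )


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def vjp(g):
        ga = matmul(g, swapaxes(b, -1, -2))
        gb = matmul(swapaxes(a, -1, -2), g)
        if ga.shape != a.shape:
            ga = _unbroadcast(ga, a.shape)
        if gb.shape != b.shape:
            gb = _unbroadcast(gb, b.shape)
        return ga, gb

    return _node(np.matmul(a.data, b.data), (a, b), vjp)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)

    def vjp(g):
        if axis is None:
            return (broadcast_to(reshape(g, (1,) * a.ndim), a.shape),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % a.ndim for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else n for i, n in enumerate(a.shape))
            g = reshape(g, kshape)
        return (broadcast_to(g, a.shape),)

    return _node(np.sum(a.data, axis=axis, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return div(tsum(a, axis=axis, keepdims=keepdims), constant(float(n)))


def reshape(a, shape):
    a = as_tensor(a)
    old = a.shape
    return _node(
        a.data.reshape(shape), (a,), lambda g: (reshape(g, old),)
    )


def swapaxes(a, ax1, ax2):
    a = as_tensor(a)
    return _node(
        np.swapaxes(a.data, ax1, ax2), (a,), lambda g: (swapaxes(g, ax1, ax2),)
    )


def broadcast_to(a, shape):
    a = as_tensor(a)
    shape = tuple(shape)
    return _node(
        np.broadcast_to(a.data, shape).copy(),
        (a,),
        lambda g: (_unbroadcast(g, a.shape),),
    )


def getitem(a, idx):
    a = as_tensor(a)
    return _node(a.data[idx], (a,), lambda g: (_scatter(g, idx, a.shape),))


def _scatter(g, idx, shape):
    g = as_tensor(g)

    def vjp(gg):
        return (getitem(gg, idx),)

    out = np.zeros(shape, dtype=np.float64)
    np.add.at(out, idx, g.data)
    return _node(out, (g,), vjp)


def concatenate(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(lo), int(hi))
            outs.append(getitem(g, tuple(idx)))
        return tuple(outs)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, vjp)


# ---------------------------------------------------------------------------
# reverse pass
# ---------------------------------------------------------------------------

def _topo(out: Tensor):
    order, seen = [], set()
    stack = [(out, False)]
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


def grad(out: Tensor, wrt, create_graph=False):
    """Gradients of a scalar ``out`` w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned gradients are themselves graph
    nodes, so they can be fed back into ``grad`` (used for the WGAN
    gradient penalty).
    """
    if out.size != 1:
        raise ValueError("grad expects a scalar output; reduce it first")
    single = isinstance(wrt, Tensor)
    wrt_list = [wrt] if single else list(wrt)

    grads = {id(out): broadcast_to(constant(np.ones(())), out.shape)}
    for node in reversed(_topo(out)):
        g = grads.get(id(node))
        if g is None or node._vjp is None:
            continue
        for p, pg in zip(node._parents, node._vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg

    results = []
    for w in wrt_list:
        g = grads.get(id(w))
        if g is None:
            g = constant(np.zeros(w.shape))
        elif g.shape != w.shape:
            g = reshape(g, w.shape)
        if not create_graph:
            g = g.detach()
        results.append(g)
    return results[0] if single else results
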