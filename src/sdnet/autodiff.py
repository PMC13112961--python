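"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery to express and train the CNN-LSTM decoder on a CPU:
broadcast-aware elementwise ops, batched matmul, a two-operand ``einsum``,
sliding-window views (with scatter-add backward), batch normalisation as a
fused primitive, and the usual activations.  Gradients are accumulated by a
topological sweep over the recorded tape.

Design notes: data is kept in whatever dtype the caller supplies (the decoder
uses float32 throughout); sliding windows are as_strided views so the forward
pass never materialises the window redundancy.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "add", "sub", "mul", "matmul", "einsum2", "relu", "sigmoid",
           "tanh", "square", "reduce_mean", "reduce_sum", "reshape", "transpose",
           "narrow", "stack_last", "sliding_windows", "batch_norm", "backward"]


class Tensor:
    """A node in the computation graph wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared", "name")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward: Optional[Callable] = None,
                 name: str = ""):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward
        self._grad_shared = False
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        # first contribution adopts the array by reference (flagged shared so a
        # later contribution copies before mutating); avoids a zeros pass per node
        if self.grad is None:
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def grad_buffer(self) -> np.ndarray:
        """An owned, writable gradient buffer (for in-place scatter backward)."""
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
            self._grad_shared = False
        elif self._grad_shared:
            self.grad = self.grad.copy()
            self._grad_shared = False
        return self.grad

    def zero_grad(self) -> None:
        self.grad = None
        self._grad_shared = False

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}, name={self.name!r})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*ts: Tensor) -> bool:
    return any(t.requires_grad for t in ts)


def _reduce_middle(g: np.ndarray, axes: tuple) -> np.ndarray:
    """Sum over a contiguous middle run of axes via einsum (fast for large g)."""
    lead = int(np.prod(g.shape[:axes[0]], dtype=int))
    mid = int(np.prod([g.shape[a] for a in axes], dtype=int))
    chan = int(np.prod(g.shape[axes[-1] + 1:], dtype=int))
    g3 = np.ascontiguousarray(g).reshape(lead, mid, chan)
    out = np.einsum("rnc->rc", g3)
    shape = list(g.shape)
    for a in axes:
        shape[a] = 1
    return out.reshape(shape)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        if len(axes) > 1 and axes == tuple(range(axes[0], axes[-1] + 1)) and g.size > 1 << 20:
            g = _reduce_middle(g, axes)
        else:
            g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a: Tensor, b: Tensor, out: np.ndarray,
            da: Callable[[np.ndarray], np.ndarray],
            db: Callable[[np.ndarray], np.ndarray]) -> Tensor:
    req = _needs(a, b)

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(_unbroadcast(da(g), a.data.shape).astype(a.data.dtype, copy=False))
        if b.requires_grad:
            b.accumulate(_unbroadcast(db(g), b.data.shape).astype(b.data.dtype, copy=False))

    return Tensor(out, req, (a, b), bwd if req else None)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def add_(a: Tensor, b: Tensor) -> Tensor:
    """In-place broadcast add, consuming ``a``'s buffer (``a`` must be a
    single-consumer intermediate, e.g. a fresh einsum output)."""
    a, b = _as_tensor(a), _as_tensor(b)
    a.data += b.data
    return _binary(a, b, a.data, lambda g: g, lambda g: g)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data @ b.data
    return _binary(a, b, out,
                   lambda g: g @ np.swapaxes(b.data, -1, -2),
                   lambda g: np.swapaxes(a.data, -1, -2) @ g)


def einsum2(subscripts: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum whose gradients are themselves einsums.

    Every index of each input must appear in the output or in the other input
    (no internal sums within a single operand), which holds for all uses here.
    """
    a, b = _as_tensor(a), _as_tensor(b)
    lhs, out_sub = subscripts.split("->")
    in0, in1 = lhs.split(",")
    for sub_i, other in ((in0, in1), (in1, in0)):
        assert set(sub_i) <= set(out_sub) | set(other), subscripts
    out = np.einsum(subscripts, a.data, b.data, optimize=True)
    if not out.flags.c_contiguous:
        out = np.ascontiguousarray(out)   # downstream fused ops need C order
    req = _needs(a, b)

    def bwd(g: np.ndarray) -> None:
        if a.requires_grad:
            ga = np.einsum(f"{out_sub},{in1}->{in0}", g, b.data, optimize=True)
            a.accumulate(ga.astype(a.data.dtype, copy=False))
        if b.requires_grad:
            gb = np.einsum(f"{out_sub},{in0}->{in1}", g, a.data, optimize=True)
            b.accumulate(gb.astype(b.data.dtype, copy=False))

    return Tensor(out, req, (a, b), bwd if req else None)


def _unary(a: Tensor, out: np.ndarray, da: Callable[[np.ndarray], np.ndarray]) -> Tensor:
    req = a.requires_grad

    def bwd(g: np.ndarray) -> None:
        a.accumulate(da(g).astype(a.data.dtype, copy=False))

    return Tensor(out, req, (a,), bwd if req else None)


def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = np.maximum(a.data, 0)
    return _unary(a, out, lambda g: g * (a.data > 0))


def sigmoid(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _unary(a, out, lambda g: g * out * (1.0 - out))


def tanh(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out = np.tanh(a.data)
    return _unary(a, out, lambda g: g * (1.0 - out * out))


def square(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    return _unary(a, a.data * a.data, lambda g: g * 2.0 * a.data)


def reduce_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def da(g: np.ndarray) -> np.ndarray:
        if axis is None:
            return np.broadcast_to(g, a.data.shape)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g2, a.data.shape)

    return _unary(a, out, da)


def reduce_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size / out.size

    def da(g: np.ndarray) -> np.ndarray:
        if axis is None:
            return np.broadcast_to(g / n, a.data.shape)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return np.broadcast_to(g2 / n, a.data.shape)

    return _unary(a, out, da)


def reshape(a: Tensor, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.data.shape
    return _unary(a, a.data.reshape(shape), lambda g: g.reshape(old))


def transpose(a: Tensor, axes) -> Tensor:
    a = _as_tensor(a)
    inv = np.argsort(axes)
    return _unary(a, np.transpose(a.data, axes), lambda g: np.transpose(g, inv))


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    """Slice ``length`` elements from ``start`` along ``axis``."""
    a = _as_tensor(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    req = a.requires_grad

    def bwd(g: np.ndarray) -> None:
        # scatter straight into the parent's buffer: cheap for repeated slicing
        a.grad_buffer()[idx] += g

    return Tensor(a.data[idx], req, (a,), bwd if req else None)


def stack_last(tensors: Sequence[Tensor], axis: int) -> Tensor:
    """Stack equal-shaped tensors along a new axis (LSTM time axis)."""
    out = np.stack([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)

    def bwd(g: np.ndarray) -> None:
        parts = np.moveaxis(g, axis, 0)
        for t, gi in zip(tensors, parts):
            if t.requires_grad:
                t.accumulate(gi.astype(t.data.dtype, copy=False))

    return Tensor(out, req, tuple(tensors), bwd if req else None)


def sliding_windows(a: Tensor, axis: int, length: int) -> Tensor:
    """All contiguous windows of ``length`` along ``axis`` as a strided view.

    Output inserts a window-offset axis of size ``length`` directly after
    ``axis``; the windowed axis shrinks to ``n - length + 1``.  Backward
    scatter-adds window gradients back onto the series.
    """
    a = _as_tensor(a)
    x = a.data
    n = x.shape[axis]
    t = n - length + 1
    if t <= 0:
        raise ValueError(f"series of length {n} too short for windows of {length}")
    view = np.lib.stride_tricks.sliding_window_view(x, length, axis=axis)
    # sliding_window_view appends the window axis; move it next to `axis`
    view = np.moveaxis(view, -1, axis + 1)

    def da(g: np.ndarray) -> np.ndarray:
        full = np.zeros_like(x)
        mov = np.moveaxis(full, axis, 0)                # (n, ...)
        gk = np.moveaxis(g, (axis, axis + 1), (0, 1))   # (t, k, ...)
        for k in range(length):
            mov[k:k + t] += gk[:, k]
        return full

    return _unary(a, view, da)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
               running: Optional[dict] = None, momentum: float = 0.1,
               eps: float = 1e-5, training: bool = True) -> Tensor:
    """Batch normalisation as a fused primitive.

    ``axes`` are the reduction axes (batch/time/lag); ``gamma``/``beta`` must
    broadcast against ``x``.  In training mode batch statistics are used and,
    when a ``running`` dict with keys ``mean``/``var`` is supplied, its
    exponential moving averages are updated in place.  In evaluation mode the
    running statistics are used and no update occurs.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    # contiguous-middle reduction -> einsum-fused statistics (large tensors)
    fast = axes == tuple(range(axes[0], axes[-1] + 1)) and axes[0] >= 1
    lead = int(np.prod(x.data.shape[:axes[0]], dtype=int)) if fast else 0
    mid = int(np.prod([x.data.shape[a] for a in axes], dtype=int)) if fast else 0
    chan = x.data.size // max(lead * mid, 1) if fast else 0
    kshape = tuple(1 if i in axes else s for i, s in enumerate(x.data.shape))

    def stats3(arr: np.ndarray) -> np.ndarray:
        return np.einsum("rnc->rc", arr.reshape(lead, mid, chan)).reshape(kshape)

    def dot3(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        return np.einsum("rnc,rnc->rc", a1.reshape(lead, mid, chan),
                         a2.reshape(lead, mid, chan)).reshape(kshape)

    if training:
        if fast and x.data.flags.c_contiguous:
            mean = stats3(x.data) / mid
            var = np.maximum(dot3(x.data, x.data) / mid - mean * mean, 0.0)
        else:
            fast = False
            mean = x.data.mean(axis=axes, keepdims=True)
            var = np.maximum((x.data * x.data).mean(axis=axes, keepdims=True)
                             - mean * mean, 0.0)
        if running is not None:
            running["mean"] *= (1.0 - momentum)
            running["mean"] += momentum * mean
            running["var"] *= (1.0 - momentum)
            running["var"] += momentum * var
    else:
        if running is None:
            raise ValueError("evaluation-mode batch_norm requires running statistics")
        mean, var = running["mean"], running["var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    scale = (gamma.data * inv_std).astype(x.data.dtype)
    out = x.data * scale
    out += (beta.data - mean * scale).astype(x.data.dtype)
    req = _needs(x, gamma, beta)

    def bwd(g: np.ndarray) -> None:
        if fast and training and g.flags.c_contiguous:
            sum_g = stats3(g)
            sum_gx = dot3(g, x.data)
            # sum of g * xhat, without materialising xhat
            sum_gxh = (sum_gx - mean * sum_g) * inv_std
            if gamma.requires_grad:
                gamma.accumulate(_unbroadcast(sum_gxh, gamma.data.shape).astype(gamma.data.dtype).reshape(gamma.data.shape))
            if beta.requires_grad:
                beta.accumulate(_unbroadcast(sum_g, beta.data.shape).astype(beta.data.dtype).reshape(beta.data.shape))
            if x.requires_grad:
                # gx = scale*(g - sum_g/N - xhat*sum_gxh/N) = a*g + b*x + c
                a = scale
                b = (-scale * inv_std * sum_gxh / mid).astype(x.data.dtype)
                c = (-scale * (sum_g - sum_gxh * mean * inv_std) / mid).astype(x.data.dtype)
                gx = g * a
                gx += x.data * b
                gx += c
                x.accumulate(gx)
            return
        xhat = None
        if gamma.requires_grad or (x.requires_grad and training):
            xhat = x.data * inv_std
            xhat -= mean * inv_std
        if gamma.requires_grad:
            gamma.accumulate(_unbroadcast((g * xhat), gamma.data.shape).astype(gamma.data.dtype, copy=False))
        if beta.requires_grad:
            beta.accumulate(_unbroadcast(g, beta.data.shape).astype(beta.data.dtype, copy=False))
        if x.requires_grad:
            if training:
                gg = g * gamma.data
                m1 = gg.mean(axis=axes, keepdims=True)
                m2 = (gg * xhat).mean(axis=axes, keepdims=True)
                gg -= m1
                gg -= xhat * m2
                gg *= inv_std
                gx = gg
            else:
                gx = g * scale
            x.accumulate(gx.astype(x.data.dtype, copy=False))

    return Tensor(out, req, (x, gamma, beta), bwd if req else None)


def batch_norm_relu(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple,
                    running: Optional[dict] = None, momentum: float = 0.1,
                    eps: float = 1e-5, training: bool = True) -> Tensor:
    """Fused ``relu(batch_norm(x))`` for large contiguous-middle reductions.

    Functionally identical to ``relu(batch_norm(...))`` but with one output
    buffer and einsum-fused statistics; the rectifier mask is recovered from
    the output sign in backward.  Falls back to the composed ops when the
    reduction axes are not a contiguous middle run.
    """
    fast = (axes == tuple(range(axes[0], axes[-1] + 1)) and axes[0] >= 1
            and x.data.flags.c_contiguous)
    if not fast:
        return relu(batch_norm(x, gamma, beta, axes, running, momentum, eps, training))
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    lead = int(np.prod(x.data.shape[:axes[0]], dtype=int))
    mid = int(np.prod([x.data.shape[a] for a in axes], dtype=int))
    chan = x.data.size // (lead * mid)
    kshape = tuple(1 if i in axes else s for i, s in enumerate(x.data.shape))

    def stats3(arr: np.ndarray) -> np.ndarray:
        return np.einsum("rnc->rc", arr.reshape(lead, mid, chan)).reshape(kshape)

    def dot3(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
        return np.einsum("rnc,rnc->rc", a1.reshape(lead, mid, chan),
                         a2.reshape(lead, mid, chan)).reshape(kshape)

    if training:
        mean = stats3(x.data) / mid
        var = np.maximum(dot3(x.data, x.data) / mid - mean * mean, 0.0)
        if running is not None:
            running["mean"] *= (1.0 - momentum)
            running["mean"] += momentum * mean
            running["var"] *= (1.0 - momentum)
            running["var"] += momentum * var
    else:
        if running is None:
            raise ValueError("evaluation-mode batch_norm requires running statistics")
        mean, var = running["mean"], running["var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    scale = (gamma.data * inv_std).astype(x.data.dtype)
    shift = (beta.data - mean * scale).astype(x.data.dtype)
    y = x.data * scale
    y += shift
    np.maximum(y, 0, out=y)
    req = _needs(x, gamma, beta)

    def bwd(g: np.ndarray) -> None:
        gm = np.where(y > 0, g, x.data.dtype.type(0))
        sum_g = stats3(gm)
        sum_gx = dot3(gm, x.data)
        sum_gxh = (sum_gx - mean * sum_g) * inv_std
        if gamma.requires_grad:
            gamma.accumulate(_unbroadcast(sum_gxh, gamma.data.shape).astype(gamma.data.dtype).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta.accumulate(_unbroadcast(sum_g, beta.data.shape).astype(beta.data.dtype).reshape(beta.data.shape))
        if x.requires_grad:
            if training:
                b = (-scale * inv_std * sum_gxh / mid).astype(x.data.dtype)
                c = (-scale * (sum_g - sum_gxh * mean * inv_std) / mid).astype(x.data.dtype)
                gm *= scale
                gm += x.data * b
                gm += c
            else:
                gm *= scale
            x.accumulate(gm)

    return Tensor(y, req, (x, gamma, beta), bwd if req else None)


def backward(loss: Tensor) -> None:
    """Reverse sweep from a scalar loss, accumulating ``.grad`` on the tape."""
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    loss.grad = np.ones_like(loss.data)
    for node in reversed(order):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
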