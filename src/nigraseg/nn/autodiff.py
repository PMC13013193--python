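"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the segmentation networks: a tape-based
autodiff engine with exactly the operators an encoder-decoder CNN needs
(broadcasted arithmetic, ReLU/sigmoid, reductions, concatenation, N-D
convolution via im2col, nearest/linear 2x upsampling and spatial dropout).
Convolutions are dimension-agnostic, so the same code drives the 3D SN
network and the 2D midbrain network. Everything is float32.

Gradient correctness of each primitive is pinned by finite-difference
checks in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference / validation passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array with an optional backward tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward = None
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this (scalar or seeded) node."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs are deep for big U-Nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=False)
                else:
                    parent.grad = parent.grad + g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(isinstance(p, Tensor) for p in parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape))
                 if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _node(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def sub(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _node(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape),
                            _unbroadcast(-g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _node(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.shape),
                            _unbroadcast(g * a.data, b.shape)))


def div(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    return _node(a.data / b.data, (a, b),
                 lambda g: (_unbroadcast(g / b.data, a.shape),
                            _unbroadcast(-g * a.data / b.data ** 2, b.shape)))


def pow_(a, p: float) -> Tensor:
    a = _wrap(a)
    return _node(a.data ** p, (a,),
                 lambda g: (g * p * a.data ** (p - 1),))


def sqrt(a) -> Tensor:
    return pow_(a, 0.5)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: (g * mask,))


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    return _node(y, (a,), lambda g: (g * y * (1.0 - y),))


def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        return (np.broadcast_to(gg, a.shape).copy(),)

    return _node(out, (a,), backward)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)
    n = a.data.size if axis is None else \
        np.prod([a.shape[ax] for ax in np.atleast_1d(axis)])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


def _stride_slices(d: int, stride: int):
    return (slice(None), slice(None)) + (slice(None, None, stride),) * d


def _im2col(xp: np.ndarray, kernel: tuple, stride: int):
    """(N,C,*Sp) -> (N, P, C*prod(k)) patch matrix plus output spatial shape."""
    d = len(kernel)
    win = sliding_window_view(xp, kernel, axis=tuple(range(2, 2 + d)))
    if stride > 1:
        win = win[(slice(None), slice(None))
                  + (slice(None, None, stride),) * d]
    n, c = win.shape[:2]
    out_spatial = win.shape[2:2 + d]
    # (N,C,*So,*K) -> (N,*So,C,*K) -> (N,P,C*K)
    perm = (0,) + tuple(range(2, 2 + d)) + (1,) + tuple(range(2 + d, 2 + 2 * d))
    cols = win.transpose(perm).reshape(n, int(np.prod(out_spatial)), -1)
    return cols, out_spatial


def convnd(x, w, b, stride: int = 1, pad: int | None = None) -> Tensor:
    """N-D convolution (cross-correlation): x (N,Cin,*S), w (Cout,Cin,*K).

    ``pad`` defaults to (k-1)//2 ("same" output for stride 1, odd kernels).
    """
    x, w, b = _wrap(x), _wrap(w), _wrap(b)
    d = x.data.ndim - 2
    kernel = w.shape[2:]
    if pad is None:
        pad = (kernel[0] - 1) // 2
    cout = w.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((pad, pad),) * d) if pad \
        else x.data
    cols, out_spatial = _im2col(xp, kernel, stride)
    wm = w.data.reshape(cout, -1)
    out = cols @ wm.T + b.data  # (N,P,Cout)
    n = x.shape[0]
    out = np.moveaxis(out.reshape((n,) + tuple(out_spatial) + (cout,)),
                      -1, 1)

    def backward(g):
        p_total = int(np.prod(out_spatial))
        g2 = np.moveaxis(g, 1, -1).reshape(n, p_total, cout)
        grad_b = g2.sum(axis=(0, 1))
        grad_w = np.einsum("npo,npk->ok", g2, cols,
                           optimize=True).reshape(w.shape)
        # grad wrt input as a transposed convolution: zero-stuff the output
        # gradient to the stride-1 grid, pad by (k-1-p), correlate with the
        # channel-swapped, spatially flipped kernel — one BLAS matmul
        # instead of a python scatter loop.
        if stride > 1:
            stuffed_shape = tuple(stride * (so - 1) + 1
                                  for so in out_spatial)
            gup = np.zeros((n, cout) + stuffed_shape, dtype=g.dtype)
            gup[(slice(None), slice(None))
                + tuple(slice(None, None, stride) for _ in kernel)] = g
        else:
            gup = g
        # right pad absorbs input voxels the strided window never reached
        tpad = []
        for s_in, k, so in zip(x.shape[2:], kernel, out_spatial):
            extra = s_in + 2 * pad - k - stride * (so - 1)
            tpad.append((k - 1 - pad, k - 1 - pad + extra))
        gpad = np.pad(gup, ((0, 0), (0, 0)) + tuple(tpad))
        gcols, gsp = _im2col(gpad, kernel, 1)
        wt = np.flip(w.data, axis=tuple(range(2, 2 + d))).swapaxes(0, 1)
        gx = gcols @ wt.reshape(w.shape[1], -1).T
        gx = np.moveaxis(gx.reshape((n,) + tuple(gsp) + (w.shape[1],)),
                         -1, 1)
        return gx, grad_w, grad_b

    return _node(out, (x, w, b), backward)


def upsample_nearest2x(x) -> Tensor:
    x = _wrap(x)
    d = x.data.ndim - 2
    out = x.data
    for ax in range(2, 2 + d):
        out = np.repeat(out, 2, axis=ax)

    def backward(g):
        gx = g
        for ax in range(2, 2 + d):
            n = gx.shape[ax] // 2
            shape = gx.shape[:ax] + (n, 2) + gx.shape[ax + 1:]
            gx = gx.reshape(shape).sum(axis=ax + 1)
        return (gx,)

    return _node(out, (x,), backward)


def _linup_axis(a: np.ndarray, axis: int) -> np.ndarray:
    a = np.moveaxis(a, axis, -1)
    n = a.shape[-1]
    out = np.empty(a.shape[:-1] + (2 * n,), dtype=a.dtype)
    out[..., 0::2] = a
    out[..., 1:-1:2] = 0.5 * (a[..., :-1] + a[..., 1:])
    out[..., -1] = a[..., -1]
    return np.moveaxis(out, -1, axis)


def _linup_axis_T(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    n = g.shape[-1] // 2
    gx = g[..., 0::2].copy()
    mids = g[..., 1:-1:2]
    gx[..., :-1] += 0.5 * mids
    gx[..., 1:] += 0.5 * mids
    gx[..., -1] += g[..., -1]
    return np.moveaxis(gx, -1, axis)


def upsample_linear2x(x) -> Tensor:
    """Linear (bi/trilinear-style) 2x upsampling; exact adjoint backward."""
    x = _wrap(x)
    d = x.data.ndim - 2
    out = x.data
    for ax in range(2, 2 + d):
        out = _linup_axis(out, ax)

    def backward(g):
        gx = g
        for ax in reversed(range(2, 2 + d)):
            gx = _linup_axis_T(gx, ax)
        return (gx,)

    return _node(out, (x,), backward)


def spatial_dropout(x, rate: float, rng: np.random.Generator,
                    on: bool = True) -> Tensor:
    """Channel-wise dropout; active only when ``on`` (training or TTD)."""
    x = _wrap(x)
    if not on or rate <= 0:
        return x
    d = x.data.ndim - 2
    keep = (rng.random(x.shape[:2]) >= rate).astype(np.float32) / (1.0 - rate)
    keep = keep.reshape(x.shape[:2] + (1,) * d)
    return _node(x.data * keep, (x,), lambda g: (g * keep,))
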