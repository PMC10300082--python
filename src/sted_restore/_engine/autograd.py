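"""Compact reverse-mode automatic differentiation on numpy arrays.

The engine implements exactly the operations the UNet-RCAN restoration
network needs: stride-1 "same" N-d convolution, 2x max pooling, 2x
transposed convolution, LeakyReLU / sigmoid activations, global average
pooling, channel concatenation, replicate padding (for the Laplacian used
by the edge loss) and elementwise arithmetic with broadcasting.  Gradients
flow through a tape built dynamically at forward time and are accumulated
by a topological backward sweep.

Arrays are laid out channels-first: ``(N, C, *spatial)`` with 2 or 3
spatial axes.  Every op works for both cases.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        """Run the backward sweep from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(Tensor.as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(Tensor.as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _needs_grad(*tensors) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise ops
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward if _needs_grad(a, b) else None
    return out


def mul(a, b) -> Tensor:
    a, b = Tensor.as_tensor(a), Tensor.as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward if _needs_grad(a, b) else None
    return out


def square(a) -> Tensor:
    return mul(a, a)


def sqrt(a) -> Tensor:
    a = Tensor.as_tensor(a)
    y = np.sqrt(a.data)
    out = Tensor(y, parents=(a,))

    def backward(g):
        a._accumulate(g * 0.5 / np.maximum(y, 1e-300))

    out._backward = backward if _needs_grad(a) else None
    return out


def mean(a) -> Tensor:
    a = Tensor.as_tensor(a)
    out = Tensor(np.asarray(a.data.mean()), parents=(a,))

    def backward(g):
        a._accumulate(np.full_like(a.data, g / a.data.size))

    out._backward = backward if _needs_grad(a) else None
    return out


def tsum(a) -> Tensor:
    a = Tensor.as_tensor(a)
    out = Tensor(np.asarray(a.data.sum()), parents=(a,))

    def backward(g):
        a._accumulate(np.full_like(a.data, g))

    out._backward = backward if _needs_grad(a) else None
    return out


def leaky_relu(a, slope: float = 0.3) -> Tensor:
    a = Tensor.as_tensor(a)
    pos = a.data > 0
    out = Tensor(np.where(pos, a.data, slope * a.data), parents=(a,))

    def backward(g):
        a._accumulate(np.where(pos, g, slope * g))

    out._backward = backward if _needs_grad(a) else None
    return out


def sigmoid(a) -> Tensor:
    a = Tensor.as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out = Tensor(y, parents=(a,))

    def backward(g):
        a._accumulate(g * y * (1.0 - y))

    out._backward = backward if _needs_grad(a) else None
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tensors)

    def backward(g):
        splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accumulate(piece)

    out._backward = backward if _needs_grad(*tensors) else None
    return out


# ---------------------------------------------------------------------------
# spatial ops
# ---------------------------------------------------------------------------

def _correlate(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Stride-1 cross-correlation of (N,Ci,*S) with (Co,Ci,*K), zero pad."""
    nsp = w.ndim - 2
    if pad:
        width = [(0, 0), (0, 0)] + [(pad, pad)] * nsp
        x = np.pad(x, width)
    win = sliding_window_view(x, w.shape[2:], axis=tuple(range(2, 2 + nsp)))
    # win: (N, Ci, *Sout, *K); contract Ci and K against w
    ax_w = (1,) + tuple(range(2, 2 + nsp))
    ax_x = (1,) + tuple(range(2 + nsp, 2 + 2 * nsp))
    out = np.tensordot(win, w, axes=(ax_x, ax_w))  # (N, *Sout, Co)
    return np.moveaxis(out, -1, 1)


def conv_nd(x, w, b=None) -> Tensor:
    """Same-padding stride-1 convolution; kernel extent must be odd."""
    x, w = Tensor.as_tensor(x), Tensor.as_tensor(w)
    k = w.data.shape[2]
    if any(s % 2 == 0 for s in w.data.shape[2:]):
        raise ValueError("conv_nd requires odd kernel extents")
    pad = k // 2
    y = _correlate(x.data, w.data, pad)
    parents = [x, w]
    if b is not None:
        b = Tensor.as_tensor(b)
        nsp = w.data.ndim - 2
        y = y + b.data.reshape((1, -1) + (1,) * nsp)
        parents.append(b)
    out = Tensor(y, parents=parents)

    def backward(g):
        nsp = w.data.ndim - 2
        sp = tuple(range(2, 2 + nsp))
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0,) + sp))
        if w.requires_grad or w._parents:
            width = [(0, 0), (0, 0)] + [(pad, pad)] * nsp
            xp = np.pad(x.data, width) if pad else x.data
            win = sliding_window_view(xp, w.data.shape[2:], axis=sp)
            # dW[o,c,*k] = sum_{n,*s} g[n,o,*s] * win[n,c,*s,*k]
            dw = np.tensordot(g, win, axes=((0,) + sp, (0,) + sp))
            w._accumulate(dw)
        if x.requires_grad or x._parents:
            wf = np.flip(w.data, axis=tuple(range(2, w.data.ndim))).swapaxes(0, 1)
            x._accumulate(_correlate(g, wf, k - 1 - pad))

    out._backward = backward if _needs_grad(x, w) else None
    return out


def laplacian(x, spatial_dims: int) -> Tensor:
    """Discrete Laplacian (4-/6-neighbour stencil) with replicate borders."""
    x = Tensor.as_tensor(x)
    stencil = np.zeros((1, 1) + (3,) * spatial_dims, dtype=x.data.dtype)
    centre = (0, 0) + (1,) * spatial_dims
    stencil[centre] = -2.0 * spatial_dims
    for ax in range(spatial_dims):
        for off in (0, 2):
            idx = [0, 0] + [1] * spatial_dims
            idx[2 + ax] = off
            stencil[tuple(idx)] = 1.0
    padded = replicate_pad(x, 1)
    return _conv_valid_fixed(padded, stencil)


def _conv_valid_fixed(x: Tensor, w: np.ndarray) -> Tensor:
    """Valid correlation against a constant (non-trainable) kernel."""
    y = _correlate(x.data, w, pad=0)
    out = Tensor(y, parents=(x,))

    def backward(g):
        k = w.shape[2]
        wf = np.flip(w, axis=tuple(range(2, w.ndim))).swapaxes(0, 1)
        x._accumulate(_correlate(g, wf, k - 1))

    out._backward = backward if _needs_grad(x) else None
    return out


def replicate_pad(x, pad: int) -> Tensor:
    """Edge-replicating pad of all spatial axes of an (N,C,*S) tensor."""
    x = Tensor.as_tensor(x)
    nsp = x.data.ndim - 2
    width = [(0, 0), (0, 0)] + [(pad, pad)] * nsp
    out = Tensor(np.pad(x.data, width, mode="edge"), parents=(x,))

    def backward(g):
        g = np.array(g, copy=True)
        for ax in range(2, 2 + nsp):
            # fold the replicated slabs back onto the edge rows
            lead = tuple(slice(None) for _ in range(ax))
            for _ in range(pad):
                g[lead + (1,)] += g[lead + (0,)]
                g[lead + (-2,)] += g[lead + (-1,)]
                g = g[lead + (slice(1, -1),)]
        x._accumulate(g)

    out._backward = backward if _needs_grad(x) else None
    return out


def max_pool(x) -> Tensor:
    """2x max pooling (stride 2) over all spatial axes; extents must be even."""
    x = Tensor.as_tensor(x)
    nsp = x.data.ndim - 2
    spatial = x.data.shape[2:]
    if any(s % 2 for s in spatial):
        raise ValueError(f"max_pool needs even spatial extents, got {spatial}")
    shape = x.data.shape[:2]
    for s in spatial:
        shape = shape + (s // 2, 2)
    blocks = x.data.reshape(shape)
    # move the size-2 block axes to the end and flatten them
    block_axes = tuple(3 + 2 * i for i in range(nsp))
    blocks = np.moveaxis(blocks, block_axes, tuple(range(-nsp, 0)))
    flat = blocks.reshape(blocks.shape[: 2 + nsp] + (2 ** nsp,))
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def backward(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gb = gflat.reshape(blocks.shape)
        gb = np.moveaxis(gb, tuple(range(-nsp, 0)), block_axes)
        x._accumulate(gb.reshape(x.data.shape))

    out._backward = backward if _needs_grad(x) else None
    return out


def conv_transpose2(x, w, b=None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact 2x upsampling).

    ``w`` has shape (Cin, Cout, *2s): each input pixel paints a 2^d block.
    """
    x, w = Tensor.as_tensor(x), Tensor.as_tensor(w)
    nsp = w.data.ndim - 2
    n, ci = x.data.shape[:2]
    co = w.data.shape[1]
    spatial = x.data.shape[2:]
    # y[n, o, *(2s+a)] = sum_c x[n,c,*s] w[c,o,*a]
    y = np.tensordot(x.data, w.data, axes=((1,), (0,)))  # (N, *S, Co, *2s)
    y = np.moveaxis(y, 1 + nsp, 1)  # (N, Co, *S, *2s)
    # interleave: (N, Co, s1, 2, s2, 2, ...) -> (N, Co, 2*s1, 2*s2, ...)
    perm = [0, 1]
    for i in range(nsp):
        perm += [2 + i, 2 + nsp + i]
    y = y.transpose(perm).reshape((n, co) + tuple(2 * s for s in spatial))
    parents = [x, w]
    if b is not None:
        b = Tensor.as_tensor(b)
        y = y + b.data.reshape((1, -1) + (1,) * nsp)
        parents.append(b)
    out = Tensor(y, parents=parents)

    def backward(g):
        sp = tuple(range(2, 2 + nsp))
        if b is not None and (b.requires_grad or b._parents):
            b._accumulate(g.sum(axis=(0,) + sp))
        # reshape g back into (N, Co, *S, *2block)
        shape = g.shape[:2]
        for s in spatial:
            shape = shape + (s, 2)
        gb = g.reshape(shape)
        block_axes = tuple(3 + 2 * i for i in range(nsp))
        gb = np.moveaxis(gb, block_axes, tuple(range(-nsp, 0)))  # (N,Co,*S,*2)
        if w.requires_grad or w._parents:
            dw = np.tensordot(x.data, gb, axes=((0,) + sp, (0,) + sp))
            w._accumulate(dw)  # (Ci, Co, *2)
        if x.requires_grad or x._parents:
            dx = np.tensordot(gb, w.data, axes=((1,) + tuple(range(-nsp, 0)),
                                                (1,) + tuple(range(2, 2 + nsp))))
            x._accumulate(np.moveaxis(dx, -1, 1))

    out._backward = backward if _needs_grad(x, w) else None
    return out


def global_avg_pool(x) -> Tensor:
    """Mean over spatial axes, keeping them as singletons (N,C,1,...)."""
    x = Tensor.as_tensor(x)
    nsp = x.data.ndim - 2
    sp = tuple(range(2, 2 + nsp))
    out = Tensor(x.data.mean(axis=sp, keepdims=True), parents=(x,))

    def backward(g):
        count = np.prod([x.data.shape[a] for a in sp])
        x._accumulate(np.broadcast_to(g / count, x.data.shape).copy())

    out._backward = backward if _needs_grad(x) else None
    return out
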