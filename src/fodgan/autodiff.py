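"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the primitives needed by the 3D convolutional
networks in :mod:`fodgan.networks`: broadcasting arithmetic, reductions,
``matmul``, patch extraction/scatter (``im2col``/``col2im``, from which both
convolution and transposed convolution are composed), nearest-neighbour
upsampling, and the pointwise nonlinearities.

Backward passes are themselves built from these primitives, so gradients are
graph-connected tensors and can be differentiated again.  That second order
capability is what the Wasserstein gradient penalty requires: the penalty is
a function of the critic's input-gradient, and its parameter gradient is a
genuine double backward.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "no_grad",
    "grad",
    "add",
    "mul",
    "matmul",
    "tsum",
    "tmean",
    "reshape",
    "transpose",
    "broadcast_to",
    "pow_const",
    "tanh",
    "leaky_relu",
    "tabs",
    "im2col",
    "col2im",
    "upsample_nearest",
    "block_sum",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (also usable to re-enable)."""

    def __init__(self, enabled: bool = False):
        self._target = enabled

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = self._target
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    """An n-d array plus the local reverse-mode graph that produced it."""

    __slots__ = ("data", "requires_grad", "parents", "grad")

    def __init__(self, data, requires_grad=False, parents=()):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.parents = parents  # tuple of (Tensor, vjp callable)
        self.grad = None

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def requires_grad_(self, flag: bool = True) -> "Tensor":
        self.requires_grad = flag
        return self

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self):
        """Accumulate ``.grad`` (plain arrays) on every reachable leaf."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        leaf_grads = _backward(self, _ones_like(self), create_graph=False)
        for leaf, g in leaf_grads.items():
            if leaf.grad is None:
                leaf.grad = g.data.copy()
            else:
                leaf.grad = leaf.grad + g.data

    # -- operators -------------------------------------------------------
    def _co(self, other) -> "Tensor":
        """Coerce, keeping 0-d scalars in this tensor's float dtype."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if arr.ndim == 0 and np.issubdtype(self.dtype, np.floating):
            arr = arr.astype(self.dtype)
        return Tensor(arr)

    def __add__(self, other):
        return add(self, self._co(other))

    __radd__ = __add__

    def __neg__(self):
        return mul(self, self._co(-1.0))

    def __sub__(self, other):
        return add(self, -self._co(other))

    def __rsub__(self, other):
        return add(self._co(other), -self)

    def __mul__(self, other):
        return mul(self, self._co(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_const(self._co(other), -1.0))

    def __rtruediv__(self, other):
        return mul(self._co(other), pow_const(self, -1.0))

    def __pow__(self, e):
        return pow_const(self, float(e))

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def tensor(data, requires_grad=False, dtype=None) -> Tensor:
    arr = np.asarray(data, dtype=dtype)
    return Tensor(arr, requires_grad=requires_grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _const(x) -> Tensor:
    return Tensor(np.asarray(x))


def _ones_like(t: Tensor) -> Tensor:
    return Tensor(np.ones_like(t.data))


def _make(data, parents) -> Tensor:
    if _GRAD_ENABLED:
        parents = tuple((p, f) for p, f in parents if p.requires_grad or p.parents)
        if parents:
            return Tensor(data, requires_grad=True, parents=parents)
    return Tensor(data)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce ``g`` back to ``shape`` after NumPy broadcasting (graph-safe)."""
    while g.ndim > len(shape):
        g = tsum(g, axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, tuple(shape))
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = _make(a.data + b.data, (
        (a, lambda g: _unbroadcast(g, a.shape)),
        (b, lambda g: _unbroadcast(g, b.shape)),
    ))
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data * b.data, (
        (a, lambda g: _unbroadcast(mul(g, b), a.shape)),
        (b, lambda g: _unbroadcast(mul(g, a), b.shape)),
    ))


def pow_const(a: Tensor, e: float) -> Tensor:
    out_data = a.data ** e
    return _make(out_data, (
        (a, lambda g: mul(g, mul(_const(np.asarray(e, dtype=a.dtype)), pow_const(a, e - 1.0)))),
    ))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    axes = axis
    if axes is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axes, int):
        axes = (axes,)
    axes = tuple(ax % a.ndim for ax in axes)
    out_data = a.data.sum(axis=axes, keepdims=keepdims)
    kept = [1 if i in axes else s for i, s in enumerate(a.shape)]

    def vjp(g):
        gg = g if keepdims else reshape(g, tuple(kept))
        return broadcast_to(gg, a.shape)

    return _make(out_data, ((a, vjp),))


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), _const(np.asarray(1.0 / n, dtype=a.dtype)))


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _make(np.broadcast_to(a.data, shape), (
        (a, lambda g: _unbroadcast(g, a.shape)),
    ))


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return _make(a.data.reshape(shape), (
        (a, lambda g: reshape(g, a.shape)),
    ))


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return _make(a.data.transpose(axes), (
        (a, lambda g: transpose(g, inv)),
    ))


def _matmul_np(a, b):
    # 2-D x small batched operand: a single large GEMM beats the broadcast
    # batched path (which is very slow for degenerate inner dimensions)
    if a.ndim == 2 and b.ndim == 3 and b.nbytes <= (16 << 20):
        K, B_, N = b.shape[1], b.shape[0], b.shape[2]
        flat = a @ np.ascontiguousarray(b.transpose(1, 0, 2)).reshape(K, B_ * N)
        return flat.reshape(a.shape[0], B_, N).transpose(1, 0, 2)
    if b.ndim == 2 and a.ndim == 3:
        B_, M, K = a.shape
        return (a.reshape(B_ * M, K) @ b).reshape(B_, M, b.shape[1])
    return np.matmul(a, b)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def swap(t):
        perm = list(range(t.ndim))
        perm[-1], perm[-2] = perm[-2], perm[-1]
        return transpose(t, perm)

    return _make(_matmul_np(a.data, b.data), (
        (a, lambda g: _unbroadcast(matmul(g, swap(b)), a.shape)),
        (b, lambda g: _unbroadcast(matmul(swap(a), g), b.shape)),
    ))


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)
    out = _make(out_data, ())
    if _GRAD_ENABLED and (a.requires_grad or a.parents):
        y = out  # capture output: d tanh = 1 - y^2, differentiable again

        def vjp(g):
            return mul(g, add(_const(np.asarray(1.0, dtype=a.dtype)), -mul(y, y)))

        out.parents = ((a, vjp),)
        out.requires_grad = True
    return out


def leaky_relu(a: Tensor, slope: float = 0.0) -> Tensor:
    mask = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
    return _make(np.where(a.data > 0, a.data, a.data * slope), (
        (a, lambda g: mul(g, _const(mask))),
    ))


def tabs(a: Tensor) -> Tensor:
    sign = np.sign(a.data)
    return _make(np.abs(a.data), (
        (a, lambda g: mul(g, _const(sign))),
    ))


# -- patch extraction / scatter (convolution building blocks) ---------------

def _conv_out_size(n, k, s, p):
    return (n + 2 * p - k) // s + 1


try:  # jitted patch copy/scatter kernels; pure-NumPy fallback below
    import numba as _nb

    @_nb.njit(cache=True)
    def _im2col_kernel(x, k0, k1, k2, s0, s1, s2, od, oh, ow):  # pragma: no cover
        B, C = x.shape[0], x.shape[1]
        cols = np.empty((B, C, k0, k1, k2, od, oh, ow), dtype=x.dtype)
        for b in range(B):
            for c in range(C):
                xb = x[b, c]
                for a in range(k0):
                    for kb in range(k1):
                        for kc in range(k2):
                            dst = cols[b, c, a, kb, kc]
                            for i in range(od):
                                row = xb[i * s0 + a]
                                for j in range(oh):
                                    line = row[j * s1 + kb]
                                    for l in range(ow):
                                        dst[i, j, l] = line[l * s2 + kc]
        return cols

    @_nb.njit(cache=True)
    def _im2col_kernel_strided(x, k0, k1, k2, s0, s1, s2, od, oh, ow):  # pragma: no cover
        # cache-friendlier order for strided (downsampling) extraction
        B, C = x.shape[0], x.shape[1]
        cols = np.empty((B, C, k0, k1, k2, od, oh, ow), dtype=x.dtype)
        for b in range(B):
            for c in range(C):
                xb = x[b, c]
                for a in range(k0):
                    for kb in range(k1):
                        for i in range(od):
                            row = xb[i * s0 + a]
                            for j in range(oh):
                                line = row[j * s1 + kb]
                                for kc in range(k2):
                                    dst = cols[b, c, a, kb, kc, i, j]
                                    for l in range(ow):
                                        dst[l] = line[l * s2 + kc]
        return cols

    @_nb.njit(cache=True)
    def _col2im_kernel(c8, xp, k0, k1, k2, s0, s1, s2):  # pragma: no cover
        B, C = c8.shape[0], c8.shape[1]
        od, oh, ow = c8.shape[5], c8.shape[6], c8.shape[7]
        for b in range(B):
            for c in range(C):
                for a in range(k0):
                    for kb in range(k1):
                        for kc in range(k2):
                            src = c8[b, c, a, kb, kc]
                            for i in range(od):
                                for j in range(oh):
                                    for l in range(ow):
                                        xp[b, c, i * s0 + a, j * s1 + kb,
                                           l * s2 + kc] += src[i, j, l]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _im2col_np(x, kernel, stride, pad):
    B, C = x.shape[:2]
    k0, k1, k2 = kernel
    s0, s1, s2 = stride
    p0, p1, p2 = pad
    if any(pad):
        x = np.pad(x, ((0, 0), (0, 0), (p0, p0), (p1, p1), (p2, p2)))
    od = _conv_out_size(x.shape[2], k0, s0, 0)
    oh = _conv_out_size(x.shape[3], k1, s1, 0)
    ow = _conv_out_size(x.shape[4], k2, s2, 0)
    if _HAVE_NUMBA:
        kern = _im2col_kernel_strided if max(stride) > 1 else _im2col_kernel
        cols = kern(x, k0, k1, k2, s0, s1, s2, od, oh, ow)
    else:
        cols = np.empty((B, C, k0, k1, k2, od, oh, ow), dtype=x.dtype)
        for a in range(k0):
            ae = a + (od - 1) * s0 + 1
            for b in range(k1):
                be = b + (oh - 1) * s1 + 1
                for c in range(k2):
                    ce = c + (ow - 1) * s2 + 1
                    cols[:, :, a, b, c] = x[:, :, a:ae:s0, b:be:s1, c:ce:s2]
    return cols.reshape(B, C * k0 * k1 * k2, od * oh * ow)


def _col2im_np(cols, channels, spatial, kernel, stride, pad):
    B = cols.shape[0]
    D, H, W = spatial
    k0, k1, k2 = kernel
    s0, s1, s2 = stride
    p0, p1, p2 = pad
    od = _conv_out_size(D, k0, s0, p0)
    oh = _conv_out_size(H, k1, s1, p1)
    ow = _conv_out_size(W, k2, s2, p2)
    c8 = cols.reshape(B, channels, k0, k1, k2, od, oh, ow)
    xp = np.zeros((B, channels, D + 2 * p0, H + 2 * p1, W + 2 * p2), dtype=cols.dtype)
    if _HAVE_NUMBA:
        _col2im_kernel(c8, xp, k0, k1, k2, s0, s1, s2)
    else:
        for a in range(k0):
            ae = a + (od - 1) * s0 + 1
            for b in range(k1):
                be = b + (oh - 1) * s1 + 1
                for c in range(k2):
                    ce = c + (ow - 1) * s2 + 1
                    xp[:, :, a:ae:s0, b:be:s1, c:ce:s2] += c8[:, :, a, b, c]
    if any(pad):
        xp = xp[:, :, p0:p0 + D, p1:p1 + H, p2:p2 + W]
    return xp


def im2col(x: Tensor, kernel, stride, pad) -> Tensor:
    """(B,C,D,H,W) -> (B, C*prod(kernel), n_patches); linear, inverse-paired with col2im."""
    spatial = x.shape[2:]
    channels = x.shape[1]
    return _make(_im2col_np(x.data, kernel, stride, pad), (
        (x, lambda g: col2im(g, channels, spatial, kernel, stride, pad)),
    ))


def col2im(cols: Tensor, channels, spatial, kernel, stride, pad) -> Tensor:
    """Scatter-add patches back onto the (B,C,*spatial) grid (adjoint of im2col)."""
    return _make(_col2im_np(cols.data, channels, tuple(spatial), kernel, stride, pad), (
        (cols, lambda g: im2col(g, kernel, stride, pad)),
    ))


def upsample_nearest(x: Tensor, scale) -> Tensor:
    s0, s1, s2 = scale
    data = x.data
    if s0 > 1:
        data = np.repeat(data, s0, axis=2)
    if s1 > 1:
        data = np.repeat(data, s1, axis=3)
    if s2 > 1:
        data = np.repeat(data, s2, axis=4)
    return _make(data, (
        (x, lambda g: block_sum(g, scale)),
    ))


def block_sum(x: Tensor, scale) -> Tensor:
    """Sum non-overlapping blocks (adjoint of nearest-neighbour upsampling)."""
    s0, s1, s2 = scale
    B, C, D, H, W = x.shape
    data = x.data.reshape(B, C, D // s0, s0, H // s1, s1, W // s2, s2).sum(axis=(3, 5, 7))
    return _make(data, (
        (x, lambda g: upsample_nearest(g, scale)),
    ))


# ---------------------------------------------------------------------------
# backward machinery
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p, _ in node.parents:
            if id(p) not in seen and (p.parents or p.requires_grad):
                stack.append((p, False))
    return order  # children after parents; reverse for backward


def _backward(root: Tensor, grad_root: Tensor, create_graph: bool):
    grads = {id(root): grad_root}
    hold = {id(root): root}
    leaves = {}
    ctx = no_grad(enabled=create_graph)
    with ctx:
        for node in reversed(_toposort(root)):
            g = grads.pop(id(node), None)
            hold.pop(id(node), None)
            if g is None:
                continue
            if not node.parents:
                if node.requires_grad:
                    leaves[node] = g
                continue
            for p, vjp in node.parents:
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = add(grads[id(p)], pg)
                else:
                    grads[id(p)] = pg
                    hold[id(p)] = p
    return leaves


def grad(output: Tensor, inputs, create_graph: bool = False):
    """d(output)/d(inputs); with ``create_graph`` the result is differentiable."""
    if output.data.size != 1:
        raise ValueError("grad() requires a scalar output")
    single = isinstance(inputs, Tensor)
    inputs = [inputs] if single else list(inputs)
    leaves = _backward(output, _ones_like(output), create_graph=create_graph)
    out = []
    for t in inputs:
        g = leaves.get(t)
        if g is None:
            g = Tensor(np.zeros_like(t.data))
        out.append(g)
    return out[0] if single else out
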