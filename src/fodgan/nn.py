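"""Neural-network layers and the Adam optimiser on top of :mod:`fodgan.autodiff`.

Layers are deliberately plain: parameters are ``Tensor`` leaves held in
attribute order, state dicts are flat ``{name: ndarray}`` mappings so
checkpoints serialise to a single ``.npz``.  Batch normalisation is composed
from engine primitives (mean / power / multiply), which makes it transparent
to the double backward used by the gradient penalty.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "Linear",
    "BatchNorm",
    "Activation",
    "UpsampleNearest",
    "Sequential",
    "Adam",
]


class Module:
    def parameters(self):
        """Ordered list of (name, Tensor) pairs of trainable leaves."""
        out = []
        for key, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend((f"{key}.{n}", p) for n, p in val.parameters())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend((f"{key}.{i}.{n}", p) for n, p in item.parameters())
        return out

    def buffers(self):
        out = []
        for key, val in vars(self).items():
            if isinstance(val, Tensor) and not val.requires_grad:
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend((f"{key}.{n}", b) for n, b in val.buffers())
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend((f"{key}.{i}.{n}", b) for n, b in item.buffers())
        return out

    def zero_grad(self):
        for _, p in self.parameters():
            p.grad = None

    def state_dict(self):
        d = {f"param.{n}": p.data.copy() for n, p in self.parameters()}
        d.update({f"buffer.{n}": b.data.copy() for n, b in self.buffers()})
        return d

    def load_state_dict(self, d):
        for n, p in self.parameters():
            p.data = np.asarray(d[f"param.{n}"]).copy()
        for n, b in self.buffers():
            b.data = np.asarray(d[f"buffer.{n}"]).copy()

    def n_parameters(self):
        return int(sum(p.data.size for _, p in self.parameters()))

    def __call__(self, x, train=True):
        return self.forward(x, train=train)


def _triple(v):
    if isinstance(v, (tuple, list)):
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def _fan_in_normal(rng, shape, fan_in, dtype):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(dtype)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, rng=None, dtype=np.float32,
                 init="normal"):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        k = int(np.prod(self.kernel))
        shape = (cout, cin) + self.kernel
        if init == "zeros":
            w = np.zeros(shape, dtype=dtype)
        else:
            w = _fan_in_normal(rng, shape, cin * k, dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def forward(self, x, train=True):
        cout, cin = self.weight.shape[:2]
        ck = cin * int(np.prod(self.kernel))
        cols = ad.im2col(x, self.kernel, self.stride, self.padding)  # (B,CK,P)
        wmat = ad.reshape(self.weight, (cout, ck))
        out = ad.matmul(wmat, cols) + ad.reshape(self.bias, (1, cout, 1))
        B = x.shape[0]
        od = ad._conv_out_size(x.shape[2], self.kernel[0], self.stride[0], self.padding[0])
        oh = ad._conv_out_size(x.shape[3], self.kernel[1], self.stride[1], self.padding[1])
        ow = ad._conv_out_size(x.shape[4], self.kernel[2], self.stride[2], self.padding[2])
        return ad.reshape(out, (B, cout, od, oh, ow))


class ConvTranspose3d(Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, rng=None, dtype=np.float32,
                 init="normal"):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        shape = (cin, cout) + self.kernel
        if init == "zeros":
            w = np.zeros(shape, dtype=dtype)
        else:
            w = _fan_in_normal(rng, shape, cin, dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)

    def out_spatial(self, spatial):
        return tuple((n - 1) * s - 2 * p + k for n, k, s, p in
                     zip(spatial, self.kernel, self.stride, self.padding))

    def forward(self, x, train=True):
        cin, cout = self.weight.shape[:2]
        B = x.shape[0]
        spatial_in = x.shape[2:]
        spatial_out = self.out_spatial(spatial_in)
        P = int(np.prod(spatial_in))
        k = int(np.prod(self.kernel))
        xflat = ad.reshape(x, (B, cin, P))
        wmat = ad.transpose(ad.reshape(self.weight, (cin, cout * k)), (1, 0))
        cols = ad.matmul(wmat, xflat)  # (B, cout*k, P); patch p sits at stride position p
        out = ad.col2im(cols, cout, spatial_out, self.kernel, self.stride, self.padding)
        return out + ad.reshape(self.bias, (1, cout, 1, 1, 1))


class Linear(Module):
    def __init__(self, fin, fout, rng=None, dtype=np.float32, init="normal"):
        if init == "zeros":
            w = np.zeros((fin, fout), dtype=dtype)
        else:
            w = _fan_in_normal(rng, (fin, fout), fin, dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(fout, dtype=dtype), requires_grad=True)

    def forward(self, x, train=True):
        return ad.matmul(x, self.weight) + ad.reshape(self.bias, (1, -1))


class BatchNorm(Module):
    """Batch normalisation over the batch (and spatial axes for 5-d inputs)."""

    def __init__(self, channels, eps=1e-5, momentum=0.1, dtype=np.float32):
        self.eps = float(eps)
        self.momentum = float(momentum)
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = Tensor(np.zeros(channels, dtype=dtype))
        self.running_var = Tensor(np.ones(channels, dtype=dtype))

    def forward(self, x, train=True):
        if x.ndim == 5:
            axes, bshape = (0, 2, 3, 4), (1, -1, 1, 1, 1)
        else:
            axes, bshape = (0,), (1, -1)
        if train:
            mu = ad.tmean(x, axis=axes, keepdims=True)
            xc = x - mu
            var = ad.tmean(xc * xc, axis=axes, keepdims=True)
            with ad.no_grad():
                m = self.momentum
                self.running_mean.data = ((1 - m) * self.running_mean.data
                                          + m * mu.data.reshape(-1))
                self.running_var.data = ((1 - m) * self.running_var.data
                                         + m * var.data.reshape(-1))
        else:
            mu = ad.reshape(self.running_mean, bshape)
            xc = x - mu
            var = ad.reshape(self.running_var, bshape)
        inv = ad.pow_const(var + self.eps, -0.5)
        return xc * inv * ad.reshape(self.gamma, bshape) + ad.reshape(self.beta, bshape)


class Activation(Module):
    def __init__(self, kind, slope=0.0):
        self.kind = kind
        self.slope = float(slope)

    def forward(self, x, train=True):
        if self.kind == "tanh":
            return ad.tanh(x)
        if self.kind in ("relu", "leaky_relu"):
            return ad.leaky_relu(x, self.slope)
        if self.kind == "none":
            return x
        raise ValueError(f"unknown activation {self.kind!r}")


class UpsampleNearest(Module):
    def __init__(self, scale):
        self.scale = _triple(scale)

    def forward(self, x, train=True):
        return ad.upsample_nearest(x, self.scale)


class Sequential(Module):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer(x, train=train)
        return x


class Adam:
    """Adam with the conventional (0.9, 0.999) moments; only lr is exposed."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = [p for _, p in params] if params and isinstance(params[0], tuple) else list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self):
        d = {"t": np.asarray(self.t)}
        for i in range(len(self.params)):
            d[f"m.{i}"] = self.m[i]
            d[f"v.{i}"] = self.v[i]
        return d

    def load_state_dict(self, d):
        self.t = int(d["t"])
        self.m = [np.asarray(d[f"m.{i}"]).copy() for i in range(len(self.params))]
        self.v = [np.asarray(d[f"v.{i}"]).copy() for i in range(len(self.params))]
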