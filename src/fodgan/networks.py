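"""Declarative architecture of the alpha-WGAN sub-networks.

Four networks cooperate: the Generator/Decoder maps a latent Gaussian vector
(dimension 5000 at paper scale) to a 28-channel SH coefficient volume of
128 x 128 x 64 voxels; the Discriminator scores volumes with a single real
number (Wasserstein critic); the Encoder shares the critic topology but
emits a latent vector; the Code Discriminator is a 3-layer MLP critic on
latent vectors.  Architectures are declared as :class:`NetSpec` layer tables
and validated by a symbolic shape trace at construction, so the paper-scale
models can be checked without allocating their ~10^9 parameters.

``scale_spec`` derives desk-scale variants from the same tables: channel
counts shrink by a multiplier, the latent dimension is replaced, and the two
resolution-dependent kernels (the Generator's lifting layer and the critics'
final collapse layer) become dims/(32, 32, 16), which reproduces the printed
kernels exactly at 128 x 128 x 64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .nn import (Activation, BatchNorm, Conv3d, ConvTranspose3d, Linear, Module,
                 Sequential, UpsampleNearest)

__all__ = ["LayerSpec", "NetSpec", "ModelScale", "paper_generator_spec",
           "paper_discriminator_spec", "paper_encoder_spec",
           "paper_code_discriminator_spec", "scale_spec", "shape_trace", "build",
           "Network", "TINY_SCALE"]

_DOWN_FACTOR = (32, 32, 16)  # net spatial factor between the lifting grid and output


def _triple(v):
    if isinstance(v, (tuple, list)):
        return tuple(int(x) for x in v)
    return (int(v),) * 3


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv3d | transposed_conv3d | linear | upsample_nearest
    in_channels: int = 0
    out_channels: int = 0
    kernel: tuple = (1, 1, 1)
    stride: tuple = (1, 1, 1)
    padding: tuple = (0, 0, 0)
    batch_norm: bool = False
    activation: str = "none"  # leaky_relu | relu | tanh | none
    act_slope: float = 0.0
    scale: tuple = (1, 1, 1)  # upsample factor (upsample_nearest only)

    def __post_init__(self):
        if self.kind not in ("conv3d", "transposed_conv3d", "linear", "upsample_nearest"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind != "upsample_nearest" and (self.in_channels <= 0 or self.out_channels <= 0):
            raise ValueError("channel counts must be positive")
        if self.act_slope < 0:
            raise ValueError("activation slope must be >= 0")
        for name in ("kernel", "stride", "padding", "scale"):
            object.__setattr__(self, name, _triple(getattr(self, name)))


@dataclass(frozen=True)
class NetSpec:
    name: str
    layers: tuple
    latent_dim: int
    input_shape: tuple   # (C, D, H, W) or (F,)
    output_shape: tuple  # contract, verified by shape_trace

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        trace = shape_trace(self)
        if trace[-1] != tuple(self.output_shape):
            raise ValueError(
                f"{self.name}: shape trace closes at {trace[-1]}, contract is "
                f"{tuple(self.output_shape)}"
            )
        prev = None
        for ls in self.layers:
            if ls.kind == "upsample_nearest":
                continue
            if prev is not None and ls.in_channels != prev:
                raise ValueError(f"{self.name}: channel chain broken at {ls}")
            prev = ls.out_channels

    def to_json(self) -> str:
        return json.dumps({"name": self.name, "latent_dim": self.latent_dim,
                           "input_shape": self.input_shape,
                           "output_shape": self.output_shape,
                           "layers": [asdict(l) for l in self.layers]})

    @classmethod
    def from_json(cls, s: str) -> "NetSpec":
        d = json.loads(s)
        layers = tuple(LayerSpec(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in l.items()}) for l in d["layers"])
        return cls(d["name"], layers, d["latent_dim"], tuple(d["input_shape"]),
                   tuple(d["output_shape"]))


@dataclass(frozen=True)
class ModelScale:
    """Desk-scale instantiation: output dims, channel shrink factor, latent size."""

    dims: tuple = (128, 128, 64)
    channel_multiplier: float = 1.0
    latent_dim: int = 5000

    def __post_init__(self):
        object.__setattr__(self, "dims", _triple(self.dims))
        if not (0 < self.channel_multiplier <= 1):
            raise ValueError("channel multiplier must be in (0, 1]")
        for d, f in zip(self.dims, _DOWN_FACTOR):
            if d % f != 0 or d // f < 1:
                raise ValueError(
                    f"dims {self.dims} must be divisible by {_DOWN_FACTOR} "
                    "(spatial factor of the up/down-sampling chain)"
                )

    @property
    def lift(self):
        return tuple(d // f for d, f in zip(self.dims, _DOWN_FACTOR))


TINY_SCALE = ModelScale(dims=(32, 32, 16), channel_multiplier=1.0 / 50.0, latent_dim=64)


def _conv_out(n, k, s, p):
    out = (n + 2 * p - k) // s + 1
    if out < 1 or n + 2 * p < k:
        raise ValueError(f"conv trace underflow: size {n}, kernel {k}, pad {p}")
    return out


def shape_trace(spec: NetSpec) -> list:
    """Per-layer output shapes from the declared input; raises on mismatch."""
    shape = tuple(spec.input_shape)
    trace = [shape]
    for ls in spec.layers:
        if ls.kind == "linear":
            if len(shape) != 1 or shape[0] != ls.in_channels:
                raise ValueError(f"{spec.name}: linear layer expects ({ls.in_channels},), got {shape}")
            shape = (ls.out_channels,)
        elif ls.kind == "upsample_nearest":
            c, *sp = shape
            shape = (c,) + tuple(n * s for n, s in zip(sp, ls.scale))
        elif ls.kind == "conv3d":
            c, *sp = shape
            if c != ls.in_channels:
                raise ValueError(f"{spec.name}: conv expects {ls.in_channels} channels, got {c}")
            shape = (ls.out_channels,) + tuple(
                _conv_out(n, k, s, p) for n, k, s, p in zip(sp, ls.kernel, ls.stride, ls.padding))
        elif ls.kind == "transposed_conv3d":
            if len(shape) == 1:
                if shape[0] != ls.in_channels:
                    raise ValueError(f"{spec.name}: latent dim {shape[0]} != {ls.in_channels}")
                sp = (1, 1, 1)
            else:
                c, *sp = shape
                if c != ls.in_channels:
                    raise ValueError(f"{spec.name}: channels {c} != {ls.in_channels}")
            shape = (ls.out_channels,) + tuple(
                (n - 1) * s - 2 * p + k
                for n, k, s, p in zip(sp, ls.kernel, ls.stride, ls.padding))
        trace.append(shape)
    # critics collapse to (C,1,1,1); report as (C,)
    if len(trace[-1]) == 4 and trace[-1][1:] == (1, 1, 1) and spec.output_shape and \
            len(spec.output_shape) == 1:
        trace[-1] = (trace[-1][0],)
    return trace


# ---------------------------------------------------------------------------
# paper-scale tables
# ---------------------------------------------------------------------------

_G_CHANNELS = (3200, 1600, 800, 400, 200)
_D_CHANNELS = (125, 250, 500, 1000, 2000)
_CD_HIDDEN = 4096


def paper_generator_spec(scale: ModelScale = ModelScale()) -> NetSpec:
    """Generator/Decoder: lifting transposed conv, then five upsample+conv blocks.

    Layer 1 lifts the latent vector onto a dims/(32,32,16) grid (4x4x4 at
    paper scale) with batch norm and leaky-ReLU slope 0.1; blocks 2-5 double
    the grid with nearest-neighbour upsampling before a 3x3x3 convolution
    (batch norm, ReLU); block 6 upsamples by (2,2,1) and maps to the 28 SH
    channels through tanh.
    """
    mult = scale.channel_multiplier
    ch = [max(2, round(c * mult)) if mult != 1 else c for c in _G_CHANNELS]
    layers = [LayerSpec("transposed_conv3d", scale.latent_dim, ch[0], kernel=scale.lift,
                        stride=1, padding=0, batch_norm=True,
                        activation="leaky_relu", act_slope=0.1)]
    for cin, cout in zip(ch[:-1], ch[1:]):
        layers.append(LayerSpec("upsample_nearest", scale=(2, 2, 2)))
        layers.append(LayerSpec("conv3d", cin, cout, kernel=3, stride=1, padding=1,
                                batch_norm=True, activation="relu"))
    layers.append(LayerSpec("upsample_nearest", scale=(2, 2, 1)))
    layers.append(LayerSpec("conv3d", ch[-1], 28, kernel=3, stride=1, padding=1,
                            activation="tanh"))
    return NetSpec("generator", tuple(layers), scale.latent_dim,
                   (scale.latent_dim,), (28,) + scale.dims)


def _critic_layers(scale: ModelScale, out_channels: int):
    mult = scale.channel_multiplier
    ch = [max(2, round(c * mult)) if mult != 1 else c for c in _D_CHANNELS]
    slopes = (0.2, 0.05, 0.05, 0.05, 0.05)
    layers = []
    cin = 28
    for i, (cout, slope) in enumerate(zip(ch, slopes)):
        kernel = (4, 4, 4) if i < 4 else (4, 4, 3)
        stride = (2, 2, 2) if i < 4 else (2, 2, 1)
        layers.append(LayerSpec("conv3d", cin, cout, kernel=kernel, stride=stride,
                                padding=1, batch_norm=(i > 0),
                                activation="leaky_relu", act_slope=slope))
        cin = cout
    layers.append(LayerSpec("conv3d", cin, out_channels, kernel=scale.lift, stride=1,
                            padding=0, activation="none"))
    return tuple(layers)


def paper_discriminator_spec(scale: ModelScale = ModelScale()) -> NetSpec:
    """Critic: six strided convolutions, batch norm in layers 2-5, scalar output."""
    return NetSpec("discriminator", _critic_layers(scale, 1), scale.latent_dim,
                   (28,) + scale.dims, (1,))


def paper_encoder_spec(scale: ModelScale = ModelScale()) -> NetSpec:
    """Encoder: the critic topology with a latent-sized final output."""
    return NetSpec("encoder", _critic_layers(scale, scale.latent_dim), scale.latent_dim,
                   (28,) + scale.dims, (scale.latent_dim,))


def paper_code_discriminator_spec(scale: ModelScale = ModelScale()) -> NetSpec:
    """Latent critic: 5000 -> 4096 -> 4096 -> 1 MLP, batch norm + leaky ReLU 0.2."""
    mult = scale.channel_multiplier
    hidden = max(2, round(_CD_HIDDEN * mult)) if mult != 1 else _CD_HIDDEN
    layers = (
        LayerSpec("linear", scale.latent_dim, hidden, batch_norm=True,
                  activation="leaky_relu", act_slope=0.2),
        LayerSpec("linear", hidden, hidden, batch_norm=True,
                  activation="leaky_relu", act_slope=0.2),
        LayerSpec("linear", hidden, 1, activation="none"),
    )
    return NetSpec("code_discriminator", layers, scale.latent_dim,
                   (scale.latent_dim,), (1,))


_SPEC_BUILDERS = {
    "generator": paper_generator_spec,
    "discriminator": paper_discriminator_spec,
    "encoder": paper_encoder_spec,
    "code_discriminator": paper_code_discriminator_spec,
}


def scale_spec(spec: NetSpec, scale: ModelScale) -> NetSpec:
    """Re-derive a spec's table at a different scale; topology is preserved."""
    try:
        builder = _SPEC_BUILDERS[spec.name]
    except KeyError:
        raise ValueError(f"cannot rescale unknown network {spec.name!r}") from None
    return builder(scale)


def all_paper_specs(scale: ModelScale = ModelScale()) -> dict:
    return {name: fn(scale) for name, fn in _SPEC_BUILDERS.items()}


class Network(Module):
    """A built network: Sequential layers plus the spec it was built from."""

    def __init__(self, spec: NetSpec, seed: int = 0, dtype=np.float32, init="normal"):
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        mods = []
        for ls in spec.layers:
            if ls.kind == "conv3d":
                mods.append(Conv3d(ls.in_channels, ls.out_channels, ls.kernel,
                                   ls.stride, ls.padding, rng=rng, dtype=dtype, init=init))
            elif ls.kind == "transposed_conv3d":
                mods.append(ConvTranspose3d(ls.in_channels, ls.out_channels, ls.kernel,
                                            ls.stride, ls.padding, rng=rng, dtype=dtype,
                                            init=init))
            elif ls.kind == "linear":
                mods.append(Linear(ls.in_channels, ls.out_channels, rng=rng,
                                   dtype=dtype, init=init))
            elif ls.kind == "upsample_nearest":
                mods.append(UpsampleNearest(ls.scale))
            if ls.batch_norm:
                mods.append(BatchNorm(ls.out_channels, dtype=dtype))
            if ls.activation != "none":
                mods.append(Activation(ls.activation, ls.act_slope))
        self.net = Sequential(mods)

    def forward(self, x, train=True):
        from . import autodiff as ad
        if x.ndim == 2 and self.spec.layers[0].kind == "transposed_conv3d":
            x = ad.reshape(x, x.shape + (1, 1, 1))
        out = self.net(x, train=train)
        if out.ndim == 5 and out.shape[2:] == (1, 1, 1):
            out = ad.reshape(out, out.shape[:2])
        return out


def build(spec: NetSpec, seed: int = 0, dtype=np.float32, init="normal") -> Network:
    """Instantiate a spec with seeded, reproducible fan-in-scaled normal init."""
    return Network(spec, seed=seed, dtype=dtype, init=init)
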