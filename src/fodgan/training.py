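"""alpha-WGAN objective and training loop.

Three coupled losses drive the four networks (batch means in angle brackets,
lambda the reconstruction weight, kappa the gradient-penalty weight):

    L_GE  = -<D(x_dec)> - <D(x_syn)> - <CD(z_e)> + lambda <||x_real - x_dec||_L1>
    L_D   =  <D(x_dec)> + <D(x_syn)> - 2 <D(x_train)> + kappa phi_D
    L_CD  =  <CD(z_e)> - <CD(z_r)> + kappa phi_CD

with phi_D the two-interpolant gradient penalty evaluated at
x_hat = a x_train + (1-a) x_syn and x_tilde = b x_train + (1-b) x_dec
(a, b uniform per batch item), and phi_CD the single-interpolant penalty at
z_hat = g z_e + (1-g) z_r.  One epoch performs one Adam step for the
Encoder, two for the Generator (the loss is recomputed before each step on
the same batch), four Discriminator steps on fresh batches, and one Code
Discriminator step; all optimisers share learning rate 1e-4 and batch size 6
by default.  All randomness flows from the run seed, so trajectories are
bit-reproducible and checkpoints resume exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam
from .networks import ModelScale, NetSpec, Network, all_paper_specs, build
from .sh import SHBasis, SHImage

__all__ = ["TrainConfig", "BatchBundle", "InterpolantDraw", "TrainState",
           "TrainingDiverged", "compute_normalization", "normalize_intensity",
           "denormalize_intensity", "loss_ge", "loss_d", "loss_cd",
           "gradient_penalty_d", "gradient_penalty_cd", "make_bundle",
           "epoch_step", "train", "save_checkpoint", "load_checkpoint",
           "reconstruction_l1", "ArrayDataSource"]

_NORM_EPS = 1e-12
_SCHEDULE = (("encoder", 1), ("generator", 2))  # then 4 x D, 1 x CD


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; training aborts with a checkpoint."""


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch_size: int = 6
    lambda_l1: float = 50000.0
    kappa_gp: float = 10.0
    steps_e: int = 1
    steps_g: int = 2
    steps_d: int = 4
    steps_cd: int = 1
    epochs: int = 100
    seed: int = 0
    checkpoint_every: int = 0  # 0: only on completion (when out_dir is given)

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.epochs + 1) <= 0:
            raise ValueError("lr, batch size must be positive; epochs >= 0")
        if self.lambda_l1 < 0 or self.kappa_gp < 0:
            raise ValueError("lambda and kappa must be >= 0")


# ---------------------------------------------------------------------------
# intensity normalisation (tanh output range)
# ---------------------------------------------------------------------------

def compute_normalization(images) -> np.ndarray:
    """Per-channel max-abs scale over a cohort (channels where all-zero -> 1)."""
    arr = _as_array(images)
    scales = np.abs(arr).max(axis=(0, 2, 3, 4))
    scales[scales == 0] = 1.0
    return scales.astype(arr.dtype)


def normalize_intensity(img, scales):
    """Map coefficients into [-1, 1] by per-channel scale; clips outliers.

    Returns (normalized, n_clipped); accepts an SHImage or a bare array whose
    leading axis is the channel axis.
    """
    scales = np.asarray(scales)
    if np.any(scales <= 0):
        raise ValueError("normalisation scales must be strictly positive")
    if isinstance(img, SHImage):
        data = img.coefficients / scales[:, None, None, None]
        n_clip = int(np.sum(np.abs(data) > 1))
        return SHImage(np.clip(data, -1, 1), img.voxel_size, img.basis), n_clip
    bshape = (-1,) + (1,) * (img.ndim - 1) if img.ndim in (4,) else \
        (1, -1) + (1,) * (img.ndim - 2)
    data = img / scales.reshape(bshape)
    n_clip = int(np.sum(np.abs(data) > 1))
    return np.clip(data, -1, 1), n_clip


def denormalize_intensity(img, scales):
    """Inverse of :func:`normalize_intensity` (up to clipping)."""
    scales = np.asarray(scales)
    if isinstance(img, SHImage):
        return SHImage(img.coefficients * scales[:, None, None, None],
                       img.voxel_size, img.basis)
    bshape = (-1,) + (1,) * (img.ndim - 1) if img.ndim == 4 else \
        (1, -1) + (1,) * (img.ndim - 2)
    return img * scales.reshape(bshape)


def _as_array(images):
    if isinstance(images, np.ndarray):
        return images
    return np.stack([im.coefficients if isinstance(im, SHImage) else np.asarray(im)
                     for im in images])


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

@dataclass
class BatchBundle:
    """One training batch and its derived tensors."""

    x_train: Tensor
    z_r: Tensor
    x_syn: Tensor
    z_e: Tensor
    x_dec: Tensor


@dataclass
class InterpolantDraw:
    """Per-batch-item uniform(0,1) mixing coefficients for the penalties."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray

    @classmethod
    def sample(cls, rng: np.random.Generator, n: int) -> "InterpolantDraw":
        return cls(rng.uniform(size=n), rng.uniform(size=n), rng.uniform(size=n))


def make_bundle(G, E, x_train: np.ndarray, z_r: np.ndarray, train=True,
                with_graph=True) -> BatchBundle:
    """Run the forward passes x_syn = G(z_r), z_e = E(x), x_dec = G(z_e)."""
    xt = ad.tensor(x_train)
    zr = ad.tensor(z_r)
    with ad.no_grad(enabled=with_graph):
        x_syn = G(zr, train=train)
        z_e = E(xt, train=train)
        x_dec = G(z_e, train=train)
    return BatchBundle(xt, zr, x_syn, z_e, x_dec)


def _batch_l1(a: Tensor, b: Tensor) -> Tensor:
    diff = ad.tabs(a - b)
    axes = tuple(range(1, diff.ndim))
    return ad.tmean(ad.tsum(diff, axis=axes))


def loss_ge(bundle: BatchBundle, D, CD, lambda_l1: float) -> Tensor:
    """Generator/Encoder loss: adversarial terms plus the weighted L1 term.

    The L1 term is the batch mean of the per-sample sum of absolute
    coefficient differences between the training image and its decoded
    reconstruction.
    """
    return (-ad.tmean(D(bundle.x_dec)) - ad.tmean(D(bundle.x_syn))
            - ad.tmean(CD(bundle.z_e))
            + lambda_l1 * _batch_l1(bundle.x_train, bundle.x_dec))


def _penalty_term(critic, x_mix: np.ndarray) -> Tensor:
    xh = ad.tensor(x_mix, requires_grad=True)
    out = ad.tsum(critic(xh))
    g = ad.grad(out, xh, create_graph=True)
    axes = tuple(range(1, g.ndim))
    norm = ad.pow_const(ad.tsum(g * g, axis=axes) + _NORM_EPS, 0.5)
    one = ad.tensor(np.asarray(1.0, dtype=norm.dtype))
    return ad.tmean((norm - one) ** 2)


def _mix(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> np.ndarray:
    w = w.reshape((-1,) + (1,) * (a.ndim - 1)).astype(a.dtype)
    return w * a + (1.0 - w) * b


def gradient_penalty_d(D, x_train, x_syn, x_dec, draws: InterpolantDraw) -> Tensor:
    """Two-interpolant critic penalty <(||grad D|| - 1)^2>, per-sample mixes."""
    x_train = x_train.data if isinstance(x_train, Tensor) else np.asarray(x_train)
    x_syn = x_syn.data if isinstance(x_syn, Tensor) else np.asarray(x_syn)
    x_dec = x_dec.data if isinstance(x_dec, Tensor) else np.asarray(x_dec)
    t1 = _penalty_term(D, _mix(x_train, x_syn, draws.alpha))
    t2 = _penalty_term(D, _mix(x_train, x_dec, draws.beta))
    return t1 + t2


def gradient_penalty_cd(CD, z_e, z_r, draws: InterpolantDraw) -> Tensor:
    z_e = z_e.data if isinstance(z_e, Tensor) else np.asarray(z_e)
    z_r = z_r.data if isinstance(z_r, Tensor) else np.asarray(z_r)
    return _penalty_term(CD, _mix(z_e, z_r, draws.gamma))


def loss_d(bundle: BatchBundle, D, kappa: float,
           draws: InterpolantDraw | None = None) -> Tensor:
    """Critic loss <D(x_dec)> + <D(x_syn)> - 2<D(x_train)> + kappa phi_D."""
    x_dec = bundle.x_dec.detach()
    x_syn = bundle.x_syn.detach()
    out = (ad.tmean(D(x_dec)) + ad.tmean(D(x_syn))
           - 2.0 * ad.tmean(D(bundle.x_train)))
    if kappa != 0:
        if draws is None:
            raise ValueError("interpolant draws required when kappa != 0")
        out = out + kappa * gradient_penalty_d(D, bundle.x_train, x_syn, x_dec, draws)
    return out


def loss_cd(bundle: BatchBundle, CD, kappa: float,
            draws: InterpolantDraw | None = None) -> Tensor:
    """Latent critic loss <CD(z_e)> - <CD(z_r)> + kappa phi_CD."""
    z_e = bundle.z_e.detach()
    out = ad.tmean(CD(z_e)) - ad.tmean(CD(bundle.z_r))
    if kappa != 0:
        if draws is None:
            raise ValueError("interpolant draws required when kappa != 0")
        out = out + kappa * gradient_penalty_cd(CD, z_e, bundle.z_r, draws)
    return out


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainState:
    nets: dict
    optims: dict
    rng: np.random.Generator
    config: TrainConfig
    normalization: np.ndarray
    voxel_size: tuple
    epoch: int = 0
    step_counts: dict = field(default_factory=lambda: {"E": 0, "G": 0, "D": 0, "CD": 0})
    history: list = field(default_factory=list)


class ArrayDataSource:
    """Uniform random batches (with replacement) from a stacked image array."""

    def __init__(self, images: np.ndarray):
        self.images = np.asarray(images, dtype=np.float32)
        if self.images.ndim != 5:
            raise ValueError("expected (n, channels, x, y, z) images")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        idx = rng.integers(0, len(self.images), size=n)
        return self.images[idx]


def _check_finite(name, value):
    if not np.isfinite(value):
        raise TrainingDiverged(f"{name} became non-finite ({value}); "
                               "aborting with checkpoint")


def epoch_step(state: TrainState, data: ArrayDataSource, config: TrainConfig) -> TrainState:
    """One schedule iteration: E x1, G x2 (shared batch), D x4, CD x1."""
    nets, optims, rng = state.nets, state.optims, state.rng
    G, E, D, CD = nets["generator"], nets["encoder"], nets["discriminator"], \
        nets["code_discriminator"]
    latent = G.spec.latent_dim
    B = config.batch_size
    Df = lambda t: D(t, train=True)
    CDf = lambda t: CD(t, train=True)

    # --- Generator/Encoder phase: recompute the loss before every step
    x = data.sample(rng, B)
    z = rng.standard_normal((B, latent)).astype(np.float32)
    record = {}
    plan = [("E", optims["encoder"])] * config.steps_e + \
           [("G", optims["generator"])] * config.steps_g
    for label, optim in plan:
        bundle = make_bundle(G, E, x, z, train=True, with_graph=True)
        lge = loss_ge(bundle, Df, CDf, config.lambda_l1)
        _check_finite("L_GE", lge.item())
        G.zero_grad(); E.zero_grad(); D.zero_grad(); CD.zero_grad()
        lge.backward()
        optim.step()
        state.step_counts[label] += 1
        record["L_GE"] = lge.item()

    # --- Discriminator phase: fresh batches each loop
    for _ in range(config.steps_d):
        x = data.sample(rng, B)
        z = rng.standard_normal((B, latent)).astype(np.float32)
        bundle = make_bundle(G, E, x, z, train=True, with_graph=False)
        draws = InterpolantDraw.sample(rng, B)
        ld = loss_d(bundle, Df, config.kappa_gp, draws)
        _check_finite("L_D", ld.item())
        D.zero_grad()
        ld.backward()
        optims["discriminator"].step()
        state.step_counts["D"] += 1
        record["L_D"] = ld.item()

    # --- Code-discriminator step
    x = data.sample(rng, B)
    z = rng.standard_normal((B, latent)).astype(np.float32)
    bundle = make_bundle(G, E, x, z, train=True, with_graph=False)
    draws = InterpolantDraw.sample(rng, B)
    for _ in range(config.steps_cd):
        lcd = loss_cd(bundle, CDf, config.kappa_gp, draws)
        _check_finite("L_CD", lcd.item())
        CD.zero_grad()
        lcd.backward()
        optims["code_discriminator"].step()
        state.step_counts["CD"] += 1
        record["L_CD"] = lcd.item()

    state.epoch += 1
    state.history.append({"epoch": state.epoch, **record})
    return state


def _build_all(specs: dict, seed: int) -> dict:
    return {name: build(spec, seed=seed + i)
            for i, (name, spec) in enumerate(sorted(specs.items()))}


def train(config: TrainConfig, cohort, scale: ModelScale | None = None,
          specs: dict | None = None, out_dir=None, state: TrainState | None = None,
          progress=None) -> TrainState:
    """Train the four networks on a cohort of SHImage (or stacked array).

    Either ``specs`` (a dict of the four NetSpec) or ``scale`` must be given
    when starting fresh; pass ``state`` from :func:`load_checkpoint` to
    resume.  Checkpoints (networks, optimisers, RNG state, normalisation)
    land in ``out_dir`` at ``config.checkpoint_every`` cadence and at the
    end; resumed runs reproduce uninterrupted ones bit-for-bit.
    """
    arr = _as_array(cohort).astype(np.float32)
    voxel = cohort[0].voxel_size if (not isinstance(cohort, np.ndarray)
                                     and isinstance(cohort[0], SHImage)) else (1.0, 1.0, 1.0)
    if state is None:
        if specs is None:
            if scale is None:
                raise ValueError("need specs, scale, or a state to resume from")
            specs = all_paper_specs(scale)
        g_out = specs["generator"].output_shape
        if tuple(arr.shape[1:]) != tuple(g_out):
            raise ValueError(f"cohort images {arr.shape[1:]} do not match the "
                             f"generator output contract {g_out}")
        scales = compute_normalization(arr)
        nets = _build_all(specs, config.seed)
        optims = {name: Adam(net.parameters(), lr=config.lr)
                  for name, net in nets.items()}
        state = TrainState(nets, optims, np.random.default_rng(config.seed),
                           config, scales, tuple(voxel))
    norm, n_clip = normalize_intensity(arr, state.normalization)
    data = ArrayDataSource(norm)
    try:
        while state.epoch < config.epochs:
            epoch_step(state, data, config)
            if progress is not None:
                progress(state)
            if out_dir and config.checkpoint_every and \
                    state.epoch % config.checkpoint_every == 0:
                save_checkpoint(state, out_dir)
    except TrainingDiverged:
        if out_dir:
            save_checkpoint(state, out_dir)
        raise
    if out_dir:
        save_checkpoint(state, out_dir)
    return state


def reconstruction_l1(state: TrainState, images) -> float:
    """Held-out mean per-sample L1 between x and G(E(x)), normalised units.

    Evaluated with batch statistics, the same normalisation the training
    objective sees; the batch-norm running buffers are restored afterwards so
    evaluation has no side effects.
    """
    arr = _as_array(images).astype(np.float32)
    norm, _ = normalize_intensity(arr, state.normalization)
    G, E = state.nets["generator"], state.nets["encoder"]
    snapshots = [(b, b.data.copy()) for net in (G, E) for _, b in net.buffers()]
    try:
        with ad.no_grad():
            z = E(ad.tensor(norm), train=True)
            rec = G(z, train=True)
    finally:
        for buf, saved in snapshots:
            buf.data = saved
    return float(np.mean(np.sum(np.abs(norm - rec.data),
                                axis=tuple(range(1, norm.ndim)))))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: TrainState, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    arrays = {}
    for name, net in state.nets.items():
        for k, v in net.state_dict().items():
            arrays[f"net.{name}.{k}"] = v
    for name, optim in state.optims.items():
        for k, v in optim.state_dict().items():
            arrays[f"optim.{name}.{k}"] = v
    arrays["normalization"] = state.normalization
    np.savez(os.path.join(out_dir, "checkpoint.npz"), **arrays)
    meta = {
        "specs": {name: net.spec.to_json() for name, net in state.nets.items()},
        "seeds": {name: net.seed for name, net in state.nets.items()},
        "config": asdict(state.config),
        "epoch": state.epoch,
        "step_counts": state.step_counts,
        "history": state.history,
        "rng_state": state.rng.bit_generator.state,
        "voxel_size": list(state.voxel_size),
    }
    with open(os.path.join(out_dir, "meta.json"), "w") as fh:
        json.dump(meta, fh)


def load_checkpoint(out_dir) -> TrainState:
    with open(os.path.join(out_dir, "meta.json")) as fh:
        meta = json.load(fh)
    data = np.load(os.path.join(out_dir, "checkpoint.npz"))
    config = TrainConfig(**meta["config"])
    nets, optims = {}, {}
    for name, spec_json in meta["specs"].items():
        spec = NetSpec.from_json(spec_json)
        net = build(spec, seed=meta["seeds"][name])
        prefix = f"net.{name}."
        net.load_state_dict({k[len(prefix):]: data[k] for k in data.files
                             if k.startswith(prefix)})
        nets[name] = net
        optim = Adam(net.parameters(), lr=config.lr)
        oprefix = f"optim.{name}."
        optim.load_state_dict({k[len(oprefix):]: data[k] for k in data.files
                               if k.startswith(oprefix)})
        optims[name] = optim
    rng = np.random.default_rng()
    rng.bit_generator.state = meta["rng_state"]
    state = TrainState(nets, optims, rng, config, data["normalization"],
                       tuple(meta["voxel_size"]), epoch=meta["epoch"],
                       step_counts=meta["step_counts"], history=meta["history"])
    return state
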