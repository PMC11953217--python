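"""Sampling synthetic FOD volumes from a trained generator."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .sh import SHBasis, SHImage, write_fod
from .training import TrainState, denormalize_intensity, load_checkpoint

__all__ = ["SampleRequest", "sample_latent", "generate_images", "generate_fods"]


@dataclass(frozen=True)
class SampleRequest:
    n_samples: int
    latent_dim: int
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.n_samples < 1 or self.latent_dim < 1:
            raise ValueError("n_samples and latent_dim must be >= 1")


def sample_latent(n: int, dim: int, seed: int) -> np.ndarray:
    """(n, dim) i.i.d. standard-normal latent batch, deterministic per seed."""
    if n < 1 or dim < 1:
        raise ValueError("n and dim must be >= 1")
    return np.random.default_rng(seed).standard_normal((n, dim)).astype(np.float32)


def generate_images(state: TrainState, n: int, seed: int, batch: int = 8) -> list:
    """Decode n latent draws into denormalised SHImage volumes (eval mode)."""
    G = state.nets["generator"]
    latent = G.spec.latent_dim
    z = sample_latent(n, latent, seed)
    basis = SHBasis.from_n_coeff(G.spec.output_shape[0])
    out = []
    for start in range(0, n, batch):
        with ad.no_grad():
            raw = G(ad.tensor(z[start:start + batch]), train=False).data
        for item in raw:
            coeffs = denormalize_intensity(item.astype(np.float64), state.normalization)
            out.append(SHImage(coeffs, state.voxel_size, basis))
    return out


def generate_fods(checkpoint, request: SampleRequest) -> list:
    """Generate volumes from a checkpoint directory and write them as NIfTI.

    Files are zero-padded ``fod_###.nii.gz`` plus a ``manifest.json`` carrying
    the seed and file list, so generated cohorts are citable and reproducible.
    Returns the list of written paths (or the images if no out_dir is set).
    """
    state = checkpoint if isinstance(checkpoint, TrainState) else load_checkpoint(checkpoint)
    latent = state.nets["generator"].spec.latent_dim
    if request.latent_dim != latent:
        raise ValueError(f"request latent dim {request.latent_dim} != checkpoint "
                         f"latent dim {latent}")
    images = generate_images(state, request.n_samples, request.seed)
    if request.out_dir is None:
        return images
    os.makedirs(request.out_dir, exist_ok=True)
    paths = []
    for i, img in enumerate(images):
        path = os.path.join(request.out_dir, f"fod_{i:03d}.nii.gz")
        write_fod(img, path)
        paths.append(path)
    with open(os.path.join(request.out_dir, "manifest.json"), "w") as fh:
        json.dump({"seed": request.seed, "n_samples": request.n_samples,
                   "latent_dim": latent,
                   "files": [os.path.basename(p) for p in paths]}, fh, indent=1)
    return paths
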