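"""Seeded synthetic FOD phantoms with matching ground truth.

Real training data for the generative model are brain FOD volumes; the
phantoms emulate their qualitative structure at desk scale: an ellipsoidal
"brain" support with zero background, a small number of smooth fibre bundles
whose voxels carry a single-fibre SH lobe aligned with the local tangent
(summed where bundles cross), an isotropic "ventricle" compartment, additive
coefficient noise, and per-subject geometric jitter.  Every output is a pure
function of (spec, seed).

Bundle lobes use the zonal-harmonic addition theorem: an axially symmetric
kernel with zonal coefficients ``c_l`` about +z has coefficients
``c_l * sqrt(4*pi/(2l+1)) * Y_lm(mu)`` about axis ``mu``, which equals
rotating the canonical lobe with :func:`fodgan.sh.rotate_sh` but vectorises
over all voxels at once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .sh import SHBasis, SHImage, basis_matrix, fit_sh, sphere_points
from .tracts import Connectome, StreamlineSet

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "make_cohort",
           "make_toy_connectome", "single_fibre_lobe", "lobe_at_directions"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of a synthetic FOD phantom."""

    grid_dims: tuple = (16, 16, 8)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    lmax: int = 6
    n_bundles: int = 2
    bundle_radius: float = 3.0          # mm
    bundle_amplitude: float = 1.0       # peak FOD amplitude of one lobe
    bundle_bow: float = 0.05            # control-point bow, fraction of extent
    bundle_paths: tuple | None = None   # explicit (n_bundles, 3, 3) control points, mm
    lobe_kappa: float = 5.0             # Watson concentration of the fibre lobe
    ventricle_radii: tuple = (0.12, 0.12, 0.2)  # fractions of extent
    ventricle_amplitude: float = 1.0
    background_amplitude: float = 0.2
    noise_sd: float = 0.005             # coefficient noise inside the brain mask
    jitter_sd: float = 0.5              # mm, per-subject control-point jitter
    n_streamlines: int = 10             # per bundle
    seed: int = 0

    def __post_init__(self):
        if any(d < 4 for d in self.grid_dims):
            raise ValueError("grid dims must be >= 4 per axis")
        if self.bundle_radius <= 0:
            raise ValueError("bundle radius must be positive")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise/jitter standard deviations must be >= 0")

    @property
    def extent(self):
        return tuple(d * v for d, v in zip(self.grid_dims, self.voxel_size))


@dataclass
class Phantom:
    """A phantom image plus its geometric ground truth."""

    image: SHImage
    brain_mask: np.ndarray
    ventricle_mask: np.ndarray
    bundle_masks: list
    bundles: list  # StreamlineSet per bundle


@lru_cache(maxsize=8)
def single_fibre_lobe(lmax: int, kappa: float, amplitude: float = 1.0) -> tuple:
    """Zonal SH coefficients (c_l per even l) of a Watson-like lobe about +z.

    Kernel exp(kappa * (u.z)^2 - kappa), peak value ``amplitude`` along the
    axis before SH truncation.  Fitted once by least squares on a dense
    lattice; m != 0 coefficients vanish by symmetry.
    """
    dirs = sphere_points(1024)
    amp = amplitude * np.exp(kappa * (dirs[:, 2] ** 2 - 1.0))
    coeffs = fit_sh(amp, dirs, SHBasis(lmax))
    zonal = []
    i = 0
    for l in range(0, lmax + 1, 2):
        block = coeffs[i:i + 2 * l + 1]
        zonal.append(block[l])  # m = 0 entry
        i += 2 * l + 1
    return tuple(zonal)


def lobe_at_directions(directions, lmax: int, kappa: float, amplitude: float = 1.0):
    """SH coefficients (n, n_coeff) of the single-fibre lobe aligned per direction."""
    basis = SHBasis(lmax)
    zonal = np.asarray(single_fibre_lobe(lmax, kappa, amplitude))
    B = basis_matrix(basis, directions)
    scale = np.concatenate([
        np.full(2 * l + 1, zonal[i] * np.sqrt(4.0 * np.pi / (2 * l + 1)))
        for i, l in enumerate(range(0, lmax + 1, 2))
    ])
    return B * scale[None, :]


def _bezier(p0, p1, p2, t):
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2


def _bezier_tangent(p0, p1, p2, t):
    t = t[:, None]
    d = 2 * (1 - t) * (p1 - p0) + 2 * t * (p2 - p1)
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def _default_paths(spec: PhantomSpec):
    ex, ey, ez = spec.extent
    c = np.array([ex, ey, ez]) / 2.0
    m = spec.bundle_radius + 1.0  # keep end caps inside the grid
    bow = spec.bundle_bow
    zc = 0.7 * ez  # crossing plane above the central ventricle
    paths = [
        np.array([[m, c[1], zc], [c[0], c[1] + bow * ey, zc], [ex - m, c[1], zc]]),
        np.array([[c[0], m, zc], [c[0] + bow * ex, c[1], zc], [c[0], ey - m, zc]]),
        np.array([[m, m, c[2]], [c[0], c[1], c[2] + bow * ez], [ex - m, ey - m, c[2]]]),
    ]
    while len(paths) < spec.n_bundles:
        k = len(paths)
        paths.append(paths[k % 3] + np.array([0.0, 0.0, 0.2 * ez * (k // 3)]))
    return [p.copy() for p in paths[:spec.n_bundles]]


def _voxel_centres(spec: PhantomSpec):
    grids = np.meshgrid(*[(np.arange(d) + 0.5) * v
                          for d, v in zip(spec.grid_dims, spec.voxel_size)], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def make_phantom(spec: PhantomSpec, _paths=None) -> Phantom:
    """Build one phantom: FOD image, brain/ventricle/bundle masks, streamlines."""
    rng = np.random.default_rng(spec.seed)
    basis = SHBasis(spec.lmax)
    n_coeff = len(basis)
    dims = tuple(spec.grid_dims)
    centres = _voxel_centres(spec)
    extent = np.asarray(spec.extent)
    half = extent / 2.0

    # brain support: inscribed ellipsoid at 0.48 of the half-extent margin
    rel = (centres - half) / (0.96 * half)
    brain = (rel ** 2).sum(axis=1) <= 1.0

    vr = np.asarray(spec.ventricle_radii) * extent
    ventricle = (((centres - half) / vr) ** 2).sum(axis=1) <= 1.0
    ventricle &= brain

    y00 = 1.0 / np.sqrt(4.0 * np.pi)
    coeffs = np.zeros((centres.shape[0], n_coeff))
    coeffs[brain, 0] = spec.background_amplitude / y00

    if _paths is not None:
        paths = _paths
    elif spec.bundle_paths is not None:
        paths = [np.asarray(p, dtype=float) for p in spec.bundle_paths]
    else:
        paths = _default_paths(spec)
    if len(paths) != spec.n_bundles:
        raise ValueError("need one control-point triple per bundle")
    t = np.linspace(0.0, 1.0, 64)
    bundle_masks, bundles = [], []
    for p0, p1, p2 in (np.asarray(p, dtype=float) for p in paths):
        line = _bezier(p0, p1, p2, t)
        if np.any(line < 0) or np.any(line > extent[None, :]):
            raise ValueError("bundle centerline leaves the grid; shrink the path or "
                             "enlarge the grid")
        tang = _bezier_tangent(p0, p1, p2, t)
        d2 = ((centres[:, None, :] - line[None, :, :]) ** 2).sum(axis=2)
        nearest = np.argmin(d2, axis=1)
        inside = (d2[np.arange(len(centres)), nearest] <= spec.bundle_radius ** 2) & brain \
            & ~ventricle
        mask = inside.reshape(dims)
        bundle_masks.append(mask)
        if inside.any():
            lobes = lobe_at_directions(tang[nearest[inside]], spec.lmax,
                                       spec.lobe_kappa, spec.bundle_amplitude)
            coeffs[inside] += lobes

        # streamlines: centerline copies shifted orthogonally within the tube
        lines = []
        for _ in range(spec.n_streamlines):
            ref = tang[len(t) // 2]
            helper = np.array([0.0, 0.0, 1.0])
            if abs(ref @ helper) > 0.9:
                helper = np.array([1.0, 0.0, 0.0])
            e1 = np.cross(ref, helper)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(ref, e1)
            r = spec.bundle_radius * 0.7 * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            offset = r * (np.cos(ang) * e1 + np.sin(ang) * e2)
            pts = np.clip(line + offset, 0.0, extent - 1e-9)
            lines.append(pts)
        bundles.append(StreamlineSet(lines))

    # ventricle: purely isotropic compartment
    coeffs[ventricle, 1:] = 0.0
    coeffs[ventricle, 0] = spec.ventricle_amplitude / y00

    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=coeffs.shape)
        noise[~brain] = 0.0
        noise[ventricle, 1:] = 0.0  # keep the ventricle strictly l=0
        coeffs += noise

    img = SHImage(coeffs.reshape(dims + (n_coeff,)).transpose(3, 0, 1, 2),
                  spec.voxel_size, basis)
    return Phantom(img, brain.reshape(dims), ventricle.reshape(dims),
                   bundle_masks, bundles)


def make_cohort(n: int, spec: PhantomSpec, seed: int) -> list:
    """n phantom images with per-subject jittered geometry (seed + index each)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    images = []
    base_paths = _default_paths(spec) if spec.bundle_paths is None \
        else [np.asarray(p, dtype=float) for p in spec.bundle_paths]
    for i in range(n):
        child = int(seed) + i
        sub = replace(spec, seed=child)
        rng = np.random.default_rng(child + 1_000_003)  # jitter stream, distinct from noise
        paths = [p + rng.normal(0.0, spec.jitter_sd, size=p.shape) for p in base_paths]
        images.append(make_phantom(sub, _paths=paths).image)
    return images


def make_toy_connectome(n_nodes: int, n_blocks: int = 4, density: float = 0.3,
                        seed: int = 0, mean_within: float = 1.0,
                        mean_between: float = 0.1) -> Connectome:
    """Block-structured random connectome: dense diagonal blocks, sparse rest.

    Each upper-triangle entry is Bernoulli(density) * Exponential(mean), the
    mean depending on whether the pair shares a block; symmetrised, zero
    diagonal.  Expected weight per cell is density * mean.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    block = (np.arange(n_nodes) * n_blocks) // n_nodes
    same = block[:, None] == block[None, :]
    means = np.where(same, mean_within, mean_between)
    present = rng.uniform(size=(n_nodes, n_nodes)) < density
    w = rng.exponential(means) * present
    w = np.triu(w, k=1)
    w = w + w.T
    return Connectome(w)
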