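"""Training-pool augmentation by small random rotations.

Each volume is expanded to five instances: the original, one rotation about
each principal axis, and one triply-rotated variant (R_z R_y R_x), with
angles drawn from N(0, sd^2), sd = 1 degree by default.  Rotation acts on
the spatial grid (trilinear resampling about the grid centre, zero padding)
and, by default, reorients the per-voxel SH coefficients with the same
rotation so fibre lobes stay aligned with the rotated anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .sh import Rotation3D, SHImage, sh_rotation_matrix

__all__ = ["AugmentationPolicy", "random_axis_rotation", "random_triple_rotation",
           "rotate_image", "augment_dataset", "augment_cohort"]


@dataclass(frozen=True)
class AugmentationPolicy:
    angle_sd_deg: float = 1.0
    variants: int = 4           # rotated copies per subject, on top of the original
    include_triple: bool = True
    reorient_sh: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.angle_sd_deg < 0:
            raise ValueError("angle sd must be >= 0")
        if self.variants < 0:
            raise ValueError("variants must be >= 0")


def random_axis_rotation(axis: str, sd_deg: float, rng: np.random.Generator) -> Rotation3D:
    """Rotation about a principal axis by an angle ~ N(0, sd_deg^2)."""
    if sd_deg < 0:
        raise ValueError("sd must be >= 0")
    angle = np.radians(rng.normal(0.0, sd_deg)) if sd_deg > 0 else 0.0
    return Rotation3D.about_axis(axis, angle)


def random_triple_rotation(sd_deg: float, rng: np.random.Generator,
                           return_components: bool = False):
    """Product R_z R_y R_x of three independent single-axis rotations."""
    rx = random_axis_rotation("x", sd_deg, rng)
    ry = random_axis_rotation("y", sd_deg, rng)
    rz = random_axis_rotation("z", sd_deg, rng)
    r = rz @ ry @ rx
    return (r, (rx, ry, rz)) if return_components else r


def rotate_image(img: SHImage, R: Rotation3D, reorient_sh: bool = True) -> SHImage:
    """Rotate a coefficient volume about its grid centre (mm).

    Spatial resampling is trilinear with zero padding outside the grid;
    with ``reorient_sh`` the per-voxel SH coefficients are additionally
    rotated so the angular content follows the grid.
    """
    if np.array_equal(R.matrix, np.eye(3)):
        return img.copy()
    dims = img.grid_dims
    voxel = np.asarray(img.voxel_size)
    centre = np.asarray(dims) * voxel / 2.0
    idx = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
    mm = np.stack([(g + 0.5) * v for g, v in zip(idx, voxel)])
    rel = mm.reshape(3, -1) - centre[:, None]
    src_mm = R.matrix.T @ rel + centre[:, None]
    src_idx = (src_mm / voxel[:, None] - 0.5).reshape((3,) + dims)
    out = np.empty_like(img.coefficients)
    for ch in range(out.shape[0]):
        out[ch] = map_coordinates(img.coefficients[ch], src_idx, order=1,
                                  mode="constant", cval=0.0)
    if reorient_sh:
        M = sh_rotation_matrix(img.basis, R)
        out = np.einsum("ij,jxyz->ixyz", M, out)
    return SHImage(out, img.voxel_size, img.basis)


def _policy_rotations(policy: AugmentationPolicy, rng: np.random.Generator):
    rots = []
    axes = ("x", "y", "z")
    for i in range(policy.variants):
        if i < 3:
            rots.append(random_axis_rotation(axes[i], policy.angle_sd_deg, rng))
        elif policy.include_triple:
            rots.append(random_triple_rotation(policy.angle_sd_deg, rng))
        else:
            rots.append(random_axis_rotation(axes[i % 3], policy.angle_sd_deg, rng))
    return rots


def augment_dataset(img: SHImage, policy: AugmentationPolicy,
                    rng: np.random.Generator | None = None) -> list:
    """Original plus ``policy.variants`` rotated copies (default 5 total)."""
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    out = [img.copy()]
    for R in _policy_rotations(policy, rng):
        out.append(rotate_image(img, R, reorient_sh=policy.reorient_sh))
    return out


def augment_cohort(cohort, policy: AugmentationPolicy) -> list:
    """Augment every subject; child-seeded per subject, so order-independent."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    out = []
    for i, img in enumerate(cohort):
        rng = np.random.default_rng(policy.seed + i)
        out.extend(augment_dataset(img, policy, rng))
    return out
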