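"""Quantitative validation of synthetic FOD cohorts.

The suite mirrors how generated brain FOD volumes are compared with a
held-out validation cohort: voxelwise (pairwise sums of squared differences,
per-channel histograms), connectome-wise (sum-to-two normalisation, weighted
global efficiency, Mantel permutation correlations), and tract-wise
(Sorensen-Dice overlap of rasterised bundle masks, along-tract fibre-density
profiles on 100-point resampled streamlines, relative differences of
regional fibre-density statistics).  All comparisons work on the three
groupings of subject pairs: both synthetic, both validation, and mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse.csgraph import dijkstra
from scipy.stats import mannwhitneyu

from .sh import SHImage
from .tracts import Connectome, StreamlineSet

__all__ = ["BinaryMask", "TractProfile", "CohortComparison", "dice",
           "pairwise_ssd", "channel_histograms", "normalize_connectome",
           "global_efficiency", "mantel", "resample_streamline", "afd_map",
           "along_tract_profile", "relative_diff", "streamlines_to_mask",
           "tract_volume", "cohort_compare"]


@dataclass
class BinaryMask:
    """3D boolean grid with isotropic-or-not voxel size in mm."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("mask must be a non-empty 3D grid")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be positive")


@dataclass
class TractProfile:
    """Mean and sd of a scalar map sampled along a tract, per arc increment."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be equal-length vectors")
        if np.any(self.sd < -1e-12):
            raise ValueError("sd must be non-negative")

    @property
    def n_points(self):
        return len(self.mean)


@dataclass
class CohortComparison:
    """Per-pair (or per-subject) statistics for the three pair groupings."""

    syn_syn: np.ndarray
    val_val: np.ndarray
    syn_val: np.ndarray
    p_value: float | None = None


def dice(A: BinaryMask, B: BinaryMask) -> float:
    """Sorensen-Dice overlap 2|A*B| / (|A|+|B|) of two binary volumes."""
    if A.data.shape != B.data.shape:
        raise ValueError(f"mask grids differ: {A.data.shape} vs {B.data.shape}")
    sa, sb = int(A.data.sum()), int(B.data.sum())
    if sa + sb == 0:
        raise ValueError("dice undefined for two empty masks")
    return 2.0 * int((A.data & B.data).sum()) / (sa + sb)


def pairwise_ssd(cohort):
    """Sum of voxelwise squared differences for every unordered image pair.

    Returns (values, mean, sd); values are ordered (i, j), i < j.
    """
    arrs = [im.coefficients if isinstance(im, SHImage) else np.asarray(im)
            for im in cohort]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all images must share grid and basis")
    vals = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            d = arrs[i] - arrs[j]
            vals.append(float(np.dot(d.ravel(), d.ravel())))
    vals = np.asarray(vals)
    return vals, float(vals.mean()), float(vals.std())


def channel_histograms(cohort, bin_edges):
    """Per-channel voxel-value histograms over an entire cohort.

    Counts conserve the total voxel number per channel (edges are padded to
    +-inf), suitable for the log-scale overlays used to compare cohorts.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    edges = np.concatenate([[-np.inf], bin_edges, [np.inf]])
    arrs = [im.coefficients if isinstance(im, SHImage) else np.asarray(im)
            for im in cohort]
    n_ch = arrs[0].shape[0]
    counts = np.zeros((n_ch, len(edges) - 1), dtype=np.int64)
    for a in arrs:
        for ch in range(n_ch):
            counts[ch] += np.histogram(a[ch].ravel(), bins=edges)[0]
    return counts


def normalize_connectome(C: Connectome) -> Connectome:
    """Rescale so all entries sum to two (each connection counted twice)."""
    total = C.total_weight()
    if total <= 0:
        raise ValueError("cannot normalise a connectome with zero total weight")
    return Connectome(C.weights * (2.0 / total), labels=list(C.labels))


def global_efficiency(C: Connectome) -> float:
    """Weighted global efficiency: mean inverse shortest path over node pairs.

    Connection lengths are 1/weight (zero weight = absent edge), path lengths
    accumulate lengths, and disconnected pairs contribute zero efficiency;
    the mean runs over all n(n-1) ordered pairs.
    """
    w = C.weights
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    dist = dijkstra(lengths, directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist), np.divide(1.0, dist,
                       out=np.zeros_like(dist), where=dist > 0), 0.0)
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def _triu_vec(m):
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _corr(a, b, method):
    if method == "spearman":
        a = np.argsort(np.argsort(a)).astype(float)
        b = np.argsort(np.argsort(b)).astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero variance in upper-triangle entries")
    return float((a @ b) / denom)


def mantel(C1, C2, n_permutations: int = 9999, seed: int | None = None,
           method: str = "pearson"):
    """Mantel permutation test between two same-size connectivity matrices.

    r is the correlation of the upper-triangle off-diagonal entries; the
    p-value permutes node labels of the second matrix, with the add-one
    estimator (count of permuted r >= observed + 1) / (n_permutations + 1).
    """
    m1 = C1.weights if isinstance(C1, Connectome) else np.asarray(C1, dtype=float)
    m2 = C2.weights if isinstance(C2, Connectome) else np.asarray(C2, dtype=float)
    if m1.shape != m2.shape or m1.shape[0] < 3:
        raise ValueError("matrices must share shape and have >= 3 nodes")
    v1 = _triu_vec(m1)
    r_obs = _corr(v1, _triu_vec(m2), method)
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    count = 0
    for _ in range(int(n_permutations)):
        perm = rng.permutation(n)
        r = _corr(v1, _triu_vec(m2[np.ix_(perm, perm)]), method)
        if r >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return r_obs, p


def resample_streamline(polyline, n_points: int = 100) -> np.ndarray:
    """Resample a polyline to ``n_points`` equidistant in arc length.

    Endpoints are preserved exactly; interior points are linear
    interpolations along the cumulative arc-length parametrisation.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("polyline needs at least two points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise ValueError("polyline has zero length")
    targets = np.linspace(0.0, s[-1], n_points)
    out = np.column_stack([np.interp(targets, s, pts[:, k]) for k in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def afd_map(img: SHImage) -> np.ndarray:
    """Apparent-fibre-density proxy: the FOD's integral over the sphere.

    In the orthonormal basis this is c0 * sqrt(4*pi) per voxel.  Fixel-wise
    AFD from a segmented FOD can be substituted for this map anywhere a
    scalar volume is accepted.
    """
    return img.coefficients[0] * np.sqrt(4.0 * np.pi)


def _sample_map(map3d, voxel_size, points_mm):
    idx = (points_mm / np.asarray(voxel_size)[None, :]) - 0.5
    return map_coordinates(np.asarray(map3d, dtype=float), idx.T, order=1,
                           mode="nearest")


def along_tract_profile(map3d, tract: StreamlineSet, voxel_size=(1.0, 1.0, 1.0),
                        n_points: int = 100) -> TractProfile:
    """Mean/sd profile of a scalar map along a tract.

    Every streamline is resampled to ``n_points`` equidistant points and the
    map is sampled by trilinear interpolation; statistics run across
    streamlines per increment.
    """
    if len(tract) == 0:
        raise ValueError("tract is empty")
    map3d = np.asarray(map3d, dtype=float)
    extent = np.asarray(map3d.shape) * np.asarray(voxel_size)
    samples = np.empty((len(tract), n_points))
    for i, line in enumerate(tract):
        pts = resample_streamline(line, n_points)
        if np.any(pts < -1e-9) or np.any(pts > extent[None, :] + 1e-9):
            raise ValueError("streamline leaves the map extent")
        samples[i] = _sample_map(map3d, voxel_size, pts)
    return TractProfile(samples.mean(axis=0), samples.std(axis=0))


def relative_diff(mean_syn, mean_val, sd_syn, sd_val):
    """Relative differences |a-b|/(a+b) of fibre-density means and sds."""
    ms, mv = np.asarray(mean_syn, dtype=float), np.asarray(mean_val, dtype=float)
    ss, sv = np.asarray(sd_syn, dtype=float), np.asarray(sd_val, dtype=float)
    if np.any(ms + mv <= 0) or np.any(ss + sv <= 0):
        raise ValueError("relative difference requires positive denominators")
    return np.abs(ms - mv) / (ms + mv), np.abs(ss - sv) / (ss + sv)


def _dda_voxels(p0, p1, voxel, dims, hit):
    """Mark every voxel the segment p0->p1 (mm) traverses (3D DDA)."""
    v = np.asarray(voxel, dtype=float)
    a = p0 / v
    b = p1 / v
    d = b - a
    cur = np.minimum(np.floor(a).astype(int), np.asarray(dims) - 1)
    cur = np.maximum(cur, 0)
    end = np.minimum(np.floor(b).astype(int), np.asarray(dims) - 1)
    end = np.maximum(end, 0)
    hit[tuple(cur)] = True
    step = np.sign(d).astype(int)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for k in range(3):
        if d[k] != 0:
            nxt = np.floor(a[k]) + (1 if step[k] > 0 else 0)
            t_max[k] = (nxt - a[k]) / d[k]
            t_delta[k] = abs(1.0 / d[k])
    guard = int(np.abs(end - cur).sum()) + 6
    for _ in range(guard):
        if np.all(cur == end):
            break
        k = int(np.argmin(t_max))
        cur[k] += step[k]
        cur[k] = min(max(cur[k], 0), dims[k] - 1)
        t_max[k] += t_delta[k]
        hit[tuple(cur)] = True


def streamlines_to_mask(tract: StreamlineSet, voxel_size=1.0, extent=None) -> BinaryMask:
    """Rasterise streamlines onto a voxel grid by segment traversal.

    A voxel is marked if any streamline *segment* passes through it (3D DDA
    walk), not merely if a vertex falls inside, so masks stay continuous at
    coarse step sizes.  ``extent`` is the grid shape in voxels; the grid
    origin is at 0 mm.
    """
    if len(tract) == 0:
        raise ValueError("tract is empty")
    voxel = (float(voxel_size),) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
    all_pts = np.concatenate(list(tract))
    if extent is None:
        extent = tuple(int(np.ceil(all_pts[:, k].max() / voxel[k])) + 1 for k in range(3))
    dims = tuple(int(d) for d in extent)
    bounds = np.asarray(dims) * np.asarray(voxel)
    bad = (all_pts < -1e-9) | (all_pts > bounds[None, :] + 1e-9)
    if np.any(bad):
        offender = all_pts[np.any(bad, axis=1)][0]
        raise ValueError(f"extent {dims} too small: streamline point {offender} mm "
                         f"outside grid bounds {tuple(bounds)} mm")
    hit = np.zeros(dims, dtype=bool)
    for line in tract:
        for p0, p1 in zip(line[:-1], line[1:]):
            _dda_voxels(np.asarray(p0), np.asarray(p1), voxel, dims, hit)
    return BinaryMask(hit, voxel)


def tract_volume(mask: BinaryMask) -> float:
    """Mask volume in mm^3 (voxel count times voxel volume)."""
    return float(mask.data.sum()) * float(np.prod(mask.voxel_size))


def cohort_compare(group_syn, group_val, statistic, mode: str = "pairwise",
                   rng_seed: int | None = None) -> CohortComparison:
    """Compare two cohorts by a statistic.

    ``pairwise`` mode applies ``statistic(a, b)`` to all within- and
    between-group pairs (dice, Mantel r, SSD).  ``per_subject`` mode applies
    ``statistic(a)`` per subject and adds a two-sided Wilcoxon-Mann-Whitney
    rank-sum p-value between the groups (global efficiency, tract volume).
    """
    if not len(group_syn) or not len(group_val):
        raise ValueError("both groups must be non-empty")
    if mode == "pairwise":
        def pairs_within(g):
            return [statistic(g[i], g[j]) for i in range(len(g))
                    for j in range(i + 1, len(g))]
        syn_syn = np.asarray(pairs_within(group_syn), dtype=float)
        val_val = np.asarray(pairs_within(group_val), dtype=float)
        syn_val = np.asarray([statistic(a, b) for a in group_syn for b in group_val],
                             dtype=float)
        return CohortComparison(syn_syn, val_val, syn_val)
    if mode == "per_subject":
        syn = np.asarray([statistic(a) for a in group_syn], dtype=float)
        val = np.asarray([statistic(b) for b in group_val], dtype=float)
        p = float(mannwhitneyu(syn, val, alternative="two-sided").pvalue)
        return CohortComparison(syn, val, np.concatenate([syn, val]), p_value=p)
    raise ValueError(f"unknown mode {mode!r}; use 'pairwise' or 'per_subject'")
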