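"""Validation metrics: overlap, network measures, tract profiling."""

import numpy as np
import pytest

from fodgan import sh
from fodgan.metrics import (BinaryMask, CohortComparison, afd_map,
                            along_tract_profile, channel_histograms,
                            cohort_compare, dice, global_efficiency, mantel,
                            normalize_connectome, pairwise_ssd, relative_diff,
                            resample_streamline, streamlines_to_mask,
                            tract_volume)
from fodgan.tracts import Connectome, StreamlineSet


def _mask(arr):
    return BinaryMask(np.asarray(arr, dtype=bool))


class TestDice:
    def test_identity_is_one(self):
        a = _mask(np.eye(4)[:, :, None])
        assert dice(a, a) == 1.0

    def test_disjoint_is_zero(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, 0, 0] = True
        b[3, 3, 0] = True
        assert dice(_mask(a), _mask(b)) == 0.0

    def test_subset_formula(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.zeros((4, 4, 1), bool)
        a[0, 0, 0] = True
        b[0, 0, 0] = b[0, 1, 0] = b[1, 0, 0] = True
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.5)

    def test_symmetry_and_errors(self, rng):
        a = _mask(rng.uniform(size=(5, 5, 3)) > 0.5)
        b = _mask(rng.uniform(size=(5, 5, 3)) > 0.5)
        assert dice(a, b) == dice(b, a)
        with pytest.raises(ValueError, match="grids differ"):
            dice(a, _mask(np.ones((4, 4, 4), bool)))
        with pytest.raises(ValueError, match="empty"):
            dice(_mask(np.zeros((2, 2, 2))), _mask(np.zeros((2, 2, 2))))


class TestPairwiseSSD:
    def test_examples(self):
        one = sh.SHImage(np.full((1, 1, 1, 1), 1.0), (1, 1, 1), sh.SHBasis(0))
        three = sh.SHImage(np.full((1, 1, 1, 1), 3.0), (1, 1, 1), sh.SHBasis(0))
        vals, mean, sd = pairwise_ssd([one, three])
        assert list(vals) == [4.0]
        vals, _, _ = pairwise_ssd([one, one])
        assert vals[0] == 0.0

    def test_pair_count(self, rng):
        cohort = [rng.standard_normal((2, 3, 3, 3)) for _ in range(5)]
        vals, mean, sd = pairwise_ssd(cohort)
        assert len(vals) == 10  # C(5,2)
        assert mean == pytest.approx(vals.mean())

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_ssd([rng.standard_normal((2, 3, 3, 3)),
                          rng.standard_normal((2, 4, 3, 3))])


class TestChannelHistograms:
    def test_counts_conserve_voxels(self, rng):
        cohort = [rng.standard_normal((3, 4, 4, 2)) for _ in range(3)]
        counts = channel_histograms(cohort, np.linspace(-1, 1, 11))
        assert counts.shape == (3, 12)
        assert np.all(counts.sum(axis=1) == 3 * 4 * 4 * 2)

    def test_constant_image_single_bin(self):
        img = np.full((1, 2, 2, 2), 0.25)
        counts = channel_histograms([img], np.linspace(0, 1, 5))
        assert (counts[0] > 0).sum() == 1


class TestConnectomeMeasures:
    def test_normalization_sum_is_two(self, rng):
        w = np.abs(rng.standard_normal((116, 116)))
        w = np.triu(w, 1)
        conn = Connectome(w + w.T)
        out = normalize_connectome(conn)
        assert out.weights.sum() == pytest.approx(2.0, abs=1e-12)
        assert np.array_equal(out.weights, out.weights.T)

    def test_normalization_idempotent_and_two_node(self):
        two = Connectome(np.array([[0.0, 7.0], [7.0, 0.0]]))
        out = normalize_connectome(two)
        assert out.weights[0, 1] == pytest.approx(1.0)
        again = normalize_connectome(out)
        assert np.allclose(again.weights, out.weights, atol=1e-15)
        with pytest.raises(ValueError):
            normalize_connectome(Connectome(np.zeros((3, 3))))

    def test_global_efficiency_complete_triangle(self):
        w = 0.37
        conn = Connectome(np.full((3, 3), w) - np.diag([w] * 3))
        # direct edge of length 1/w always beats the 2/w detour
        assert global_efficiency(conn) == pytest.approx(w, abs=1e-12)

    def test_global_efficiency_edgeless(self):
        assert global_efficiency(Connectome(np.zeros((5, 5)))) == 0.0

    def _floyd_warshall_eff(self, w):
        n = w.shape[0]
        with np.errstate(divide="ignore"):
            d = np.where(w > 0, 1.0 / w, np.inf)
        np.fill_diagonal(d, 0.0)
        for k in range(n):
            d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
        np.fill_diagonal(inv, 0.0)
        return inv.sum() / (n * (n - 1))

    def test_global_efficiency_matches_floyd_warshall_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 16))
            w = np.abs(rng.standard_normal((n, n)))
            w[rng.uniform(size=(n, n)) < 0.5] = 0.0  # sparse, maybe disconnected
            w = np.triu(w, 1)
            conn = Connectome(w + w.T)
            assert global_efficiency(conn) == pytest.approx(
                self._floyd_warshall_eff(conn.weights), abs=1e-12)

    def test_normalization_preserves_efficiency_ratios(self, rng):
        w = np.abs(rng.standard_normal((12, 12)))
        w = np.triu(w, 1)
        a = Connectome(w + w.T)
        b = Connectome(3.7 * (w + w.T))
        ra = global_efficiency(normalize_connectome(a))
        rb = global_efficiency(normalize_connectome(b))
        assert ra == pytest.approx(rb, rel=1e-12)


class TestMantel:
    def _random_conn(self, seed, n=15):
        rng = np.random.default_rng(seed)
        w = np.abs(rng.standard_normal((n, n)))
        w = np.triu(w, 1)
        return Connectome(w + w.T)

    def test_self_correlation_is_one(self):
        c = self._random_conn(0)
        r, p = mantel(c, c, n_permutations=99, seed=1)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_affine_invariance(self):
        c = self._random_conn(3)
        scaled = Connectome(2.5 * c.weights)
        r, _ = mantel(c, scaled, n_permutations=9, seed=0)
        assert r == pytest.approx(1.0)

    def test_invariant_under_joint_node_permutation(self):
        a, b = self._random_conn(5), self._random_conn(6)
        r0, _ = mantel(a, b, n_permutations=9, seed=0)
        perm = np.random.default_rng(2).permutation(a.n_nodes)
        ap = Connectome(a.weights[np.ix_(perm, perm)])
        bp = Connectome(b.weights[np.ix_(perm, perm)])
        r1, _ = mantel(ap, bp, n_permutations=9, seed=0)
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        flat = Connectome(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="variance"):
            mantel(flat, self._random_conn(1, n=4), n_permutations=9, seed=0)


class TestStreamlineOps:
    def test_resample_unit_spacing(self):
        line = np.array([[0.0, 0, 0], [99.0, 0, 0]])
        out = resample_streamline(line, 100)
        assert out.shape == (100, 3)
        spacing = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(spacing, 1.0, rtol=1e-12)

    def test_resample_preserves_endpoints_and_count(self, rng):
        line = np.cumsum(rng.uniform(0.1, 1.0, size=(17, 3)), axis=0)
        out = resample_streamline(line, 100)
        assert len(out) == 100
        assert np.array_equal(out[0], line[0])
        assert np.array_equal(out[-1], line[-1])
        # equidistance is in arc length along the polyline: walk the segments
        # independently and evaluate the curve at i*L/99
        seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = cum[-1]
        for i in (1, 37, 63, 98):
            s = i * total / 99
            j = int(np.searchsorted(cum, s, side="right")) - 1
            t = (s - cum[j]) / seg[j]
            expected = line[j] + t * (line[j + 1] - line[j])
            assert np.abs(out[i] - expected).max() < 1e-9

    def test_resample_fixed_point(self):
        line = np.linspace([0, 0, 0], [33, 0, 0], 100)
        out = resample_streamline(line, 100)
        assert np.abs(out - line).max() < 1e-10

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            resample_streamline(np.zeros((1, 3)), 10)

    def test_rasterisation_axis_segment(self):
        tract = StreamlineSet([np.array([[0.5, 0.5, 0.5], [5.5, 0.5, 0.5]])])
        mask = streamlines_to_mask(tract, voxel_size=1.0, extent=(8, 2, 2))
        assert mask.data.sum() in (5, 6)  # endpoint-inclusive traversal
        assert np.all(mask.data[:, 1:, :] == 0)

    def test_rasterisation_matches_supersampling_oracle(self, rng):
        pts = np.cumsum(rng.uniform(0.2, 1.5, size=(8, 3)), axis=0) + 1.0
        tract = StreamlineSet([pts])
        mask = streamlines_to_mask(tract, voxel_size=1.0, extent=(16, 16, 16))
        dense = []
        for p0, p1 in zip(pts[:-1], pts[1:]):
            t = np.linspace(0, 1, 2000)[:, None]
            dense.append(p0 + t * (p1 - p0))
        dense = np.floor(np.concatenate(dense)).astype(int)
        oracle = np.zeros((16, 16, 16), bool)
        oracle[tuple(dense.T)] = True
        # DDA must cover every densely-sampled voxel (it may add corner voxels)
        assert np.all(mask.data[oracle])

    def test_mask_monotone_in_streamlines(self):
        a = np.array([[0.5, 0.5, 0.5], [4.5, 0.5, 0.5]])
        b = np.array([[0.5, 3.5, 0.5], [4.5, 3.5, 0.5]])
        m1 = streamlines_to_mask(StreamlineSet([a]), extent=(6, 6, 2))
        m2 = streamlines_to_mask(StreamlineSet([a, b]), extent=(6, 6, 2))
        assert m2.data.sum() >= m1.data.sum()
        assert np.all(m2.data[m1.data])

    def test_extent_too_small_lists_offender(self):
        tract = StreamlineSet([np.array([[0.5, 0.5, 0.5], [9.5, 0.5, 0.5]])])
        with pytest.raises(ValueError, match="too small"):
            streamlines_to_mask(tract, voxel_size=1.0, extent=(4, 2, 2))

    def test_tract_volume(self):
        m = BinaryMask(np.ones((2, 2, 2), bool), (1.0, 1.0, 2.0))
        assert tract_volume(m) == pytest.approx(16.0)


class TestProfilesAndAfd:
    def test_afd_of_unit_isotropic_fod(self):
        c = np.zeros((28, 2, 2, 2))
        c[0] = 1.0 / np.sqrt(4 * np.pi)
        img = sh.SHImage(c, (1, 1, 1), sh.SHBasis(6))
        assert np.allclose(afd_map(img), 1.0)
        zero = sh.SHImage(np.zeros((28, 2, 2, 2)), (1, 1, 1), sh.SHBasis(6))
        assert np.all(afd_map(zero) == 0.0)

    def test_afd_invariant_under_rotation(self, rng):
        c = rng.standard_normal(28)
        img = sh.SHImage(np.tile(c[:, None, None, None], (1, 2, 2, 2)),
                         (1, 1, 1), sh.SHBasis(6))
        R = sh.Rotation3D.about_axis("x", 0.9)
        rot = sh.SHImage(np.tile(sh.rotate_sh(c, R)[:, None, None, None],
                                 (1, 2, 2, 2)), (1, 1, 1), sh.SHBasis(6))
        assert afd_map(rot) == pytest.approx(afd_map(img), abs=1e-8)

    def test_constant_map_profile_exactly_constant(self):
        grid = np.full((10, 10, 10), 2.5)
        tract = StreamlineSet([np.array([[1.0, 1, 1], [8.0, 8, 8]]),
                               np.array([[2.0, 1, 1], [8.0, 7, 7]])])
        prof = along_tract_profile(grid, tract, voxel_size=(1, 1, 1))
        assert prof.n_points == 100
        assert np.abs(prof.mean - 2.5).max() < 1e-12  # no endpoint leakage
        assert prof.sd.max() < 1e-12

    def test_single_streamline_zero_sd(self, rng):
        grid = rng.uniform(1, 2, size=(8, 8, 8))
        tract = StreamlineSet([np.array([[1.0, 1, 1], [6.0, 6, 6]])])
        prof = along_tract_profile(grid, tract)
        assert np.all(prof.sd == 0.0)

    def test_linear_gradient_gives_linear_profile(self):
        # map f(x) = x sampled along a straight x-aligned line
        xs = (np.arange(20) + 0.5)[:, None, None]
        grid = np.broadcast_to(xs, (20, 4, 4)).copy()
        tract = StreamlineSet([np.array([[2.0, 2.0, 2.0], [18.0, 2.0, 2.0]])])
        prof = along_tract_profile(grid, tract)
        expected = np.linspace(2.0, 18.0, 100)
        assert np.abs(prof.mean - expected).max() < 1e-9

    def test_streamline_outside_extent_rejected(self):
        grid = np.zeros((4, 4, 4))
        tract = StreamlineSet([np.array([[1.0, 1, 1], [9.0, 1, 1]])])
        with pytest.raises(ValueError, match="extent"):
            along_tract_profile(grid, tract)


class TestRelativeDiff:
    def test_examples(self):
        dfd, dsd = relative_diff(3.0, 1.0, 2.0, 2.0)
        assert dfd == pytest.approx(0.5)
        assert dsd == 0.0
        assert relative_diff(1.0, 3.0, 1.0, 1.0)[0] == pytest.approx(0.5)  # symmetric

    def test_positive_denominator_required(self):
        with pytest.raises(ValueError):
            relative_diff(0.0, 0.0, 1.0, 1.0)


class TestCohortCompare:
    def test_pairwise_counts(self, rng):
        syn = [rng.standard_normal(6) for _ in range(5)]
        val = [rng.standard_normal(6) for _ in range(4)]
        stat = lambda a, b: float(np.sum((a - b) ** 2))
        cmp = cohort_compare(syn, val, stat, mode="pairwise")
        assert len(cmp.syn_syn) == 10 and len(cmp.val_val) == 6
        assert len(cmp.syn_val) == 20

    def test_identical_groups_have_same_pair_distribution(self, rng):
        group = [rng.standard_normal(8) for _ in range(6)]
        stat = lambda a, b: float(np.abs(a - b).sum())
        cmp = cohort_compare(group, list(group), stat, mode="pairwise")
        # between-group pairs include all within-group pairs (plus self-pairs)
        within = np.sort(cmp.syn_syn)
        between = np.sort(cmp.syn_val)
        assert set(np.round(within, 10)).issubset(set(np.round(between, 10)))

    def test_per_subject_rank_sum_null_calibration(self):
        # same-distribution groups: p <= 0.05 in at most ~5% of replicates
        rejections = 0
        for rep in range(200):
            rng = np.random.default_rng(rep)
            syn = rng.standard_normal(12)
            val = rng.standard_normal(12)
            cmp = cohort_compare(list(syn), list(val), float, mode="per_subject")
            rejections += cmp.p_value <= 0.05
        assert rejections <= 20  # <= 10% of 200

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            cohort_compare([1], [2], float, mode="nope")
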