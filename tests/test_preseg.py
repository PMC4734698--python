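import itertools

import numpy as np
import pytest

from vesselseg.gabor import GaborBankConfig, PixelFeatureStack
from vesselseg.preseg import (
    fit_kmeans,
    kmeans_objective,
    refine_mask,
    select_foreground,
    stain_od,
    supervised_init,
)

from .oracles import kmeans_objective_double_loop


def stack_from(arr):
    arr = np.asarray(arr, dtype=np.float64)
    return PixelFeatureStack(values=arr, config=GaborBankConfig(n_freqs=1, n_orients=1))


class TestObjective:
    def test_zero_when_points_on_centroids(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert kmeans_objective(pts, pts.copy(), np.array([0, 1])) == 0.0

    def test_two_points_one_centroid(self):
        pts = np.array([[0.0], [2.0]])
        assert kmeans_objective(pts, np.array([[1.0]]), np.array([0, 0])) == 2.0

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(20, 3))
            cents = rng.normal(size=(2, 3))
            assign = rng.integers(0, 2, size=20)
            want = kmeans_objective_double_loop(pts, cents, assign)
            assert kmeans_objective(pts, cents, assign) == pytest.approx(want)

    def test_mismatched_assignment_rejected(self):
        with pytest.raises(ValueError):
            kmeans_objective(np.zeros((3, 2)), np.zeros((2, 2)), np.array([0, 1]))


class TestLloyd:
    def test_separated_blobs_split_exactly(self):
        pts = np.array([[0.0], [0.1], [10.0], [10.1]])
        res = fit_kmeans(pts, k=2, seed=0, standardize=False)
        assert res.converged
        a = res.assignment
        assert a[0] == a[1] and a[2] == a[3] and a[0] != a[2]
        assert res.objective_j == pytest.approx(0.01, rel=1e-4)

    def test_never_beats_exhaustive_partition_optimum(self, rng):
        """Enumerate all 2^12 two-cluster partitions as the global optimum."""
        pts = rng.normal(size=(12, 2))
        best = np.inf
        best_assign = None
        for bits in itertools.product([0, 1], repeat=12):
            assign = np.array(bits)
            if assign.min() == assign.max():
                continue
            cents = np.stack([pts[assign == j].mean(axis=0) for j in (0, 1)])
            j = kmeans_objective(pts, cents, assign)
            if j < best:
                best, best_assign = j, assign
        res = fit_kmeans(pts, k=2, seed=0, standardize=False)
        assert res.objective_j >= best - 1e-9
        # initialized at the optimum's barycenters, Lloyd stays there
        opt_cents = np.stack([pts[best_assign == j].mean(axis=0) for j in (0, 1)])
        res_opt = fit_kmeans(pts, k=2, init=opt_cents, standardize=False)
        assert res_opt.objective_j == pytest.approx(best, rel=1e-5)

    def test_objective_monotone_nonincreasing(self, rng):
        pts = rng.normal(size=(500, 5))
        res = fit_kmeans(pts, k=2, seed=3)
        hist = np.array(res.objective_history)
        assert (np.diff(hist) <= 1e-6 * np.maximum(1, hist[:-1])).all()

    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(size=(300, 4))
        a = fit_kmeans(pts, k=2, seed=7)
        b = fit_kmeans(pts, k=2, seed=7)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.objective_j == b.objective_j

    def test_channel_permutation_leaves_assignment(self, rng):
        pts = rng.normal(size=(200, 6)) + np.array([0, 0, 0, 5, 5, 5])
        perm = [3, 1, 5, 0, 2, 4]
        a = fit_kmeans(pts, k=2, init=pts[:2].copy())
        b = fit_kmeans(pts[:, perm], k=2, init=pts[:2, perm].copy())
        assert np.array_equal(a.assignment, b.assignment)

    def test_needs_k_distinct_points(self):
        pts = np.zeros((50, 3))
        with pytest.raises(ValueError, match="distinct"):
            fit_kmeans(pts, k=2)

    def test_empty_cluster_relocated(self):
        # far-out init centroid captures nothing on the first pass
        pts = np.vstack([np.zeros((5, 1)), np.ones((5, 1))])
        init = np.array([[0.5], [100.0]])
        res = fit_kmeans(pts, k=2, init=init, standardize=False)
        assert set(np.unique(res.assignment)) == {0, 1}


class TestForegroundSelection:
    def test_stronger_cluster_wins_and_label_symmetry(self):
        vals = np.zeros((4, 4, 2))
        vals[:2, :, :] = 5.0  # top half responds strongly
        feats = stack_from(vals)
        res = fit_kmeans(feats, k=2, seed=0)
        mask = select_foreground(res, feats)
        assert mask.pixels[:2, :].all() and not mask.pixels[2:, :].any()
        # swapping cluster indices changes nothing
        from dataclasses import replace

        swapped = replace(
            res,
            assignment=1 - res.assignment,
            centroids=res.centroids[::-1].copy(),
        )
        mask2 = select_foreground(swapped, feats)
        assert np.array_equal(mask.pixels, mask2.pixels)

    def test_exact_tie_warns_and_picks_cluster_zero(self):
        vals = np.zeros((2, 2, 1))
        vals[0, :, 0] = 1.0
        vals[1, :, 0] = -1.0  # symmetric magnitudes
        feats = stack_from(np.abs(vals))
        from vesselseg.preseg import KMeansResult

        res = KMeansResult(
            centroids=np.array([[1.0], [1.0]]),
            assignment=np.array([0, 0, 1, 1]),
            objective_j=0.0,
            n_iterations=1,
            objective_history=(0.0,),
            converged=True,
        )
        with pytest.warns(UserWarning, match="tie"):
            mask = select_foreground(res, feats)
        assert mask.pixels[0].all() and not mask.pixels[1].any()


class TestSupervisedInit:
    def test_centroids_are_group_means(self, rng):
        pts = rng.normal(size=(40, 3))
        fg = np.zeros(40, dtype=bool)
        fg[:10] = True
        init = supervised_init(pts, fg, standardize=False)
        np.testing.assert_allclose(init[1], pts[:10].mean(axis=0))
        np.testing.assert_allclose(init[0], pts[10:].mean(axis=0))

    def test_rejects_single_class_annotation(self, rng):
        pts = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            supervised_init(pts, np.ones(10, dtype=bool))


class TestStainGate:
    def test_od_zero_on_flat_field(self):
        from vesselseg.io import IHCImage

        img = IHCImage(np.full((64, 64), 40000, dtype=np.uint16))
        od = stain_od(img)
        assert np.allclose(od, 0.0, atol=1e-6)

    def test_dark_spot_detected(self):
        from vesselseg.io import BinaryMask, IHCImage

        arr = np.full((64, 64), 40000, dtype=np.uint16)
        arr[30:34, 30:34] = 20000
        img = IHCImage(arr)
        od = stain_od(img)
        assert od[31, 31] > 0.3
        mask = refine_mask(BinaryMask(np.ones_like(arr, dtype=bool)), img)
        assert mask.pixels[30:34, 30:34].all()
        assert mask.pixels.sum() <= 6 * 6
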