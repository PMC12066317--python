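import numpy as np
import pytest
from scipy import stats as sps

import dbsmap.sweetspot as ss
from dbsmap import (
    ImageVolume,
    SweetSpotModel,
    build_n_image,
    classify_sweet_sour,
    coverage_filter,
    fdr_correct,
    mean_effect_map,
    voxelwise_signed_rank,
)
from dbsmap.sweetspot import coverage_threshold


def _grid(n=10):
    return ImageVolume(np.zeros((n, n, n)), np.diag([1.0, 1.0, 1.0, 1.0]))


def _ball(grid, center, r):
    ijk = np.indices(grid.shape).reshape(3, -1).T
    d = np.linalg.norm(ijk - np.asarray(center), axis=1)
    return np.flatnonzero((d <= r).reshape(-1))


class TestNImage:
    def test_identical_vtas_count(self):
        grid = _grid()
        idx = _ball(grid, (5, 5, 5), 2)
        n = build_n_image([idx, idx, idx], grid)
        flat = n.data.ravel()
        assert np.all(flat[idx] == 3)
        assert flat.sum() == 3 * idx.size

    def test_disjoint_vtas_max_one(self):
        grid = _grid()
        a = _ball(grid, (2, 2, 2), 1)
        b = _ball(grid, (7, 7, 7), 1)
        n = build_n_image([a, b], grid)
        assert n.data.max() == 1
        assert n.data.sum() == a.size + b.size

    def test_counts_conserved(self):
        grid = _grid()
        rng = np.random.default_rng(0)
        idxs = [rng.choice(1000, size=rng.integers(5, 40), replace=False)
                for _ in range(7)]
        n = build_n_image(idxs, grid)
        assert n.data.sum() == sum(i.size for i in idxs)


class TestCoverageFilter:
    def test_twenty_percent_of_56_needs_12(self):
        assert coverage_threshold(56, 0.2) == 12  # ceil(11.2)

    def test_tiny_fraction_keeps_any_coverage(self):
        grid = _grid()
        n = build_n_image([_ball(grid, (5, 5, 5), 2)], grid)
        kept = coverage_filter(n, 10, fraction=1e-9)
        np.testing.assert_array_equal(kept.data, n.data >= 1)

    def test_all_zero_counts_empty(self):
        kept = coverage_filter(_grid().like(np.zeros((10, 10, 10), int)), 56, 0.2)
        assert not kept.data.any()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            coverage_threshold(56, 1.5)


class TestMeanEffectMap:
    def test_two_patient_arithmetic(self):
        grid = _grid()
        a = _ball(grid, (5, 5, 5), 2)
        b = _ball(grid, (5, 5, 5), 1)  # subset of a
        kept = grid.like(build_n_image([a, b], grid).data >= 1)
        m = mean_effect_map([a, b], np.array([4.0, -2.0]), kept)
        flat = m.data.ravel()
        assert flat[b].max() == flat[b].min() == pytest.approx(1.0)
        only_a = np.setdiff1d(a, b)
        assert flat[only_a].max() == pytest.approx(4.0)

    def test_constant_changes_constant_map(self):
        grid = _grid()
        idxs = [_ball(grid, (5, 5, 5), 2), _ball(grid, (4, 5, 5), 2)]
        kept = grid.like(build_n_image(idxs, grid).data >= 1)
        m = mean_effect_map(idxs, np.array([3.0, 3.0]), kept)
        vals = m.data[kept.data.astype(bool)]
        np.testing.assert_allclose(vals, 3.0)

    def test_patient_order_invariant(self):
        grid = _grid()
        idxs = [_ball(grid, (5, 5, 5), 2), _ball(grid, (4, 4, 4), 2), _ball(grid, (6, 6, 6), 1)]
        ch = np.array([1.0, -3.0, 2.0])
        kept = grid.like(build_n_image(idxs, grid).data >= 1)
        m1 = mean_effect_map(idxs, ch, kept)
        perm = [2, 0, 1]
        m2 = mean_effect_map([idxs[i] for i in perm], ch[perm], kept)
        np.testing.assert_allclose(m1.data, m2.data, equal_nan=True)


class TestVoxelwiseSignedRank:
    def test_matches_per_voxel_oracle(self):
        grid = _grid()
        rng = np.random.default_rng(1)
        idxs = [_ball(grid, tuple(rng.integers(3, 7, 3)), rng.integers(1, 3))
                for _ in range(9)]
        ch = rng.normal(0.5, 1.0, 9)
        kept = grid.like(build_n_image(idxs, grid).data >= 2)
        pmap = voxelwise_signed_rank(idxs, ch, kept).data.ravel()
        from dbsmap._stats import signed_rank_p

        cover = np.zeros((9, np.prod(grid.shape)), dtype=bool)
        for i, idx in enumerate(idxs):
            cover[i, idx] = True
        for v in np.flatnonzero(kept.data.ravel()):
            assert pmap[v] == signed_rank_p(ch[cover[:, v]])

    def test_sign_flip_leaves_p_unchanged(self):
        grid = _grid()
        rng = np.random.default_rng(2)
        idxs = [_ball(grid, (5, 5, 5), 2), _ball(grid, (5, 5, 4), 2),
                _ball(grid, (5, 4, 5), 2)]
        ch = rng.normal(size=3)
        kept = grid.like(build_n_image(idxs, grid).data >= 2)
        p1 = voxelwise_signed_rank(idxs, ch, kept).data
        p2 = voxelwise_signed_rank(idxs, -ch, kept).data
        np.testing.assert_allclose(p1, p2, equal_nan=True)


class TestFdrAndLabels:
    def test_bh_hand_example(self):
        grid = ImageVolume(np.zeros((4, 1, 1)), np.eye(4))
        p = grid.like(np.array([0.01, 0.02, 0.03, 0.04]).reshape(4, 1, 1))
        q = fdr_correct(p)
        np.testing.assert_allclose(q.data.ravel(), 0.04)

    def test_single_voxel_q_equals_p(self):
        grid = ImageVolume(np.zeros((1, 1, 1)), np.eye(4))
        q = fdr_correct(grid.like(np.full((1, 1, 1), 0.012)))
        assert q.data.ravel()[0] == pytest.approx(0.012)

    def test_q_monotone_in_p(self):
        grid = ImageVolume(np.zeros((50, 1, 1)), np.eye(4))
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=50))
        q = fdr_correct(grid.like(p.reshape(50, 1, 1))).data.ravel()
        assert np.all(np.diff(q) >= -1e-12)

    def test_classification(self):
        grid = ImageVolume(np.zeros((3, 1, 1)), np.eye(4))
        mean = grid.like(np.array([3.0, -3.0, 3.0]).reshape(3, 1, 1))
        q = grid.like(np.array([0.01, 0.01, 0.2]).reshape(3, 1, 1))
        lab = classify_sweet_sour(mean, q, alpha=0.05).data.ravel()
        assert lab.tolist() == [1.0, -1.0, 0.0]


class TestPrediction:
    def _maps(self, grid, idxs, ch, alpha=0.05):
        return ss._fit_flat(idxs, ch, int(np.prod(grid.shape)), 0.2, alpha)

    def test_uniform_map_predicts_its_value(self):
        grid = _grid()
        idx = _ball(grid, (5, 5, 5), 2)
        ch = np.array([2.0 + 1e-3 * i for i in range(12)])  # all ~+2, distinct
        maps = self._maps(grid, [idx] * 12, ch)
        val, fb = ss._predict_flat(maps, idx)
        # trained mean-effect under the VTA, relative to the training mean
        assert val == pytest.approx(ch.mean() - maps.train_mean, abs=1e-9)
        assert not fb

    def test_empty_intersection_flagged_zero(self):
        grid = _grid()
        idx = _ball(grid, (3, 3, 3), 2)
        far = _ball(grid, (8, 8, 8), 1)
        maps = self._maps(grid, [idx] * 12, np.linspace(1, 2, 12))
        val, fb = ss._predict_flat(maps, far)
        assert val == 0.0 and fb

    def test_voxel_order_invariant(self):
        grid = _grid()
        idx = _ball(grid, (5, 5, 5), 2)
        maps = self._maps(grid, [idx] * 12, np.linspace(-1, 3, 12))
        v1, _ = ss._predict_flat(maps, idx)
        v2, _ = ss._predict_flat(maps, idx[::-1])
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestModel:
    def test_fit_invariants(self, ventral_cohort):
        res = SweetSpotModel(ventral_cohort, "HAMA", hemisphere="left").fit()
        kept = res.kept_mask.data.astype(bool)
        # excluded voxels are NaN everywhere; kept voxels carry finite maps
        assert np.isnan(res.mean_effect.data[~kept]).all()
        assert np.isfinite(res.q_map.data[kept]).all()
        thresh = coverage_threshold(56, 0.2)
        assert res.n_image.data[kept].min() >= thresh
        lab = res.label_map.data[kept]
        mean = res.mean_effect.data[kept]
        q = res.q_map.data[kept]
        assert np.all(mean[lab == 1] > 0) and np.all(q[lab == 1] <= 0.05)
        assert np.all(mean[lab == -1] < 0)

    def test_loocv_yields_one_prediction_per_patient(self, small_cohort):
        cv = SweetSpotModel(small_cohort, "HAMA").cross_validate("loocv")
        assert len(cv.predicted) == small_cohort.n_patients
        assert cv.scheme == "loocv"

    def test_kfold_partitions_patients(self, small_cohort):
        from dbsmap import make_folds

        folds = make_folds(12, "kfold", k=5, seed=3)
        allidx = np.concatenate(folds)
        assert sorted(allidx.tolist()) == list(range(12))

    def test_plot_slices_runs(self, small_cohort):
        import matplotlib

        matplotlib.use("Agg")
        res = SweetSpotModel(small_cohort, "HAMA").fit()
        ax = res.plot_slices()
        assert ax.get_title().startswith("mean HAMA change")

    def test_heldout_vtas_never_enter_training(self, small_cohort, monkeypatch):
        model = SweetSpotModel(small_cohort, "HAMA")
        seen = []
        orig = ss._fit_flat

        def spy(vta_indices, changes, *args, **kwargs):
            seen.append([id(v) for v in vta_indices])
            return orig(vta_indices, changes, *args, **kwargs)

        monkeypatch.setattr(ss, "_fit_flat", spy)
        model.cross_validate("loocv")
        all_ids = [id(v) for v in model.vta_indices]
        assert len(seen) == small_cohort.n_patients
        for i, fold_ids in enumerate(seen):
            assert len(fold_ids) == small_cohort.n_patients - 1
            assert all_ids[i] not in fold_ids
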