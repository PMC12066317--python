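import numpy as np
import pytest

from dbsmap import generate_cohort, make_electrode, make_toy_atlas, make_tractogram
from dbsmap.synthetic import (
    SCENARIOS,
    STN_CENTERS,
    SWEET_RADIUS_MM,
    simulate_outcomes,
    sweet_sphere_indices,
)


class TestToyAtlas:
    def test_all_regions_present(self, atlas):
        present = set(np.unique(atlas.volume.data).tolist())
        assert present == {0, 1, 2, 3, 4, 5, 6, 7, 8}

    def test_mirror_symmetric_stn_volumes(self, atlas):
        left = atlas.mask("STN_left").sum()
        right = atlas.mask("STN_right").sum()
        assert left == right
        for sub in ("sensorimotor", "associative", "limbic"):
            assert atlas.mask(f"STN_left_{sub}").sum() == atlas.mask(f"STN_right_{sub}").sum()

    def test_limbic_ventral_of_sensorimotor(self, atlas):
        vol = atlas.volume
        for hemi in ("left", "right"):
            zl = vol.voxel_to_world(np.argwhere(atlas.mask(f"STN_{hemi}_limbic")))[:, 2]
            zs = vol.voxel_to_world(np.argwhere(atlas.mask(f"STN_{hemi}_sensorimotor")))[:, 2]
            assert zl.mean() < zs.mean()
            assert zl.max() < zs.min()  # disjoint thirds along the axis

    def test_coarse_voxels_rejected(self):
        with pytest.raises(ValueError, match="coarse"):
            make_toy_atlas((48, 48, 48), voxel_size_mm=1.0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="40"):
            make_toy_atlas((30, 30, 30), voxel_size_mm=0.5)


class TestMakeElectrode:
    def test_contact0_at_ventral_limbic_voxel(self, atlas):
        e = make_electrode(atlas, "left", dorsoventral_offset_mm=0.0, rng=None)
        limbic = atlas.volume.voxel_to_world(np.argwhere(atlas.mask("STN_left_limbic")))
        ventral_most = limbic[np.argmin(limbic[:, 2])]
        assert np.linalg.norm(e.contact_coords[0] - ventral_most) <= 0.5

    def test_offset_translates_z(self, atlas):
        e0 = make_electrode(atlas, "right", 0.0)
        e4 = make_electrode(atlas, "right", 4.0)
        np.testing.assert_allclose(
            e4.contact_coords[:, 2] - e0.contact_coords[:, 2], 4.0, atol=1e-9)
        np.testing.assert_allclose(e4.contact_coords[:, :2], e0.contact_coords[:, :2])

    def test_same_seed_identical(self, atlas):
        a = make_electrode(atlas, "left", 2.0, rng=np.random.default_rng(5))
        b = make_electrode(atlas, "left", 2.0, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.contact_coords, b.contact_coords)

    def test_jitter_bounded(self, atlas):
        e0 = make_electrode(atlas, "left", 0.0)
        for seed in range(10):
            e = make_electrode(atlas, "left", 0.0, rng=np.random.default_rng(seed))
            assert np.all(np.abs(e.contact_coords[0, :2] - e0.contact_coords[0, :2]) <= 0.5)


class TestMakeTractogram:
    def test_counts_and_lengths(self, atlas):
        t, bundles = make_tractogram(atlas, 100, np.random.default_rng(0))
        assert t.count == 200
        assert all(len(s) >= 10 for s in t.streamlines)
        assert len(bundles["PFC"]) == len(bundles["SMC"]) == 100

    def test_pfc_bundle_starts_in_limbic_voxels(self, atlas):
        t, bundles = make_tractogram(atlas, 30, np.random.default_rng(1))
        vol = atlas.volume
        limbic = atlas.mask("STN_left_limbic") | atlas.mask("STN_right_limbic")
        for i in bundles["PFC"]:
            ijk = np.rint(vol.world_to_voxel(t.streamlines[i][0])).astype(int)[0]
            assert limbic[tuple(ijk)]

    def test_smc_bundle_starts_dorsal(self, atlas):
        t, bundles = make_tractogram(atlas, 30, np.random.default_rng(2))
        sm = atlas.mask("STN_left_sensorimotor") | atlas.mask("STN_right_sensorimotor")
        vol = atlas.volume
        for i in bundles["SMC"]:
            ijk = np.rint(vol.world_to_voxel(t.streamlines[i][0])).astype(int)[0]
            assert sm[tuple(ijk)]

    def test_deterministic(self, atlas):
        t1, _ = make_tractogram(atlas, 20, np.random.default_rng(3))
        t2, _ = make_tractogram(atlas, 20, np.random.default_rng(3))
        for a, b in zip(t1.streamlines, t2.streamlines):
            np.testing.assert_array_equal(a, b)

    def test_too_few_fibers_rejected(self, atlas):
        with pytest.raises(ValueError, match="10"):
            make_tractogram(atlas, 5)


class TestSimulatedOutcomes:
    def test_zero_noise_no_overlap_no_fibers_gives_zero_change(self, null_cohort):
        # null scenario with noise off: the additive model must give 0
        c = generate_cohort(8, "null", seed=2, noise_sd=0.0, n_fibers_per_bundle=10)
        np.testing.assert_allclose(c.changes("HAMA"), 0.0, atol=1e-12)

    def test_change_monotone_in_sphere_overlap(self):
        c = generate_cohort(20, "ventral_effect", seed=4, noise_sd=0.0,
                            n_fibers_per_bundle=10)
        from dbsmap.vta import compute_cohort_vtas, patient_vta_indices

        vtas = compute_cohort_vtas(c)
        unions = patient_vta_indices(c, vtas)
        sphere = sweet_sphere_indices(c.atlas.volume)
        frac = np.array([np.intersect1d(u, sphere).size / sphere.size for u in unions])
        ch = c.changes("HAMA")
        order = np.argsort(frac)
        # strictly increasing in overlap wherever overlap differs (noise off,
        # up to the post-score floor at 0)
        unclipped = np.array([c.clinical_record(p).pre("HAMA") > ch[i]
                              for i, p in enumerate(c.patients)])
        f, v = frac[order], ch[order]
        keep = unclipped[order]
        for i in range(len(f) - 1):
            if keep[i] and keep[i + 1] and f[i + 1] > f[i]:
                assert v[i + 1] > v[i]

    def test_ventral_electrodes_improve_more(self):
        c = generate_cohort(24, "ventral_effect", seed=6, noise_sd=0.0,
                            n_fibers_per_bundle=10)
        z = np.array([c.electrode(p, "left").active_coordinate[2] for p in c.patients])
        ch = c.changes("HAMA")
        ventral = ch[z < np.median(z)]
        dorsal = ch[z >= np.median(z)]
        assert ventral.mean() > dorsal.mean()

    def test_regeneration_bit_identical(self):
        a = generate_cohort(56, "ventral_effect", seed=9)
        b = generate_cohort(56, "ventral_effect", seed=9)
        np.testing.assert_array_equal(a.changes("HAMA"), b.changes("HAMA"))
        np.testing.assert_array_equal(a.changes("LEDD"), b.changes("LEDD"))
        for ea, eb in zip(a.electrodes, b.electrodes):
            np.testing.assert_array_equal(ea.contact_coords, eb.contact_coords)
        for sa, sb in zip(a.tractogram.streamlines, b.tractogram.streamlines):
            np.testing.assert_array_equal(sa, sb)

    def test_different_seeds_differ(self):
        a = generate_cohort(8, "null", seed=1, n_fibers_per_bundle=10)
        b = generate_cohort(8, "null", seed=2, n_fibers_per_bundle=10)
        assert not np.array_equal(a.electrodes[0].contact_coords,
                                  b.electrodes[0].contact_coords)


class TestGenerateCohort:
    def test_cardinalities(self, ventral_cohort):
        assert len(ventral_cohort.electrodes) == 112
        assert len(ventral_cohort.clinical) == 56
        assert ventral_cohort.ground_truth.scenario == "ventral_effect"

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="8"):
            generate_cohort(4, "null", seed=0)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            generate_cohort(8, "bogus", seed=0)

    def test_null_change_uncorrelated_with_overlap_large_n(self):
        # Monte-Carlo at n=1000: planted weights are 0, so the change score
        # must be independent of sphere overlap
        c = generate_cohort(1000, "null", seed=13, n_fibers_per_bundle=10)
        from dbsmap.vta import compute_cohort_vtas, patient_vta_indices

        unions = patient_vta_indices(c, compute_cohort_vtas(c))
        sphere = sweet_sphere_indices(c.atlas.volume)
        frac = np.array([np.intersect1d(u, sphere).size / sphere.size for u in unions])
        r = np.corrcoef(frac, c.changes("HAMA"))[0, 1]
        assert abs(r) < 0.1
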