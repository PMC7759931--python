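"""Radiomic extraction: discretisation, resampling, and texture families
checked against closed forms and independent brute-force enumeration."""

import numpy as np
import pandas as pd
import pytest

from ctradiomics.radiomics import (DiscretizationSpec, ExtractionConfig,
                                   VoxelVolume, discretize, extract_all,
                                   feature_map, glcm_features, glrlm_features,
                                   glzlm_features, histogram_shape_features,
                                   ngldm_features, resample_isotropic,
                                   select_largest_lesion, COARSENESS_CAP)
from ctradiomics.synthetic import generate_lesion_phantom

from oracles import oracle_glcm, oracle_glrlm, oracle_glzlm, oracle_ngldm
from conftest import random_labeled_volume


def vol(data, spacing=(1.0, 1.0, 1.0)):
    return VoxelVolume(np.asarray(data, dtype=float), spacing)


class TestDiscretize:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-400.0, 1), (400.0, 128), (0.0, 65), (-1000.0, 1), (1000.0, 128),
         (-399.99, 1), (-393.75, 2)],
    )
    def test_bin_edges_128_over_pm400(self, hu, expected):
        v = vol(np.full((3, 3, 3), hu))
        m = np.ones((3, 3, 3), bool)
        labels = discretize(v, m, DiscretizationSpec(128))
        assert labels[1, 1, 1] == expected

    def test_outside_mask_is_zero(self):
        v = vol(np.zeros((3, 3, 3)))
        m = np.zeros((3, 3, 3), bool)
        m[0, 0, 0] = True
        labels = discretize(v, m, DiscretizationSpec(32))
        assert labels[0, 0, 0] > 0 and labels[1:].sum() == 0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DiscretizationSpec(1)
        with pytest.raises(ValueError):
            DiscretizationSpec(32, lo=10.0, hi=10.0)


class TestResample:
    def test_isotropic_input_is_identity(self):
        data = np.random.default_rng(0).normal(size=(5, 6, 7))
        m = np.ones((5, 6, 7), bool)
        out, om = resample_isotropic(vol(data), m, 1.0)
        assert np.array_equal(out.data, data)
        assert out.spacing == (1.0, 1.0, 1.0)
        assert np.array_equal(om, m)

    def test_constant_volume_stays_constant(self):
        out, om = resample_isotropic(
            vol(np.full((4, 4, 4), 37.0), (2, 2, 2)), np.ones((4, 4, 4), bool)
        )
        assert np.allclose(out.data, 37.0)
        assert om.all() and om.shape == (8, 8, 8)

    def test_anisotropic_sphere_volume_preserved(self):
        # r=10 mm sphere sampled at (1,1,5) mm; after resampling to 1 mm the
        # mask volume should approximate (4/3) pi r^3, and the physical mask
        # volume must be carried through the resampling step
        v, m = generate_lesion_phantom(
            (25, 25, 8), (1.0, 1.0, 5.0), {"kind": "constant", "value": 0.0},
            mask_radius=10.0,
        )
        _, om = resample_isotropic(v, m, 1.0)
        analytic = 4.0 / 3.0 * np.pi * 10.0**3
        assert abs(om.sum() - analytic) / analytic < 0.05
        source_mm3 = m.sum() * 5.0
        assert abs(om.sum() - source_mm3) / source_mm3 < 0.05

    def test_bad_spacing_rejected(self):
        with pytest.raises(ValueError):
            resample_isotropic(vol(np.zeros((3, 3, 3)), (0.0, 1, 1)),
                               np.ones((3, 3, 3), bool))


class TestHistogramShape:
    def test_constant_region_degenerate_stats(self):
        v, m = generate_lesion_phantom(
            (16, 16, 16), (1, 1, 1), {"kind": "constant", "value": 50.0},
            mask_radius=7.0,
        )
        f = histogram_shape_features(v, m)
        assert f["StdDev"] == 0.0
        assert f["Entropy_h"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Mean"] == 50.0

    def test_two_level_histogram(self):
        data = np.zeros((2, 2, 2))
        data[0] = -100.0
        data[1] = 100.0
        f = histogram_shape_features(vol(data), np.ones((2, 2, 2), bool))
        assert f["Uniformity"] == pytest.approx(0.5)
        assert f["Entropy_h"] == pytest.approx(np.log(2))

    def test_volume_in_ml_at_threshold(self):
        # 1000 voxels at 1 mm isotropic = exactly 1 mL, the inclusion limit
        data = np.zeros((10, 10, 10))
        f = histogram_shape_features(vol(data), np.ones((10, 10, 10), bool))
        assert f["Volume"] == pytest.approx(1.0)

    def test_sphere_more_spherical_than_slab(self):
        _, sphere = generate_lesion_phantom(
            (20, 20, 20), (1, 1, 1), {"kind": "constant", "value": 0}, 8.0
        )
        v = vol(np.zeros((20, 20, 20)))
        slab = np.zeros((20, 20, 20), bool)
        slab[:, :, 9:11] = True
        fs = histogram_shape_features(v, sphere)
        fl = histogram_shape_features(v, slab)
        assert fs["Sphericity"] > fl["Sphericity"]

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            histogram_shape_features(vol(np.zeros((3, 3, 3))),
                                     np.zeros((3, 3, 3), bool))


class TestGLCM:
    def test_constant_region(self):
        labels = np.ones((4, 4, 2), dtype=int)
        f = glcm_features(labels)
        assert f["Contrast"] == 0.0
        assert f["Homogeneity"] == pytest.approx(1.0)
        assert f["Energy"] == pytest.approx(1.0)
        assert np.isnan(f["Correlation"])

    def test_stripe_pattern_single_direction(self):
        # 1,2,1,2,... along one axis: only (1,2) pairs -> Contrast 1, Corr -1
        labels = np.tile(np.array([1, 2, 1, 2, 1, 2]), (1, 1, 1)).reshape(1, 1, 6)
        f = glcm_features(labels, directions=[(0, 0, 1)])
        assert f["Contrast"] == pytest.approx(1.0)
        assert f["Correlation"] == pytest.approx(-1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(8):
            labels, mask = random_labeled_volume(rng, (4, 4, 2), 4, mask_p=0.85)
            mine = glcm_features(labels, mask)
            ref = oracle_glcm(labels, mask)
            for k, v in ref.items():
                if np.isnan(v):
                    assert np.isnan(mine[k])
                else:
                    assert mine[k] == pytest.approx(v, abs=1e-10), k


class TestGLRLM:
    def test_single_run_closed_form(self):
        L = 6
        labels = np.ones((1, 1, L), dtype=int)
        f = glrlm_features(labels, directions=[(0, 0, 1)])
        assert f["SRE"] == pytest.approx(1.0 / L**2)
        assert f["LRE"] == pytest.approx(float(L**2))
        assert f["RP"] == pytest.approx(1.0 / L)

    def test_alternating_labels_all_unit_runs(self):
        labels = np.array([1, 2, 1, 2, 1]).reshape(1, 1, 5)
        f = glrlm_features(labels, directions=[(0, 0, 1)])
        assert f["SRE"] == pytest.approx(1.0)
        assert f["RP"] == pytest.approx(1.0)

    def test_matches_run_walk_oracle(self, rng):
        for _ in range(6):
            labels, mask = random_labeled_volume(rng, (4, 4, 2), 3, mask_p=0.9)
            mine = glrlm_features(labels, mask)
            ref = oracle_glrlm(labels, mask)
            cons = ref.pop("_voxel_conservation")
            assert cons["total_run_voxels"] == cons["expected"]
            for k, v in ref.items():
                assert mine[k] == pytest.approx(v, abs=1e-10), k


class TestGLZLM:
    def test_single_zone_closed_form(self):
        labels = np.ones((3, 3, 3), dtype=int)
        f = glzlm_features(labels)
        assert f["ZP"] == pytest.approx(1.0 / 27)
        assert f["GLNUz"] == pytest.approx(1.0)

    def test_isolated_voxel_zones(self):
        # single-voxel zones of one level, separated by another level
        labels = np.ones((1, 1, 5), dtype=int)
        labels[0, 0, ::2] = 2  # 3 isolated voxels of level 2? no: check spacing
        # voxels of level 2 at z=0,2,4 are 26-disconnected from each other
        f = glzlm_features(labels)
        # zones: three 1-voxel zones (level 2) + two 1-voxel zones (level 1)
        assert f["ZP"] == pytest.approx(1.0)
        assert f["GLNUz"] == pytest.approx((3**2 + 2**2) / 5)

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(6):
            labels, mask = random_labeled_volume(rng, (4, 4, 2), 3, mask_p=0.9)
            mine = glzlm_features(labels, mask)
            ref = oracle_glzlm(labels, mask)
            cons = ref.pop("_voxel_conservation")
            assert cons["total_zone_voxels"] == cons["expected"]
            for k, v in ref.items():
                assert mine[k] == pytest.approx(v, abs=1e-10), k


class TestNGLDM:
    def test_constant_region_hits_coarseness_cap(self):
        labels = np.ones((3, 3, 3), dtype=int)
        f = ngldm_features(labels)
        assert f["Coarseness"] == COARSENESS_CAP

    def test_checkerboard_matches_hand_enumeration(self):
        labels = np.indices((3, 3, 1)).sum(axis=0) % 2 + 1
        mine = ngldm_features(labels)
        ref = oracle_ngldm(labels, np.ones((3, 3, 1), bool))
        for k, v in ref.items():
            assert mine[k] == pytest.approx(v, abs=1e-10), k

    def test_matches_neighbourhood_oracle(self, rng):
        for _ in range(6):
            labels, mask = random_labeled_volume(rng, (4, 4, 2), 4, mask_p=0.85)
            mine = ngldm_features(labels, mask)
            ref = oracle_ngldm(labels, mask)
            for k, v in ref.items():
                if np.isnan(v):
                    assert np.isnan(mine[k])
                else:
                    assert mine[k] == pytest.approx(v, abs=1e-10), k


class TestInvariances:
    def test_axis_permutation_invariance(self, rng):
        v, m = generate_lesion_phantom(
            (14, 14, 14), (1, 1, 1),
            {"kind": "noise", "sd": 100, "mean": 0, "corr_len": 1.0},
            mask_radius=6.0, seed=5,
        )
        cfg = ExtractionConfig(resample_mm=None, allow_small=True)
        base = extract_all(v, m, cfg).to_series()
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            pv = VoxelVolume(np.transpose(v.data, perm), (1, 1, 1))
            pm = np.transpose(m, perm)
            perm_feats = extract_all(pv, pm, cfg).to_series()
            pd.testing.assert_series_equal(base, perm_feats, rtol=1e-10)

    def test_out_of_mask_voxels_do_not_matter(self, rng):
        v, m = generate_lesion_phantom(
            (12, 12, 12), (1, 1, 1),
            {"kind": "noise", "sd": 80, "mean": 30, "corr_len": 0.0},
            mask_radius=5.0, seed=9,
        )
        cfg = ExtractionConfig(resample_mm=None, allow_small=True)
        base = extract_all(v, m, cfg).to_series()
        scrambled = v.data.copy()
        scrambled[~m] = rng.normal(0, 500, size=(~m).sum()).clip(-1000, 1000)
        redo = extract_all(VoxelVolume(scrambled, v.spacing), m, cfg).to_series()
        pd.testing.assert_series_equal(base, redo, rtol=1e-12)


class TestExtractAll:
    def test_full_panel_and_determinism(self):
        v, m = generate_lesion_phantom(
            (16, 16, 16), (1, 1, 1),
            {"kind": "noise", "sd": 60, "mean": 20, "corr_len": 1.2},
            mask_radius=7.0, seed=3,
        )
        a = extract_all(v, m).to_series()
        b = extract_all(v, m).to_series()
        assert len(a) == 39
        assert a.notna().all()
        pd.testing.assert_series_equal(a, b)

    def test_constant_phantom_degenerate_triple(self):
        v, m = generate_lesion_phantom(
            (16, 16, 16), (1, 1, 1), {"kind": "constant", "value": 50.0},
            mask_radius=7.0,
        )
        f = extract_all(v, m)
        assert f["StdDev"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["Uniformity"] == 1.0

    def test_small_lesion_rejected_without_override(self):
        v, m = generate_lesion_phantom(
            (10, 10, 10), (1, 1, 1), {"kind": "constant", "value": 0}, 4.0
        )
        with pytest.raises(ValueError, match="cm\\^3"):
            extract_all(v, m)
        cfg = ExtractionConfig(allow_small=True)
        assert extract_all(v, m, cfg)["Volume"] < 1.0


class TestFeatureMap:
    def test_constant_volume_zero_stddev_map(self):
        v, m = generate_lesion_phantom(
            (8, 8, 8), (1, 1, 1), {"kind": "constant", "value": 10.0}, 3.0
        )
        fm = feature_map(v, m, "StdDev")
        assert np.all(fm[m] == 0.0)
        assert np.all(np.isnan(fm[~m]))

    def test_window_value_equals_cropped_extraction(self, rng):
        v, m = generate_lesion_phantom(
            (7, 7, 7), (1, 1, 1),
            {"kind": "noise", "sd": 90, "mean": 0, "corr_len": 0.0},
            mask_radius=3.0, seed=11,
        )
        fm = feature_map(v, m, "Mean")
        idx = tuple(np.argwhere(m)[4])
        sl = tuple(slice(max(c - 1, 0), c + 2) for c in idx)
        expected = v.data[sl][m[sl]].mean()
        assert fm[idx] == pytest.approx(expected)

    def test_shape_features_not_mappable(self):
        v, m = generate_lesion_phantom(
            (6, 6, 6), (1, 1, 1), {"kind": "constant", "value": 0}, 2.5
        )
        with pytest.raises(ValueError, match="not mappable"):
            feature_map(v, m, "Sphericity")


class TestLargestLesion:
    def test_global_max_wins(self):
        df = pd.DataFrame(
            {"lesion": ["A", "A", "B", "B"], "visit": [1, 2, 1, 2],
             "volume": [45.0, 30.0, 20.0, 19.0]}
        )
        assert select_largest_lesion(df) == "A"

    def test_tie_broken_by_earlier_attainment(self):
        df = pd.DataFrame(
            {"lesion": ["A", "B"], "visit": [2, 1], "volume": [10.0, 10.0]}
        )
        assert select_largest_lesion(df) == "B"

    def test_tie_same_visit_broken_by_id(self):
        df = pd.DataFrame(
            {"lesion": ["B", "A"], "visit": [1, 1], "volume": [5.0, 5.0]}
        )
        assert select_largest_lesion(df) == "A"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            select_largest_lesion(pd.DataFrame(columns=["lesion", "visit", "volume"]))
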