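import numpy as np
import pytest

from hipporad.catalog import ANGLES, OFFSETS, default_catalog
from hipporad.features import (QuantizedROI, aggregate_directions, extract_all,
                               glcm, glcm_features, haralick_block,
                               histogram_features, quantize, rlm,
                               rlm_features, shape_features)
from tests.conftest import make_mask, make_volume, random_level_grid
from tests.oracles import (brute_glcm, brute_glcm_features, brute_haralick,
                           brute_rlm, brute_rlm_features, brute_uniformity)


def qroi(levels, G):
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedROI(levels=levels, gray_levels=G,
                        n_voxels=int((levels > 0).sum()))


class TestQuantize:
    def test_constant_roi_maps_to_level_one(self):
        vol = make_volume(np.full((4, 4, 4), 7.0))
        q = quantize(vol, make_mask(np.ones((4, 4, 4))), 64)
        assert set(np.unique(q.levels)) == {1}

    def test_64_distinct_values_one_level_each(self):
        vol = make_volume(np.arange(64, dtype=float).reshape(4, 4, 4))
        q = quantize(vol, make_mask(np.ones((4, 4, 4))), 64)
        assert sorted(np.unique(q.levels)) == list(range(1, 65))

    def test_extremes_land_in_first_and_last_level(self, rng):
        vol = make_volume(rng.normal(size=(5, 5, 5)))
        q = quantize(vol, make_mask(np.ones((5, 5, 5))), 16)
        flat = vol.data.ravel()
        lv = q.levels.ravel()
        assert lv[np.argmin(flat)] == 1
        assert lv[np.argmax(flat)] == 16

    def test_levels_bounded_and_sentinel_outside(self, rng):
        m = np.zeros((5, 5, 5))
        m[1:4, 1:4, 1:4] = 1
        vol = make_volume(rng.normal(size=(5, 5, 5)))
        q = quantize(vol, make_mask(m), 8)
        inside = q.levels[q.levels > 0]
        assert inside.min() >= 1 and inside.max() <= 8
        assert q.n_voxels == 27

    def test_G_below_two_rejected(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            quantize(vol, make_mask(np.ones((3, 3, 3))), 1)


class TestHistogram:
    def test_constant_roi_limits(self):
        f = histogram_features(np.full(100, 5.0))
        assert f["Uniformity"] == 1.0
        assert f["Entropy"] == 0.0
        assert f["Std Deviation"] == 0.0
        assert f["Skewness"] == 0.0

    def test_two_equal_mass_bins(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        f = histogram_features(x, gray_levels=2)
        assert f["Uniformity"] == pytest.approx(0.5)

    def test_uniformity_matches_brute_force(self, rng):
        x = rng.normal(100, 20, size=500)
        f = histogram_features(x, gray_levels=64)
        assert f["Uniformity"] == pytest.approx(
            brute_uniformity(x, 64), abs=1e-12)

    def test_count_is_42(self):
        f = histogram_features(np.arange(10.0))
        assert len(f) == 42


class TestShape:
    def test_single_voxel(self):
        m = np.zeros((3, 3, 3))
        m[1, 1, 1] = 1
        f = shape_features(make_mask(m))
        assert f["Maximum 3D Diameter"] == 0.0
        assert f["Surface Area"] == pytest.approx(6.0)
        assert f["Volume"] == pytest.approx(1.0)
        assert f["Surface Volume Ratio"] == pytest.approx(6.0)
        assert f["Sphericity"] == pytest.approx(
            np.pi ** (1 / 3) * 6 ** (2 / 3) / 6)

    def test_three_voxel_bar(self):
        m = np.zeros((5, 3, 3))
        m[1:4, 1, 1] = 1
        f = shape_features(make_mask(m))
        assert f["Maximum 3D Diameter"] == pytest.approx(2.0)
        assert f["Surface Area"] == pytest.approx(14.0)
        assert f["Surface Volume Ratio"] == pytest.approx(14.0 / 3.0)

    def test_spacing_covariance(self, rng):
        m = (rng.random((6, 6, 6)) > 0.5).astype(float)
        m[3, 3, 3] = 1
        f1 = shape_features(make_mask(m, spacing=(1, 1, 1)))
        f2 = shape_features(make_mask(m, spacing=(2, 2, 2)))
        assert f2["Maximum 3D Diameter"] == pytest.approx(
            2 * f1["Maximum 3D Diameter"])
        assert f2["Volume"] == pytest.approx(8 * f1["Volume"])
        assert f2["Surface Area"] == pytest.approx(4 * f1["Surface Area"])
        assert f2["Surface Volume Ratio"] == pytest.approx(
            f1["Surface Volume Ratio"] / 2)
        assert f2["Sphericity"] == pytest.approx(f1["Sphericity"])

    def test_flip_invariance(self, rng):
        m = (rng.random((6, 5, 4)) > 0.6).astype(float)
        m[2, 2, 2] = 1
        f = shape_features(make_mask(m))
        for ax in range(3):
            g = shape_features(make_mask(np.flip(m, axis=ax)))
            for k in f:
                assert g[k] == pytest.approx(f[k], rel=1e-12), (ax, k)


class TestGLCM:
    def test_constant_column_single_cell(self):
        levels = np.ones((1, 5, 1), dtype=np.int32)
        P = glcm(qroi(levels, 4), offset=1, angle=0)
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_checkerboard_two_by_two(self):
        levels = np.array([[1, 2], [2, 1]], dtype=np.int32)[:, :, None]
        P = glcm(qroi(levels, 2), offset=1, angle=0)
        # horizontal pairs (1,2) and (2,1): all mass off-diagonal
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    def test_no_pairs_returns_none(self):
        levels = np.ones((1, 2, 1), dtype=np.int32)
        assert glcm(qroi(levels, 2), offset=7, angle=0) is None

    @pytest.mark.parametrize("angle", ANGLES)
    @pytest.mark.parametrize("offset", OFFSETS)
    def test_matches_brute_force(self, rng, offset, angle):
        for _ in range(10):
            levels = random_level_grid(rng)
            P = glcm(qroi(levels, 8), offset=offset, angle=angle)
            B = brute_glcm(levels, 8, offset, angle)
            if P is None or B is None:
                assert P is None and B is None
            else:
                np.testing.assert_allclose(P, B, atol=1e-15)
                assert P.sum() == pytest.approx(1.0, abs=1e-12)
                np.testing.assert_allclose(P, P.T, atol=0)


class TestGLCMFeatures:
    def test_degenerate_single_cell(self):
        P = np.zeros((4, 4))
        P[0, 0] = 1.0
        f = glcm_features(P)
        assert f["GLCMEnergy"] == 1.0
        assert f["GLCMEntropy"] == 0.0
        assert f["Inverse Difference Moment"] == 1.0
        assert f["Inertia"] == 0.0
        assert f["Correlation"] == 0.0  # zero variance convention

    def test_two_cell_hand_example(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        f = glcm_features(P)
        assert f["Inverse Difference Moment"] == pytest.approx(0.5)
        assert f["Inertia"] == pytest.approx(1.0)

    def test_matches_literal_formulas(self, rng):
        for _ in range(30):
            G = int(rng.integers(2, 9))
            M = rng.random((G, G))
            M = M + M.T
            P = M / M.sum()
            f = glcm_features(P)
            b = brute_glcm_features(P)
            for k in b:
                assert f[k] == pytest.approx(b[k], rel=1e-12, abs=1e-12), k


class TestHaralick:
    def test_constant_image_sum_average_two(self):
        levels = np.ones((3, 3, 1), dtype=np.int32)
        f = haralick_block(qroi(levels, 4))
        assert f["Haralick Sum Average"] == pytest.approx(2.0)
        assert f["Haralick Sum Entropy"] == pytest.approx(0.0)

    def test_alternating_pair_hand_example(self):
        from hipporad.features import _haralick_from_glcm
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        f = _haralick_from_glcm(P)
        assert f["Haralick Sum Average"] == pytest.approx(3.0)
        assert f["Haralick Sum Entropy"] == pytest.approx(0.0)

    def test_matches_brute_force_via_four_glcms(self, rng):
        for _ in range(10):
            levels = random_level_grid(rng, max_shape=(6, 6, 3), G=6)
            q = qroi(levels, 6)
            f = haralick_block(q)
            per_dir = []
            for angle in ANGLES:
                B = brute_glcm(levels, 6, 1, angle)
                if B is not None:
                    per_dir.append(brute_haralick(B))
            if not per_dir:
                assert all(np.isnan(v) for v in f.values())
                continue
            for k in per_dir[0]:
                expect = np.mean([d[k] for d in per_dir])
                assert f[k] == pytest.approx(expect, rel=1e-12, abs=1e-12), k


class TestRLM:
    def test_row_hand_enumeration(self):
        levels = np.array([[1, 1, 1, 2, 2]], dtype=np.int32)[:, :, None]
        counts, n_runs = rlm(qroi(levels, 2), offset=1, angle=0)
        assert n_runs == 2
        assert counts[0, 2] == 1  # level 1, length 3
        assert counts[1, 1] == 1  # level 2, length 2
        f = rlm_features(counts, n_runs)
        assert f["Long Run Emphasis"] == pytest.approx((9 + 4) / 2)

    def test_constant_column_closed_form(self):
        N = 7
        levels = np.ones((1, N, 1), dtype=np.int32)
        counts, n_runs = rlm(qroi(levels, 4), offset=1, angle=0)
        assert n_runs == 1
        f = rlm_features(counts, n_runs)
        assert f["Long Run Emphasis"] == pytest.approx(N**2)
        assert f["Low Gray Level Run Emphasis"] == pytest.approx(1.0)

    def test_stride_skips_voxels(self):
        # at stride 2 the row [1,2,1,2,1] reads as two all-1 lines and
        # one all-2 line
        levels = np.array([[1, 2, 1, 2, 1]], dtype=np.int32)[:, :, None]
        counts, n_runs = rlm(qroi(levels, 2), offset=2, angle=0)
        assert n_runs == 2
        assert counts[0, 2] == 1   # run of three 1s
        assert counts[1, 1] == 1   # run of two 2s

    @pytest.mark.parametrize("angle", ANGLES)
    @pytest.mark.parametrize("offset", OFFSETS)
    def test_matches_brute_force(self, rng, offset, angle):
        for _ in range(10):
            levels = random_level_grid(rng)
            counts, n_runs = rlm(qroi(levels, 8), offset=offset, angle=angle)
            bc, bn = brute_rlm(levels, 8, offset, angle)
            if counts is None or bc is None:
                assert counts is None and bc is None
                continue
            assert n_runs == bn
            np.testing.assert_allclose(counts, bc, atol=0)
            f = rlm_features(counts, n_runs)
            b = brute_rlm_features(bc, bn)
            for k in b:
                assert f[k] == pytest.approx(b[k], rel=1e-12), k


class TestAggregateDirections:
    def test_equal_values(self):
        assert aggregate_directions([2, 2, 2, 2]) == (2.0, 0.0)

    def test_population_sd(self):
        m, s = aggregate_directions([1, 2, 3, 4])
        assert m == pytest.approx(2.5)
        assert s == pytest.approx(np.sqrt(1.25))

    def test_single_direction(self):
        m, s = aggregate_directions([np.nan, 3.0, None, np.nan])
        assert (m, s) == (3.0, 0.0)

    def test_all_missing(self):
        m, s = aggregate_directions([np.nan] * 4)
        assert np.isnan(m) and np.isnan(s)


class TestExtractAll:
    def test_catalog_length_and_determinism(self, rng):
        vol = make_volume(rng.normal(100, 20, size=(10, 10, 6)))
        m = np.zeros((10, 10, 6))
        m[2:8, 2:8, 1:5] = 1
        v1 = extract_all(vol, make_mask(m))
        v2 = extract_all(vol, make_mask(m))
        assert len(v1) == 385
        assert (v1.index == default_catalog().names).all()
        assert v1.equals(v2)

    def test_constant_roi_limit_values(self):
        # ROI wide enough that offset-7 pairs exist in every direction
        vol = make_volume(np.full((16, 16, 8), 42.0))
        m = np.zeros((16, 16, 8))
        m[2:14, 2:14, 1:7] = 1
        v = extract_all(vol, make_mask(m))
        assert v["Uniformity"] == 1.0
        assert v["Entropy"] == 0.0
        for off in OFFSETS:
            assert v[f"GLCMEnergy_All Direction_offset{off}"] == 1.0
            assert v[f"GLCMEntropy_All Direction_offset{off}"] == 0.0
            assert v[f"Inverse Difference Moment_All Direction_offset{off}"] == 1.0
            assert v[f"Inertia_All Direction_offset{off}"] == 0.0
            assert v[f"Low Gray Level Run Emphasis_All Direction_offset{off}"] == 1.0
        assert not v.isna().any()

    def test_thin_roi_emits_missing_not_crash(self, rng):
        vol = make_volume(rng.normal(size=(3, 3, 3)))
        m = np.zeros((3, 3, 3))
        m[1, 1, :] = 1  # single in-plane voxel per slice: no offset-4 pairs
        v = extract_all(vol, make_mask(m))
        assert len(v) == 385
        # no co-occurring pair exists at offset 4, so every GLCM value
        # is missing; RLM still sees (length-1) runs and stays defined
        glcm4 = [c for c in v.index
                 if "offset4" in c and any(c.startswith(b) for b in (
                     "GLCMEnergy", "GLCMEntropy", "Inertia", "Correlation",
                     "Inverse Difference", "Cluster", "Haralick Correlation"))]
        assert v[glcm4].isna().all()
        assert not v.filter(like="Run Emphasis").isna().any()

    def test_monotone_idm_in_texture_smoothness(self):
        from hipporad.synthetic import generate_textured_volume
        idms = []
        for sigma in [0, 1, 2, 3]:
            vol = generate_textured_volume((20, 20, 10), (1, 1, 1),
                                           100, 20, sigma, 0, seed=11)
            m = np.ones((20, 20, 10))
            v = extract_all(vol, make_mask(m))
            idms.append(v["Inverse Difference Moment_All Direction_offset1"])
        assert all(b > a for a, b in zip(idms, idms[1:]))

    def test_glcm_invariant_to_inplane_180_flip(self, rng):
        # reversing both in-plane axes reverses every direction, which
        # the symmetrized GLCM cannot see
        vol_data = rng.normal(size=(8, 8, 4))
        m = (rng.random((8, 8, 4)) > 0.3).astype(float)
        m[4, 4, 2] = 1
        v1 = extract_all(make_volume(vol_data), make_mask(m))
        v2 = extract_all(make_volume(vol_data[::-1, ::-1].copy()),
                         make_mask(m[::-1, ::-1].copy()))
        glcm_cols = [c for c in v1.index if "offset" in c]
        np.testing.assert_allclose(v1[glcm_cols].to_numpy(),
                                   v2[glcm_cols].to_numpy(),
                                   rtol=1e-10, equal_nan=True)
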