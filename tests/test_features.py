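"""Feature-bank contracts: shape, symmetry distance, color, GLCM, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microderm.features import (
    FEATURE_NAMES,
    FeatureTable,
    apply_scaling,
    color_variegation,
    compute_features,
    compute_glcm,
    ellipse_variance,
    fit_scaling,
    haralick_features,
    intensity_channel,
    quantize,
    resample_contour,
    shape_features,
    symmetry_distance,
    texture_summary,
)
from microderm.segment import extract_contour
from tests.conftest import disc_mask


class TestShapeFeatures:
    def test_disc_limits(self):
        d = disc_mask((101, 101), (50, 50), 35)
        f = shape_features(d, extract_contour(d))
        assert f["eccentricity"] == pytest.approx(1.0, rel=0.02)
        assert f["compactness"] >= 0.95
        assert f["solidity"] >= 0.97
        assert f["convexity"] >= 0.90
        assert ellipse_variance(d, extract_contour(d)) <= 0.01

    def test_rectangle_moments(self):
        r = np.zeros((60, 60), bool)
        r[10:50, 25:35] = True  # 40 x 10
        f = shape_features(r, extract_contour(r))
        assert f["rectangularity"] == pytest.approx(1.0, abs=0.05)
        assert f["eccentricity"] == pytest.approx(4.0, rel=0.05)
        assert f["elongation"] == pytest.approx(0.75, abs=0.05)

    def test_rotation_invariance_90deg(self):
        from microderm.synthetic import SyntheticSpec, generate_lesion_shape

        mask = generate_lesion_shape(SyntheticSpec(asymmetry_amp=0.5, rng_seed=3))
        rot = np.rot90(mask)
        a = shape_features(mask, extract_contour(mask))
        b = shape_features(rot, extract_contour(rot))
        for name in a:
            assert a[name] == pytest.approx(b[name], rel=0.01), name

    def test_scale_invariance_2x(self):
        # same seeded boundary harmonics rasterized at 1x and 2x radius
        from microderm.synthetic import SyntheticSpec, generate_lesion_shape

        mask = generate_lesion_shape(SyntheticSpec(asymmetry_amp=0.4, rng_seed=5))
        big = generate_lesion_shape(
            SyntheticSpec(image_height=384, image_width=384, lesion_radius=80,
                          asymmetry_amp=0.4, rng_seed=5)
        )
        a = shape_features(mask, extract_contour(mask))
        b = shape_features(big, extract_contour(big))
        for name in ("eccentricity", "compactness", "rectangularity",
                     "convexity", "solidity"):
            assert a[name] == pytest.approx(b[name], rel=0.015), name
        # the minimum-area box is the most digitization-sensitive quantity
        assert a["elongation"] == pytest.approx(b["elongation"], rel=0.05)
        assert b["major_axis_length"] == pytest.approx(2 * a["major_axis_length"], rel=0.01)
        sd_a = symmetry_distance(extract_contour(mask).astype(float))
        sd_b = symmetry_distance(extract_contour(big).astype(float))
        assert sd_b == pytest.approx(sd_a, abs=0.01)

    def test_tiny_mask_rejected(self):
        m = np.zeros((10, 10), bool)
        m[4:6, 4:6] = True
        with pytest.raises(ValueError, match="degenerate"):
            shape_features(m, np.array([[4, 4], [4, 5], [5, 5], [5, 4]]))


def brute_force_sd(contour, n=64, n_angles=3600):
    """Dense-grid mirror-symmetry oracle: plain loops, no refinement."""
    P = resample_contour(contour, n)
    P = P - P.mean(axis=0)
    P = P / np.linalg.norm(P, axis=1).mean()
    Q = P[::-1]
    best = np.inf
    for a in range(n_angles):
        theta = a * np.pi / n_angles
        c, s = np.cos(2 * theta), np.sin(2 * theta)
        R = np.array([[c, s], [s, -c]])
        Qr = Q @ R.T
        for shift in range(n):
            rolled = np.roll(Qr, -shift, axis=0)
            cost = np.mean(np.linalg.norm(P - rolled, axis=1)) / 2.0
            if cost < best:
                best = cost
    return best


class TestSymmetryDistance:
    def test_square_is_symmetric(self):
        sq = np.array([(0, 0), (0, 10), (10, 10), (10, 0)], float)
        assert symmetry_distance(sq, n=32) <= 1e-6

    def test_similarity_invariance(self):
        poly = np.array([(1, 0), (0, 1), (-1, 0), (0, -0.5)], float)
        sd0 = symmetry_distance(poly, n=64)
        th = 1.234
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = poly @ R.T * 7.7 + np.array([13.0, -4.0])
        assert abs(symmetry_distance(moved, n=64) - sd0) <= 1e-6

    def test_matches_dense_grid_oracle(self):
        poly = np.array([(1, 0), (0, 1), (-1, 0), (0, -0.5)], float)
        assert symmetry_distance(poly, n=64) == pytest.approx(
            brute_force_sd(poly, n=64), abs=1e-3
        )

    def test_random_polygons_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(3):
            k = 10
            ang = np.sort(rng.uniform(0, 2 * np.pi, k))
            rad = rng.uniform(0.5, 1.5, k)
            poly = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
            assert symmetry_distance(poly, n=64) == pytest.approx(
                brute_force_sd(poly, n=64), abs=1e-3
            )

    def test_input_validation(self):
        sq = np.array([(0, 0), (0, 1), (1, 1), (1, 0)], float)
        with pytest.raises(ValueError):
            symmetry_distance(sq, n=7)  # odd
        with pytest.raises(ValueError):
            symmetry_distance(sq, n=4)  # too small
        bowtie = np.array([(0, 0), (1, 1), (1, 0), (0, 1)], float)
        with pytest.raises(ValueError, match="self-intersecting"):
            symmetry_distance(bowtie, n=32)


class TestColor:
    def test_intensity_channel(self):
        img = np.zeros((1, 3, 3), np.uint8)
        img[0, 0] = (3, 4, 0)
        img[0, 2] = (255, 255, 255)
        out = intensity_channel(img)
        assert out[0, 0] == 5.0
        assert out[0, 1] == 0.0
        assert out[0, 2] == pytest.approx(255 * np.sqrt(3))

    def test_two_value_channel(self):
        img = np.zeros((1, 4, 3), np.uint8)
        img[0, :2] = (1, 1, 1)
        img[0, 2:] = (3, 3, 3)
        cv = color_variegation(img, np.ones((1, 4), bool))
        # mu=2, population sigma=1 -> ln(1/2)
        assert cv["cv_red"] == pytest.approx(np.log(0.5))

    def test_sigma_equals_mu_gives_zero(self):
        img = np.zeros((1, 2, 3), np.uint8)
        img[0, 1] = (2, 2, 2)  # values {0,2}: mu=1, sigma=1
        cv = color_variegation(img, np.ones((1, 2), bool))
        assert cv["cv_red"] == pytest.approx(0.0)

    def test_constant_channel_floored(self):
        img = np.full((3, 3, 3), 100, np.uint8)
        cv = color_variegation(img, np.ones((3, 3), bool))
        assert all(v == -10.0 for v in cv.values())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            color_variegation(np.zeros((2, 2, 3), np.uint8), np.zeros((2, 2), bool))


def brute_force_glcm_haralick(gray, mask, offset, levels):
    """Independent pair-enumeration oracle with plain Python loops."""
    q = quantize(gray, levels)
    h, w = q.shape
    dx, dy = offset
    counts = np.zeros((levels, levels), float)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1
    cm = counts / counts.sum()
    n = levels
    feats = dict.fromkeys(
        ["max_probability", "energy", "entropy", "dissimilarity", "contrast",
         "inverse_difference", "inverse_difference_moment"], 0.0)
    feats["max_probability"] = cm.max()
    mu_x = sum(i * cm[i, j] for i in range(n) for j in range(n))
    mu_y = sum(j * cm[i, j] for i in range(n) for j in range(n))
    var_x = sum((i - mu_x) ** 2 * cm[i, j] for i in range(n) for j in range(n))
    var_y = sum((j - mu_y) ** 2 * cm[i, j] for i in range(n) for j in range(n))
    ent = en = dis = con = invd = invdm = corr = 0.0
    for i in range(n):
        for j in range(n):
            p = cm[i, j]
            en += p * p
            if p > 0:
                ent -= p * np.log2(p)
            dis += abs(i - j) * p
            con += (i - j) ** 2 * p
            invd += p / (1 + abs(i - j))
            invdm += p / (1 + (i - j) ** 2)
            corr += i * j * p
    feats["energy"] = en
    feats["entropy"] = ent
    feats["dissimilarity"] = dis
    feats["contrast"] = con
    feats["inverse_difference"] = invd
    feats["inverse_difference_moment"] = invdm
    sd = np.sqrt(var_x * var_y)
    feats["correlation"] = (corr - mu_x * mu_y) / sd if sd > 0 else 0.0
    return feats


class TestGlcm:
    def test_hand_enumerated_2x2(self):
        gray = np.array([[0.0, 0.0], [255.0, 255.0]])
        g = compute_glcm(gray, np.ones((2, 2), bool), (1, 0), levels=64)
        # two horizontal pairs (0,0) and (63,63); symmetrization doubles them
        assert g.counts[0, 0] == 2 and g.counts[63, 63] == 2
        assert g.counts.sum() == 4

    def test_symmetric_and_normalized(self):
        rng = np.random.default_rng(0)
        gray = rng.uniform(0, 255, (12, 12))
        g = compute_glcm(gray, np.ones((12, 12), bool), (1, -1))
        assert np.array_equal(g.counts, g.counts.T)
        assert g.normalized().sum() == pytest.approx(1.0)

    def test_constant_region_single_diagonal_entry(self):
        g = compute_glcm(np.full((5, 5), 128.0), np.ones((5, 5), bool), (0, 1))
        nz = np.nonzero(g.counts)
        assert len(nz[0]) == 1 and nz[0][0] == nz[1][0]
        assert g.normalized().max() == 1.0

    def test_validation(self):
        gray = np.zeros((4, 4))
        with pytest.raises(ValueError):
            compute_glcm(gray, np.ones((4, 4), bool), (0, 0))
        with pytest.raises(ValueError):
            compute_glcm(gray, np.ones((4, 4), bool), (1, 0), levels=32)
        with pytest.raises(ValueError, match="too small"):
            compute_glcm(gray, np.zeros((4, 4), bool), (1, 0))


class TestHaralick:
    def test_two_point_diagonal(self):
        h = haralick_features(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert h["energy"] == 0.5
        assert h["entropy"] == 1.0
        assert h["contrast"] == 0.0
        assert h["dissimilarity"] == 0.0
        assert h["max_probability"] == 0.5
        assert h["inverse_difference"] == 1.0

    def test_uniform_matrix_closed_form(self):
        h = haralick_features(np.full((4, 4), 1 / 16))
        assert h["energy"] == pytest.approx(1 / 16)
        assert h["entropy"] == pytest.approx(4.0)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            gray = rng.choice([0.0, 64.0, 128.0, 192.0], size=(8, 8))
            mask = rng.random((8, 8)) < 0.8
            if mask.sum() < 8:
                continue
            for off in ((1, 0), (0, 1), (1, 1), (1, -1)):
                try:
                    ours = haralick_features(compute_glcm(gray, mask, off))
                except ValueError:
                    continue
                oracle = brute_force_glcm_haralick(gray, mask, off, 64)
                for k in ours:
                    assert ours[k] == pytest.approx(oracle[k], abs=1e-10), k


class TestTextureSummary:
    def test_constant_region_degenerate_values(self):
        t = texture_summary(np.full((20, 20), 99.0), np.ones((20, 20), bool))
        assert t["energy"] == 1.0
        assert t["entropy"] == 0.0
        assert t["contrast"] == 0.0
        assert t["entropy_variance"] == 0.0

    def test_isotropic_noise_has_tiny_entropy_variance(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(20):
            gray = rng.uniform(0, 255, (128, 128))
            vals.append(texture_summary(gray, np.ones((128, 128), bool))["entropy_variance"])
        assert np.mean(vals) < 0.01

    def test_contrast_monotone_in_generator_texture(self, small_spec):
        from dataclasses import replace

        from microderm.synthetic import generate_sample
        from microderm.preprocess import rgb_to_gray

        lo, hi = [], []
        for seed in range(25):
            for tex, acc in ((5.0, lo), (40.0, hi)):
                spec = replace(small_spec, texture_contrast=tex, n_colors=1,
                               rng_seed=100 + seed)
                s = generate_sample(spec)
                t = texture_summary(rgb_to_gray(s.image), s.lesion_mask_truth)
                acc.append(t["contrast"])
        assert np.mean(hi) > np.mean(lo)


class TestScaling:
    def test_minmax_learned_and_applied(self):
        t = FeatureTable(pd.DataFrame({"a": [0.0, 5.0, 10.0]}), np.array([0, 1, 0]))
        p = fit_scaling(t)
        assert p.minima["a"] == 0.0 and p.maxima["a"] == 10.0
        scaled = apply_scaling(t, p)
        assert list(scaled.data["a"]) == [-1.0, 0.0, 1.0]

    def test_constant_column_maps_to_zero(self):
        t = FeatureTable(pd.DataFrame({"a": [3.0, 3.0]}), np.array([0, 1]))
        p = fit_scaling(t)
        assert p.constant["a"]
        assert (apply_scaling(t, p).data["a"] == 0.0).all()

    def test_row_order_irrelevant(self):
        df = pd.DataFrame({"a": [4.0, -2.0, 9.0], "b": [0.0, 1.0, 2.0]})
        t1 = FeatureTable(df, np.array([0, 1, 0]))
        t2 = FeatureTable(df.iloc[::-1].reset_index(drop=True), np.array([0, 1, 0]))
        p1, p2 = fit_scaling(t1), fit_scaling(t2)
        assert p1.minima.equals(p2.minima) and p1.maxima.equals(p2.maxima)

    def test_test_values_not_clipped(self):
        t = FeatureTable(pd.DataFrame({"a": [0.0, 10.0]}), np.array([0, 1]))
        p = fit_scaling(t)
        out = apply_scaling(pd.DataFrame({"a": [20.0]}), p)
        assert out["a"].iloc[0] == 3.0

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=8))
    def test_training_extremes_map_to_unit_interval_ends(self, vals):
        t = FeatureTable(pd.DataFrame({"a": vals}), np.zeros(len(vals), int))
        p = fit_scaling(t)
        scaled = apply_scaling(t, p).data["a"]
        if p.constant["a"]:
            assert (scaled == 0.0).all()
        else:
            assert scaled.min() == -1.0 and scaled.max() == 1.0


class TestFullVector:
    def test_all_features_finite_on_generator_output(self, malignant_sample, benign_sample):
        from microderm.pipeline import image_features

        for s in (malignant_sample, benign_sample):
            feats = image_features(s.image)
            assert tuple(feats) == FEATURE_NAMES
            assert all(np.isfinite(v) for v in feats.values())
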