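"""Feature families: first-order, GLCM, fractal, morphology, bank assembly."""

import dataclasses

import numpy as np
import pytest

from radiopcr.features import (
    BankConfig,
    FIRST_ORDER_NAMES,
    FRACTAL_NAMES,
    GLCM_NAMES,
    MORPHOLOGY_NAMES,
    FeatureId,
    box_counting_dimension,
    extract_bank,
    first_order_features,
    fractal_features,
    glcm_features,
    glcm_matrix,
    morphology_features,
)
from radiopcr.phantoms import ClassTexture, PhantomSpec, generate_cohort


def brute_force_glcm(img, mask, n_bins, offsets, distance=1):
    """Independent oracle: enumerate every voxel pair explicitly."""
    vals = img[mask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        binned = np.clip(((img - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    else:
        binned = np.zeros(img.shape, int)
    counts = np.zeros((n_bins, n_bins))
    H, W, S = img.shape
    for k in range(S):
        for r in range(H):
            for c in range(W):
                if not mask[r, c, k]:
                    continue
                for dr, dc in offsets:
                    r2, c2 = r + distance * dr, c + distance * dc
                    if 0 <= r2 < H and 0 <= c2 < W and mask[r2, c2, k]:
                        counts[binned[r, c, k], binned[r2, c2, k]] += 1
    counts = counts + counts.T
    return counts / counts.sum() if counts.sum() else None


class TestFirstOrder:
    def test_constant_roi(self):
        f = first_order_features(np.full(50, 3.0))
        assert f["mean"] == 3.0
        assert f["sd"] == 0.0
        assert f["entropy"] == 0.0
        assert f["energy"] == pytest.approx(50 * 9.0)
        assert f["uniformity"] == 1.0

    def test_hand_arithmetic(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert f["mean"] == 2.5
        assert f["variance"] == pytest.approx(1.25)  # population convention
        assert f["median"] == 2.5
        assert f["range"] == 3.0
        assert f["mad"] == 1.0
        assert f["rms"] == pytest.approx(np.sqrt(7.5))

    def test_symmetric_histogram_zero_skew(self):
        x = np.concatenate([np.arange(10), -np.arange(10)])
        assert abs(first_order_features(x)["skewness"]) < 1e-12

    def test_pearson_kurtosis_of_normal_sample_near_three(self):
        x = np.random.default_rng(0).standard_normal(200_00)
        assert first_order_features(x)["kurtosis"] == pytest.approx(3.0, abs=0.1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.random(500)
        a = first_order_features(x)
        b = first_order_features(rng.permutation(x))
        for name in FIRST_ORDER_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-12)


class TestGlcm:
    def test_two_by_two_horizontal_pairs_by_hand(self):
        # [[1,1],[2,2]]: the two horizontal pairs are (1,1) and (2,2)
        img = np.array([[1.0, 1.0], [2.0, 2.0]])[:, :, None]
        mask = np.ones_like(img, bool)
        p = brute_force_glcm(img, mask, n_bins=2, offsets=[(0, 1)])
        np.testing.assert_allclose(p, [[0.5, 0.0], [0.0, 0.5]])
        # with the production 4-direction convention, contrast comes only
        # from the vertical/diagonal (1,2) pairs
        f = glcm_features(img, mask, n_bins=2)
        assert f["contrast"] > 0

    def test_matrix_matches_brute_force_on_random_masked_volumes(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            img = rng.random((7, 6, 2))
            mask = rng.random((7, 6, 2)) > 0.3
            mask[0, 0, 0] = mask[0, 1, 0] = True
            p = glcm_matrix(img, mask, n_bins=4)
            expected = brute_force_glcm(
                img, mask, n_bins=4, offsets=[(0, 1), (1, 0), (1, 1), (1, -1)]
            )
            np.testing.assert_allclose(p, expected, atol=1e-12)

    def test_matrix_is_symmetric_probability(self):
        rng = np.random.default_rng(3)
        img = rng.random((10, 10, 3))
        mask = rng.random((10, 10, 3)) > 0.4
        mask[5, 5, 1] = mask[5, 6, 1] = True
        p = glcm_matrix(img, mask, n_bins=8)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(p, p.T, atol=1e-12)

    def test_constant_region_degenerate(self):
        img = np.full((4, 4, 1), 2.0)
        f = glcm_features(img, np.ones((4, 4, 1), bool), n_bins=4)
        assert f["contrast"] == 0.0
        assert f["cluster_shade"] == 0.0
        assert f["energy"] == 1.0

    def test_cluster_shade_sign_flips_under_intensity_negation(self):
        rng = np.random.default_rng(4)
        n_bins = 8
        for _ in range(5):
            # bin-centre values make the negated image bin exactly in reverse
            img = rng.integers(0, n_bins, size=(9, 9, 2)).astype(float)
            mask = np.ones(img.shape, bool)
            shade = glcm_features(img, mask, n_bins=n_bins)["cluster_shade"]
            neg = glcm_features((n_bins - 1) - img, mask, n_bins=n_bins)["cluster_shade"]
            assert neg == pytest.approx(-shade, abs=1e-9)

    def test_cluster_shade_formula_against_direct_summation(self):
        rng = np.random.default_rng(5)
        img = rng.random((8, 8, 2))
        mask = np.ones(img.shape, bool)
        p = glcm_matrix(img, mask, n_bins=6)
        f = glcm_features(img, mask, n_bins=6)
        n = p.shape[0]
        mu_i = sum(i * p[i, j] for i in range(n) for j in range(n))
        mu_j = sum(j * p[i, j] for i in range(n) for j in range(n))
        shade = sum(
            (i + j - mu_i - mu_j) ** 3 * p[i, j] for i in range(n) for j in range(n)
        )
        prom = sum(
            (i + j - mu_i - mu_j) ** 4 * p[i, j] for i in range(n) for j in range(n)
        )
        assert f["cluster_shade"] == pytest.approx(shade, rel=1e-10)
        assert f["cluster_prominence"] == pytest.approx(prom, rel=1e-10)

    def test_symmetric_intensity_distribution_zero_shade(self):
        # mirror-symmetric image: co-occurrence distribution symmetric about
        # its mean, so the third central cross-moment vanishes
        base = np.arange(8, dtype=float)
        img = np.stack([base] * 8)[:, :, None]
        mask = np.ones(img.shape, bool)
        shade = glcm_features(img, mask, n_bins=8)["cluster_shade"]
        assert shade == pytest.approx(0.0, abs=1e-9)

    def test_too_small_mask_gives_sentinel(self):
        img = np.random.default_rng(6).random((5, 5, 1))
        mask = np.zeros((5, 5, 1), bool)
        mask[2, 2, 0] = True  # a single voxel has no pair
        f = glcm_features(img, mask)
        assert all(np.isnan(f[name]) for name in GLCM_NAMES)


class TestFractal:
    def test_filled_square_dimension_two(self):
        assert box_counting_dimension(np.ones((64, 64), bool)) == pytest.approx(2.0, abs=0.1)

    def test_line_dimension_one(self):
        mask = np.zeros((64, 64), bool)
        mask[32, :] = True
        assert box_counting_dimension(mask) == pytest.approx(1.0, abs=0.1)

    def test_single_pixel_dimension_zero(self):
        mask = np.zeros((16, 16), bool)
        mask[3, 7] = True
        assert box_counting_dimension(mask) == 0.0

    def test_dimension_bounded_for_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            mask = rng.random((40, 40)) > rng.uniform(0.2, 0.9)
            if mask.any():
                d = box_counting_dimension(mask)
                assert -0.05 <= d <= 2.05

    def test_per_slice_aggregation(self):
        mask = np.zeros((64, 64, 3), bool)
        mask[:, :, 0] = True  # filled plane: d ~ 2
        mask[32, :, 1] = True  # line: d ~ 1
        f = fractal_features(mask)
        assert f["fd_max"] == pytest.approx(2.0, abs=0.1)
        assert f["fd_mean"] == pytest.approx(1.5, abs=0.1)
        assert f["fd_sd"] > 0

    def test_empty_mask_sentinel(self):
        f = fractal_features(np.zeros((8, 8, 2), bool))
        assert all(np.isnan(f[name]) for name in FRACTAL_NAMES)


class TestMorphology:
    def test_single_voxel(self):
        mask = np.zeros((5, 5, 3), bool)
        mask[2, 2, 1] = True
        f = morphology_features(mask, (1.0, 1.0, 1.0))
        assert f["volume_mm3"] == 1.0
        assert f["n_components"] == 1.0
        assert f["surface_mm2"] == 6.0
        assert f["max_planar_diameter_mm"] == 0.0

    def test_block_volume_and_planar_diameter(self):
        mask = np.zeros((12, 12, 1), bool)
        mask[1:11, 1:11, 0] = True
        f = morphology_features(mask, (1.0, 1.0, 1.0))
        assert f["volume_mm3"] == pytest.approx(100.0)
        # corner-to-corner between pixel centres of a 10x10 block
        assert f["max_planar_diameter_mm"] == pytest.approx(np.sqrt(162.0))

    def test_two_disjoint_blobs(self):
        mask = np.zeros((20, 20, 1), bool)
        mask[2:5, 2:5, 0] = True
        mask[10:14, 10:14, 0] = True
        f = morphology_features(mask, (1.0, 1.0, 1.0))
        assert f["n_components"] == 2.0

    def test_sphere_is_rounder_than_slab(self):
        shape = (30, 30, 30)
        grid = np.indices(shape) - 14.5
        ball = (grid**2).sum(axis=0) <= 10**2
        slab = np.zeros(shape, bool)
        slab[14:16, :, :] = True
        sph_ball = morphology_features(ball, (1, 1, 1))["sphericity"]
        sph_slab = morphology_features(slab, (1, 1, 1))["sphericity"]
        assert sph_ball > sph_slab

    def test_empty_mask_sentinel(self):
        f = morphology_features(np.zeros((4, 4, 1), bool), (1, 1, 1))
        assert all(np.isnan(f[name]) for name in MORPHOLOGY_NAMES)


class TestFeatureId:
    def test_string_form_roundtrips(self):
        for fid in (
            FeatureId("log", (0.35,), "first_order", "kurtosis"),
            FeatureId("ib", (20, 60), "glcm", "cluster_shade"),
            FeatureId("ib", (0, 100), "morphology", "volume_mm3"),
        ):
            assert FeatureId.from_string(str(fid)) == fid

    def test_family_assignment_enforced(self):
        with pytest.raises(ValueError):
            FeatureId("log", (1.0,), "glcm", "contrast")
        with pytest.raises(ValueError):
            FeatureId("ib", (0, 100), "first_order", "mean")


class TestExtractBank:
    @pytest.fixture()
    def tiny_cohort(self):
        spec = PhantomSpec(
            n_cases=2, prevalence_positive=0.5, grid_shape=(48, 48, 6),
            voxel_spacing_mm=(0.548, 0.548, 3.0), lesion_radius_mm=5.0, seed=11,
        )
        return generate_cohort(spec)

    def test_census_matches_config_arithmetic(self, tiny_cohort):
        cfg = BankConfig()
        bank = extract_bank(tiny_cohort.cases[0], cfg)
        expected = 13 * len(FIRST_ORDER_NAMES) + 55 * (
            len(GLCM_NAMES) + len(FRACTAL_NAMES) + len(MORPHOLOGY_NAMES)
        )
        assert len(bank) == cfg.census == expected

    def test_identical_inputs_identical_vectors(self, tiny_cohort):
        case = tiny_cohort.cases[0]
        a = extract_bank(case)
        b = extract_bank(case.copy())
        assert a.keys() == b.keys()
        for k in a:
            assert a[k] == b[k] or (np.isnan(a[k]) and np.isnan(b[k]))

    def test_texture_contrast_differs_morphology_does_not(self):
        base = dict(
            n_cases=1, prevalence_positive=0.5, grid_shape=(48, 48, 6),
            voxel_spacing_mm=(0.548, 0.548, 3.0), lesion_radius_mm=5.0,
            noise_sd=0.0, seed=21,
        )
        fine = generate_cohort(PhantomSpec(
            texture_negative=ClassTexture(0.8, 0.0),
            texture_positive=ClassTexture(0.8, 0.0), **base))
        coarse = generate_cohort(PhantomSpec(
            texture_negative=ClassTexture(3.0, 0.0),
            texture_positive=ClassTexture(3.0, 0.0), **base))
        a = extract_bank(fine.cases[0])
        b = extract_bank(coarse.cases[0])
        contrast_id = FeatureId("ib", (0, 100), "glcm", "contrast")
        assert abs(a[contrast_id] - b[contrast_id]) > 0.1 * abs(a[contrast_id])
        # the (0,100) subpopulation is the whole ROI: same mask geometry
        for name in MORPHOLOGY_NAMES:
            mid = FeatureId("ib", (0, 100), "morphology", name)
            assert a[mid] == pytest.approx(b[mid], rel=1e-9)
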