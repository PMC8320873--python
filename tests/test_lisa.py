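from fractions import Fraction

import numpy as np
import pytest

from lisaq import (
    LisaConfig,
    classify_pixels,
    full_mask,
    global_moran,
    local_moran_field,
    quadrant_labels,
)
from lisaq.lisa import QUAD_HH, QUAD_HL, QUAD_LH, QUAD_LL, QUAD_NONE


def outlier_image(center: float = 9.0, background: float = 1.0) -> np.ndarray:
    img = np.full((5, 5), background)
    img[2, 2] = center
    return img


class TestLocalMoranField:
    @pytest.mark.parametrize("scope", ["image", "window"])
    def test_uniform_image_all_plus_one(self, uniform64, scope):
        field = local_moran_field(uniform64, config=LisaConfig(stat_scope=scope))
        assert np.all(field.values == 1.0)

    def test_checkerboard_interior_window_scope(self, checkerboard64, window_config):
        # hand-derived: window [1,0,1;0,1,0;1,0,1], X̄=5/9, S²=164/648, I = -4/41
        field = local_moran_field(checkerboard64, config=window_config)
        expected = float(Fraction(-4, 41))
        assert field.values[5, 5] == pytest.approx(expected, abs=1e-12)
        assert np.all(field.values < 0)

    def test_checkerboard_image_scope_nonpositive(self, checkerboard64):
        # interior pixels have four high and four low neighbours: zero lag;
        # replicate-padded borders tip negative
        field = local_moran_field(checkerboard64)
        assert np.all(field.values <= 0)
        assert (field.values < 0).any()

    def test_flat_background_outlier_window_scope(self, window_config):
        field = local_moran_field(outlier_image(), config=window_config)
        assert field.values[2, 2] == -1.0

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            local_moran_field(np.ones((8, 8)), kernel=4)
        with pytest.raises(ValueError):
            LisaConfig(kernel=(3, 4))

    @pytest.mark.parametrize("scope", ["image", "window"])
    def test_matches_naive_oracle(self, naive_moran, scope):
        rng = np.random.default_rng(42)
        cfg = LisaConfig(stat_scope=scope)
        for _ in range(50):
            img = rng.uniform(0, 255, (8, 8))
            fast = local_moran_field(img, config=cfg).values
            slow = naive_moran(img, cfg)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_matches_naive_oracle_on_5x5_kernel(self, naive_moran):
        rng = np.random.default_rng(7)
        cfg = LisaConfig(kernel=5)
        img = rng.uniform(0, 10, (12, 12))
        np.testing.assert_allclose(
            local_moran_field(img, config=cfg).values, naive_moran(img, cfg), atol=1e-10
        )

    @pytest.mark.parametrize("scope", ["image", "window"])
    @pytest.mark.parametrize("a,b", [(2.0, 0.0), (0.5, 10.0), (100.0, 3.0)])
    def test_affine_intensity_invariance(self, scope, a, b):
        rng = np.random.default_rng(3)
        img = rng.uniform(1, 200, (16, 16))
        cfg = LisaConfig(stat_scope=scope)
        base = local_moran_field(img, config=cfg).values
        mapped = local_moran_field(a * img + b, config=cfg).values
        np.testing.assert_allclose(base, mapped, atol=1e-9)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(0, 255, (12, 20))
        f = local_moran_field(img).values
        ft = local_moran_field(img.T).values
        np.testing.assert_allclose(ft, f.T, atol=1e-12)

    def test_values_finite(self, brain64):
        for scope in ("image", "window"):
            vals = local_moran_field(brain64, config=LisaConfig(stat_scope=scope)).values
            assert np.all(np.isfinite(vals))


class TestGlobalMoran:
    def test_uniform_full_mask_is_one(self, uniform64):
        field = local_moran_field(uniform64)
        assert global_moran(field, full_mask(uniform64)) == 1.0

    @pytest.mark.parametrize("scope", ["image", "window"])
    def test_checkerboard_negative(self, checkerboard64, scope):
        field = local_moran_field(checkerboard64, config=LisaConfig(stat_scope=scope))
        assert global_moran(field, full_mask(checkerboard64)) < 0

    def test_single_pixel_mask(self, brain64):
        field = local_moran_field(brain64)
        mask = np.zeros(brain64.shape, dtype=bool)
        mask[30, 30] = True
        assert global_moran(field, mask) == field.values[30, 30]

    def test_empty_mask_rejected(self, uniform64):
        field = local_moran_field(uniform64)
        with pytest.raises(ValueError):
            global_moran(field, np.zeros(uniform64.shape, dtype=bool))

    def test_gms_decomposes_into_local_terms(self, brain64):
        field = local_moran_field(brain64)
        gms = global_moran(field, np.ones(brain64.shape, dtype=bool))
        assert gms == pytest.approx(field.values.mean(), abs=1e-12)


class TestClassification:
    def test_uniform_all_clustered(self, uniform64):
        field = local_moran_field(uniform64)
        classes = classify_pixels(field, full_mask(uniform64))
        assert classes.n_A == 0 and classes.n_B == 64 * 64

    @pytest.mark.parametrize("scope", ["image", "window"])
    def test_checkerboard_all_dispersed(self, checkerboard64, scope):
        field = local_moran_field(checkerboard64, config=LisaConfig(stat_scope=scope))
        classes = classify_pixels(field, full_mask(checkerboard64))
        assert classes.n_A == 64 * 64 and classes.n_B == 0

    def test_exact_zero_belongs_to_class_a(self):
        from dataclasses import replace

        img = np.arange(64.0).reshape(8, 8)
        field = local_moran_field(img)
        zeroed = replace(field, values=np.zeros_like(field.values))
        classes = classify_pixels(zeroed, np.ones((8, 8), dtype=bool))
        assert classes.n_A == 64 and classes.n_B == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_classes_partition_foreground(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 255, (16, 16))
        mask = rng.random((16, 16)) > 0.4
        field = local_moran_field(img)
        classes = classify_pixels(field, mask)
        assert classes.n_A + classes.n_B == int(mask.sum())
        assert not classes.labels[~mask].any()


class TestQuadrants:
    def test_uniform_all_none(self, uniform64):
        field = local_moran_field(uniform64)
        quads = quadrant_labels(uniform64, field, full_mask(uniform64))
        assert np.all(quads.labels == QUAD_NONE)

    def test_flat_background_outlier_is_hl(self, window_config):
        img = outlier_image()
        field = local_moran_field(img, config=window_config)
        quads = quadrant_labels(img, field, np.ones(img.shape, dtype=bool))
        assert quads.labels[2, 2] == QUAD_HL

    def test_checkerboard_window_scope_outliers(self, checkerboard64, window_config):
        field = local_moran_field(checkerboard64, config=window_config)
        quads = quadrant_labels(checkerboard64, field, full_mask(checkerboard64))
        assert quads.labels[5, 5] == QUAD_HL  # high pixel among lows
        assert quads.labels[5, 6] == QUAD_LH  # low pixel among highs

    def test_cluster_outlier_sign_invariant(self, brain64):
        field = local_moran_field(brain64)
        quads = quadrant_labels(brain64, field, np.ones(brain64.shape, dtype=bool))
        clustered = np.isin(quads.labels, (QUAD_HH, QUAD_LL))
        outliers = np.isin(quads.labels, (QUAD_HL, QUAD_LH))
        assert np.all(field.values[clustered] > 0)
        assert np.all(field.values[outliers] < 0)
        assert clustered.any() and outliers.any()

    def test_name_mapping(self, brain64):
        field = local_moran_field(brain64)
        quads = quadrant_labels(brain64, field, np.ones(brain64.shape, dtype=bool))
        names = set(np.unique(quads.names()))
        assert names <= {"none", "HH", "LL", "HL", "LH"}
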