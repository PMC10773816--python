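"""Texture engine tests: quantization, GLCM, Haralick features, stacks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.feature import graycomatrix

from canopytex.scene import MultispectralScene
from canopytex.texture import (
    DIRECTIONS,
    FEATURES,
    GLCMConfig,
    GLCMGrid,
    TextureError,
    build_full_stack,
    glcm_window,
    haralick_features,
    nd_average,
    pca_compress,
    quantize,
    stack_key,
    texture_image,
)

from _oracles import brute_force_glcm, literal_haralick


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

class TestQuantize:
    def test_endpoints_map_to_first_and_last_level(self):
        img = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize(img, 32)
        assert q.flat[0] == 0 and q.flat[-1] == 31

    def test_constant_image_maps_to_zero(self):
        q = quantize(np.full((5, 5), 3.7), 32)
        assert np.all(q == 0)

    def test_bin_counts_match_histogram_oracle(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(-2.0, 5.0, size=(40, 40))
        levels = 8
        q = quantize(img, levels)
        edges = np.linspace(img.min(), img.max(), levels + 1)
        expected, _ = np.histogram(img, bins=edges)
        counts = np.bincount(q.ravel(), minlength=levels)
        np.testing.assert_array_equal(counts, expected)

    def test_too_few_levels_rejected(self):
        with pytest.raises(TextureError):
            quantize(np.zeros((3, 3)), 1)


# ---------------------------------------------------------------------------
# Single-window GLCM
# ---------------------------------------------------------------------------

class TestGlcmWindow:
    def test_constant_window_concentrates_on_diagonal(self):
        w = np.full((3, 3), 5, dtype=np.int32)
        for direction in DIRECTIONS:
            g = glcm_window(w, direction, levels=8)
            assert g.matrix[5, 5] == pytest.approx(1.0)
            assert g.matrix.sum() == pytest.approx(1.0)

    def test_checkerboard_has_no_same_level_pairs_along_rows(self):
        w = np.indices((6, 6)).sum(axis=0) % 2
        g = glcm_window(w.astype(np.int32), "D1", levels=2)
        assert g.matrix[0, 0] == 0.0 and g.matrix[1, 1] == 0.0

    @pytest.mark.parametrize("direction", DIRECTIONS)
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_pair_counter(self, direction, symmetric):
        rng = np.random.default_rng(42)
        for _ in range(50):
            w = rng.integers(0, 6, size=(5, 5)).astype(np.int32)
            got = glcm_window(w, direction, symmetric=symmetric, levels=6)
            want = brute_force_glcm(w, direction, symmetric=symmetric, levels=6)
            np.testing.assert_array_equal(got.matrix, want)

    def test_symmetric_matrix_is_symmetric_and_normalized(self):
        rng = np.random.default_rng(1)
        w = rng.integers(0, 10, size=(9, 9)).astype(np.int32)
        g = glcm_window(w, "D2", symmetric=True, levels=10)
        np.testing.assert_allclose(g.matrix, g.matrix.T, atol=1e-15)
        assert g.matrix.sum() == pytest.approx(1.0, abs=1e-12)

    def test_displacement_beyond_window_raises(self):
        w = np.zeros((2, 2), dtype=np.int32)
        with pytest.raises(TextureError):
            glcm_window(w, "D3", displacement=3, levels=2)

    def test_agrees_with_skimage_graycomatrix(self):
        # Independent library cross-check.  skimage pairs (r, c) with
        # (r + d sin(theta), c + d cos(theta)), i.e. its angles grow
        # clockwise in image coordinates, while this engine's grow
        # counter-clockwise; under the symmetric GLCM the two conventions
        # coincide with theta mapped to pi - theta for the diagonals.
        rng = np.random.default_rng(7)
        w = rng.integers(0, 8, size=(11, 11)).astype(np.uint8)
        angles = {"D1": 0.0, "D2": 3 * np.pi / 4, "D3": np.pi / 2, "D4": np.pi / 4}
        for direction, angle in angles.items():
            ref = graycomatrix(
                w, [1], [angle], levels=8, symmetric=True, normed=True
            )[:, :, 0, 0]
            got = glcm_window(w.astype(np.int32), direction, levels=8)
            np.testing.assert_allclose(got.matrix, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# Haralick features
# ---------------------------------------------------------------------------

def random_glcm(rng: np.random.Generator, n: int = 8) -> np.ndarray:
    p = rng.random((n, n))
    p = (p + p.T) / 2.0
    return p / p.sum()


class TestHaralickFeatures:
    def test_single_entry_matrix_is_fully_degenerate(self):
        p = np.zeros((8, 8))
        p[5, 5] = 1.0
        f = haralick_features(p)
        assert f["Con"] == 0 and f["Dis"] == 0 and f["Ent"] == 0
        assert f["Var"] == 0 and f["Mean"] == 5
        assert f["Hom"] == pytest.approx(1.0)
        assert f["SM"] == pytest.approx(1.0)
        assert f["Cor"] == 0.0  # degenerate-sigma rule

    def test_uniform_matrix_maximizes_entropy(self):
        n = 16
        p = np.full((n, n), 1.0 / n**2)
        f = haralick_features(p)
        assert f["Ent"] == pytest.approx(2 * np.log(n))
        assert f["SM"] == pytest.approx(1.0 / n**2)

    def test_matches_literal_double_loop_evaluation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_glcm(rng)
            got = haralick_features(p)
            want = literal_haralick(p)
            for name in FEATURES:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(TextureError):
            haralick_features(np.full((4, 4), 1.0))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        raw=hnp.arrays(
            dtype=np.float64,
            shape=(6, 6),
            elements=st.floats(0.001, 1.0),
        )
    )
    def test_feature_bounds_hold_for_any_glcm(self, raw):
        p = (raw + raw.T) / 2.0
        p = p / p.sum()
        f = haralick_features(p)
        assert 0.0 < f["Hom"] <= 1.0 + 1e-12
        assert 0.0 < f["SM"] <= 1.0 + 1e-12
        assert f["Con"] >= 0 and f["Dis"] >= 0 and f["Ent"] >= 0 and f["Var"] >= 0
        assert -1.0 - 1e-9 <= f["Cor"] <= 1.0 + 1e-9
        # Cauchy-Schwarz on the |i-j| pair distribution
        assert f["Dis"] ** 2 <= f["Con"] + 1e-12

    def test_entropy_below_maximum_unless_uniform(self):
        rng = np.random.default_rng(9)
        n = 8
        for _ in range(10):
            p = random_glcm(rng, n)
            assert haralick_features(p)["Ent"] < 2 * np.log(n)


# ---------------------------------------------------------------------------
# Sliding-window texture images
# ---------------------------------------------------------------------------

class TestTextureImage:
    def test_constant_image_gives_flat_degenerate_rasters(self):
        img = np.full((20, 25), 4, dtype=np.int32)
        maps = texture_image(img, GLCMConfig(window_px=5, direction="D1", levels=8),
                             prequantized=True)
        np.testing.assert_allclose(maps["Con"], 0.0)
        np.testing.assert_allclose(maps["Hom"], 1.0)
        np.testing.assert_allclose(maps["Ent"], 0.0)
        np.testing.assert_allclose(maps["Cor"], 0.0)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_pixels_match_single_window_computation(self, direction):
        rng = np.random.default_rng(11)
        img = rng.integers(0, 8, size=(30, 35)).astype(np.int32)
        cfg = GLCMConfig(window_px=7, direction=direction, levels=8)
        maps = texture_image(img, cfg, prequantized=True)
        padded = np.pad(img, 3, mode="reflect")
        ys = rng.integers(0, 30, size=10)
        xs = rng.integers(0, 35, size=10)
        for y, x in zip(ys, xs):
            window = padded[y : y + 7, x : x + 7]
            want = haralick_features(glcm_window(window, direction, levels=8))
            for name in FEATURES:
                assert maps[name][y, x] == pytest.approx(want[name], abs=1e-10)

    def test_vertical_stripes_contrast_strongest_across_stripes(self):
        img = np.tile(np.array([0, 3] * 10), (24, 1)).astype(np.int32)
        cfg = lambda d: GLCMConfig(window_px=5, direction=d, levels=4)
        con_d1 = texture_image(img, cfg("D1"), prequantized=True)["Con"]
        con_d3 = texture_image(img, cfg("D3"), prequantized=True)["Con"]
        interior = (slice(5, -5), slice(5, -5))
        assert (con_d1[interior] > con_d3[interior]).all()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(TextureError):
            texture_image(np.zeros((4, 4), dtype=np.int32),
                          GLCMConfig(window_px=7, direction="D1"), prequantized=True)

    def test_rotating_image_90_degrees_swaps_direction_pairs(self):
        rng = np.random.default_rng(13)
        img = rng.integers(0, 16, size=(28, 32)).astype(np.int32)
        cfg = lambda d: GLCMConfig(window_px=5, direction=d, levels=16)
        rot = np.ascontiguousarray(np.rot90(img))
        for d_a, d_b in (("D1", "D3"), ("D2", "D4")):
            a = texture_image(img, cfg(d_a), prequantized=True)
            b = texture_image(rot, cfg(d_b), prequantized=True)
            for name in FEATURES:
                np.testing.assert_allclose(
                    np.rot90(a[name]), b[name], atol=1e-10
                )

    def test_nd_raster_invariant_under_rotation(self):
        rng = np.random.default_rng(14)
        img = rng.integers(0, 16, size=(26, 30)).astype(np.int32)
        rot = np.ascontiguousarray(np.rot90(img))

        def nd(of):
            return nd_average({
                d: texture_image(of, GLCMConfig(window_px=5, direction=d, levels=16),
                                 prequantized=True)
                for d in DIRECTIONS
            })

        a, b = nd(img), nd(rot)
        for name in FEATURES:
            np.testing.assert_allclose(np.rot90(a[name]), b[name], atol=1e-10)


class TestNdAverage:
    def test_mean_of_constant_rasters(self):
        stacks = {
            d: {"Con": np.full((4, 4), v)}
            for d, v in zip(DIRECTIONS, (1.0, 2.0, 3.0, 4.0))
        }
        # fill remaining features so keys align
        for d in DIRECTIONS:
            for name in FEATURES:
                stacks[d].setdefault(name, np.zeros((4, 4)))
        out = nd_average(stacks)
        np.testing.assert_allclose(out["Con"], 2.5)

    def test_identical_directions_idempotent(self):
        rng = np.random.default_rng(2)
        base = {name: rng.random((5, 5)) for name in FEATURES}
        out = nd_average({d: base for d in DIRECTIONS})
        for name in FEATURES:
            np.testing.assert_allclose(out[name], base[name])

    def test_random_stacks_equal_elementwise_mean(self):
        rng = np.random.default_rng(3)
        stacks = {
            d: {name: rng.random((6, 7)) for name in FEATURES}
            for d in DIRECTIONS
        }
        out = nd_average(stacks)
        for name in FEATURES:
            want = np.mean([stacks[d][name] for d in DIRECTIONS], axis=0)
            np.testing.assert_array_equal(out[name], want)

    def test_missing_direction_rejected(self):
        stacks = {d: {name: np.zeros((2, 2)) for name in FEATURES}
                  for d in ("D1", "D2", "D3")}
        with pytest.raises(TextureError, match="D4"):
            nd_average(stacks)


# ---------------------------------------------------------------------------
# PCA compression
# ---------------------------------------------------------------------------

class TestPcaCompress:
    def test_duplicated_band_compresses_to_one_component(self):
        rng = np.random.default_rng(5)
        band = rng.random((10, 12))
        scene = MultispectralScene(
            bands=np.stack([band, band]), band_names=("a", "b")
        )
        res = pca_compress(scene)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)
        assert res.n_selected == 1

    def test_ratios_match_correlation_eigenvalue_oracle(self):
        rng = np.random.default_rng(6)
        latent = rng.random((2, 400))
        mix = rng.random((5, 2)) @ latent + 0.05 * rng.random((5, 400))
        scene = MultispectralScene(
            bands=mix.reshape(5, 20, 20),
            band_names=("B", "G", "R", "RE", "NIR"),
        )
        res = pca_compress(scene)
        X = mix.T
        Xz = (X - X.mean(0)) / X.std(0)
        eigvals = np.sort(np.linalg.eigvalsh(np.corrcoef(Xz.T)))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_ratio, eigvals / eigvals.sum(), atol=1e-8
        )

    def test_threshold_is_strictly_exceeded(self):
        # Construct data whose first two ratios are ~(0.6, 0.31): the
        # second component is needed because 0.6 < 0.9 < 0.91.
        rng = np.random.default_rng(8)
        n = 5000
        latent1 = rng.standard_normal(n)
        latent2 = rng.standard_normal(n)
        noise = rng.standard_normal((n, 5))
        X = (
            np.outer(latent1, [1.7, 1.7, 1.7, 0.1, 0.1])
            + np.outer(latent2, [0.1, 0.1, 0.1, 1.25, 1.25])
            + 0.55 * noise
        )
        scene = MultispectralScene(
            bands=np.ascontiguousarray(X.T.reshape(5, 50, 100)),
            band_names=("B", "G", "R", "RE", "NIR"),
        )
        res = pca_compress(scene, threshold=0.90)
        cumulative = np.cumsum(res.explained_variance_ratio)
        k = res.n_selected
        assert cumulative[k - 1] > 0.90
        if k > 1:
            assert cumulative[k - 2] <= 0.90

    def test_zero_variance_band_named_in_error(self):
        bands = np.random.default_rng(1).random((3, 8, 8))
        bands[1] = 0.5
        scene = MultispectralScene(bands=bands, band_names=("B", "G", "R"))
        with pytest.raises(TextureError, match="G"):
            pca_compress(scene)

    def test_loadings_columns_are_orthonormal(self):
        rng = np.random.default_rng(12)
        scene = MultispectralScene(bands=rng.random((5, 15, 15)))
        res = pca_compress(scene)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)


# ---------------------------------------------------------------------------
# Full stack
# ---------------------------------------------------------------------------

class TestBuildFullStack:
    @staticmethod
    def two_component_pca(shape=(24, 40)):
        rng = np.random.default_rng(15)
        latent1 = rng.standard_normal(shape)
        latent2 = rng.standard_normal(shape)
        noise = [0.1 * rng.standard_normal(shape) for _ in range(5)]
        loads = [(1.0, 0.1), (0.9, 0.2), (0.8, 0.1), (0.2, 1.0), (0.1, 0.9)]
        bands = np.stack(
            [a * latent1 + b * latent2 + n for (a, b), n in zip(loads, noise)]
        )
        scene = MultispectralScene(bands=bands)
        return pca_compress(scene)

    def test_full_grid_yields_240_unique_rasters(self):
        pca = self.two_component_pca()
        assert pca.n_selected == 2
        stack = build_full_stack(pca, GLCMGrid(levels=8))
        assert len(stack) == 240
        expected = {
            stack_key(c, f, w, d)
            for c in (1, 2)
            for f in FEATURES
            for w in (3, 7, 13)
            for d in ("D1", "D2", "D3", "D4", "ND")
        }
        assert set(stack) == expected

    def test_reduced_grid_counts(self):
        pca = self.two_component_pca()
        pca.n_selected = 1
        stack = build_full_stack(pca, GLCMGrid(windows=(3,), levels=8))
        assert len(stack) == 40  # 1 component x 8 features x 1 window x 5 dirs

    def test_all_rasters_share_scene_shape(self):
        pca = self.two_component_pca()
        stack = build_full_stack(pca, GLCMGrid(windows=(3,), levels=8))
        shapes = {raster.shape for raster in stack.values()}
        assert shapes == {pca.component_images[0].shape}
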