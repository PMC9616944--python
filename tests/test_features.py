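"""Descriptor correctness against independent brute-force oracles.

The oracles re-derive each descriptor from first principles (direct pixel
counting, double-sum moment evaluation, pixel-pair enumeration) without
touching the implementation path, and are run on tiny toy images.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.color import rgb2hsv

from dermclf import DescriptorConfig, LesionImage, extract_global, load_features, store_features
from dermclf.errors import FormatError, SchemaError
from dermclf.features import (
    FeatureVector,
    _haralick_13,
    color_histogram,
    haralick,
    hu_moments,
    quantize_gray,
    to_grayscale,
)

# ---------------------------------------------------------------- oracles


def oracle_histogram(img: np.ndarray, bins: int, space: str) -> np.ndarray:
    """Direct per-pixel counting into the 3-D joint histogram."""
    data = rgb2hsv(img) if space == "HSV" else img / 255.0
    counts = np.zeros((bins, bins, bins))
    for px in data.reshape(-1, 3):
        idx = tuple(min(int(v * bins), bins - 1) for v in px)
        counts[idx] += 1
    return (counts / counts.sum()).ravel()


def oracle_hu(gray: np.ndarray) -> np.ndarray:
    """Raw -> central -> scale-normalised moments -> the seven invariants."""
    h, w = gray.shape
    # row-major convention: the first image axis is x, matching the
    # moment definitions used on (row, col) arrays
    xs, ys = np.mgrid[0:h, 0:w].astype(float)

    def m(p, q):
        return float((xs**p * ys**q * gray).sum())

    m00 = m(0, 0)
    xb, yb = m(1, 0) / m00, m(0, 1) / m00

    def mu(p, q):
        return float((((xs - xb) ** p) * ((ys - yb) ** q) * gray).sum())

    def nu(p, q):
        return mu(p, q) / m00 ** (1 + (p + q) / 2)

    n20, n02, n11 = nu(2, 0), nu(0, 2), nu(1, 1)
    n30, n03, n21, n12 = nu(3, 0), nu(0, 3), nu(2, 1), nu(1, 2)
    h1 = n20 + n02
    h2 = (n20 - n02) ** 2 + 4 * n11**2
    h3 = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    h4 = (n30 + n12) ** 2 + (n21 + n03) ** 2
    h5 = (n30 - 3 * n12) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) + (
        3 * n21 - n03
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    h6 = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (n30 + n12) * (
        n21 + n03
    )
    h7 = (3 * n21 - n03) * (n30 + n12) * ((n30 + n12) ** 2 - 3 * (n21 + n03) ** 2) - (
        n30 - 3 * n12
    ) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    return np.array([h1, h2, h3, h4, h5, h6, h7])


# (row, col) displacement per angle: (round(sin t), round(cos t)) * distance
_ANGLE_OFFSETS = {0.0: (0, 1), np.pi / 4: (1, 1), np.pi / 2: (1, 0), 3 * np.pi / 4: (1, -1)}


def oracle_glcm(q: np.ndarray, levels: int, distance: int, angle: float) -> np.ndarray:
    """Symmetric normalised GLCM by explicit enumeration of all pixel pairs."""
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((levels, levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
                counts[q[r2, c2], q[r, c]] += 1  # symmetric
    return counts / counts.sum()


def _img(pixels, image_id="x", label="nv"):
    return LesionImage(image_id, label, np.asarray(pixels, dtype=np.uint8))


def _random_img(rng, side=8):
    return _img(rng.integers(0, 256, (side, side, 3)))


# ----------------------------------------------------------- histogram


class TestColorHistogram:
    def test_single_colour_is_a_point_mass(self):
        hist = color_histogram(_img(np.full((5, 5, 3), 200)))
        assert np.isclose(hist.max(), 1.0)
        assert np.count_nonzero(hist) == 1

    def test_two_colour_image_gives_two_half_bins(self):
        cfg = DescriptorConfig(hist_color_space="RGB")
        pixels = np.array([[[10, 10, 10], [240, 240, 240]]])
        hist = color_histogram(_img(pixels), cfg)
        assert sorted(hist[hist > 0]) == [0.5, 0.5]

    @pytest.mark.parametrize("space", ["HSV", "RGB"])
    def test_matches_direct_counting_oracle(self, rng, space):
        cfg = DescriptorConfig(hist_color_space=space)
        img = _random_img(rng)
        np.testing.assert_allclose(
            color_histogram(img, cfg),
            oracle_histogram(img.pixels, cfg.hist_bins_per_channel, space),
            atol=1e-12,
        )

    def test_sums_to_one(self, rng):
        assert np.isclose(color_histogram(_random_img(rng, 16)).sum(), 1.0, atol=1e-9)


# ----------------------------------------------------------- Hu moments


class TestHuMoments:
    def _raw(self, img):
        return hu_moments(img, DescriptorConfig(hu_log_transform=False))

    def test_matches_double_sum_oracle_on_toy_grids(self, rng):
        for _ in range(5):
            img = _random_img(rng, side=rng.integers(3, 9))
            expected = oracle_hu(to_grayscale(img))
            np.testing.assert_allclose(self._raw(img), expected, rtol=1e-6, atol=1e-12)

    def test_3x3_grid_against_oracle(self):
        gray3 = np.arange(9).reshape(3, 3) * 28
        img = _img(np.repeat(gray3[:, :, None], 3, axis=2))
        np.testing.assert_allclose(self._raw(img), oracle_hu(to_grayscale(img)), rtol=1e-6)

    def test_mirror_preserves_first_six_and_negates_seventh(self, rng):
        img = _random_img(rng)
        mirrored = _img(img.pixels[:, ::-1])
        hu_a, hu_b = self._raw(img), self._raw(mirrored)
        np.testing.assert_allclose(hu_a[:6], hu_b[:6], rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(hu_a[6], -hu_b[6], rtol=1e-6, atol=1e-12)

    def test_rotation_by_90_degrees_is_invariant(self, rng):
        img = _random_img(rng)
        rotated = _img(np.rot90(img.pixels))
        np.testing.assert_allclose(self._raw(img), self._raw(rotated), rtol=1e-6, atol=1e-12)

    def test_all_zero_image_returns_zero_vector_without_error(self):
        assert np.all(hu_moments(_img(np.zeros((4, 4, 3)))) == 0.0)

    def test_log_transform_compresses_range(self, rng):
        img = _random_img(rng)
        logged = hu_moments(img, DescriptorConfig(hu_log_transform=True))
        assert np.all(np.abs(logged) <= 30.0 + 1e-9)


# ----------------------------------------------------------- Haralick


class TestHaralick:
    def test_constant_image_degenerate_values(self):
        vec = haralick(_img(np.full((6, 6, 3), 120)))
        asm, contrast, correlation = vec[0], vec[1], vec[2]
        entropy = vec[8]
        assert np.isclose(asm, 1.0)
        assert np.isclose(contrast, 0.0)
        assert np.isclose(entropy, 0.0)
        assert np.isclose(correlation, 0.0)  # zero-variance convention

    def test_checkerboard_contrast_matches_hand_enumeration(self):
        # 4x4 checkerboard of gray levels 0 and 255 -> quantized 0 / L-1
        board = np.indices((4, 4)).sum(0) % 2 * 255
        img = _img(np.repeat(board[:, :, None], 3, axis=2))
        cfg = DescriptorConfig(glcm_levels=2, glcm_angles=(0.0,))
        vec = haralick(img, cfg)
        # horizontally every one of the 12 adjacent pairs alternates:
        # GLCM is all mass off-diagonal, contrast = (1-0)^2 = 1
        assert np.isclose(vec[1], 1.0)
        assert np.isclose(vec[0], 0.5)  # two off-diagonal cells of 0.5 each

    @pytest.mark.parametrize("angle", list(_ANGLE_OFFSETS))
    def test_thirteen_stats_match_pair_enumeration_oracle(self, rng, angle):
        img = _random_img(rng, 8)
        cfg = DescriptorConfig(glcm_levels=4, glcm_angles=(angle,))
        q = quantize_gray(to_grayscale(img), 4)
        expected = _haralick_13(oracle_glcm(q, 4, 1, angle))
        np.testing.assert_allclose(haralick(img, cfg), expected, rtol=1e-6, atol=1e-9)

    def test_glcm_of_skimage_equals_enumeration(self, rng):
        """The GLCM itself (not just its statistics) matches pair counting."""
        from skimage.feature import graycomatrix

        img = _random_img(rng, 8)
        q = quantize_gray(to_grayscale(img), 4)
        for angle in _ANGLE_OFFSETS:
            p = graycomatrix(q.astype(np.uint8), [1], [angle], levels=4,
                             symmetric=True, normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(p, oracle_glcm(q, 4, 1, angle), atol=1e-12)

    def test_horizontal_mirror_is_invariant_with_four_angles(self, rng):
        img = _random_img(rng, 12)
        mirrored = _img(img.pixels[:, ::-1])
        np.testing.assert_allclose(haralick(img), haralick(mirrored), atol=1e-9)


# ----------------------------------------------------- global vector & HDF5


class TestGlobalVector:
    def test_default_length_is_532(self, rng):
        assert extract_global(_random_img(rng)).values.shape == (532,)

    def test_two_bin_config_gives_length_28(self, rng):
        cfg = DescriptorConfig(hist_bins_per_channel=2)
        assert extract_global(_random_img(rng), cfg).values.shape == (28,)

    def test_identical_images_give_identical_vectors(self, rng):
        img = _random_img(rng)
        copy = _img(img.pixels.copy())
        np.testing.assert_array_equal(
            extract_global(img).values, extract_global(copy).values
        )

    def test_concatenation_order_histogram_hu_haralick(self, rng):
        img = _random_img(rng)
        cfg = DescriptorConfig()
        vec = extract_global(img, cfg).values
        np.testing.assert_array_equal(vec[:512], color_histogram(img, cfg))
        np.testing.assert_array_equal(vec[512:519], hu_moments(img, cfg))
        np.testing.assert_array_equal(vec[519:], haralick(img, cfg))

    def test_flip_difference_is_confined_to_hu7(self, rng):
        img = _random_img(rng, 12)
        flipped = _img(img.pixels[:, ::-1])
        a = extract_global(img).values
        b = extract_global(flipped).values
        diff = np.abs(a - b)
        hu7_index = 512 + 6
        others = np.delete(diff, hu7_index)
        assert np.all(others < 1e-6)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_no_nan_or_inf_for_any_uint8_input(self, seed):
        rng = np.random.default_rng(seed)
        side = int(rng.integers(2, 16))
        vec = extract_global(_img(rng.integers(0, 256, (side, side, 3)))).values
        assert np.isfinite(vec).all()


class TestFeatureStore:
    def _vectors(self, rng, n=10, d=28):
        cfg = DescriptorConfig(hist_bins_per_channel=2)
        return [extract_global(_random_img(rng), cfg) for _ in range(n)], cfg

    def test_round_trip_is_bitwise_exact(self, tmp_path, rng):
        vectors, cfg = self._vectors(rng)
        store_features(vectors, tmp_path / "f.h5", cfg)
        loaded = load_features(tmp_path / "f.h5")
        assert [v.image_id for v in loaded] == [v.image_id for v in vectors]
        assert [v.label for v in loaded] == [v.label for v in vectors]
        for a, b in zip(loaded, vectors):
            np.testing.assert_array_equal(a.values, b.values)

    def test_empty_list_is_a_schema_error(self, tmp_path):
        with pytest.raises(SchemaError):
            store_features([], tmp_path / "f.h5")

    def test_ragged_vectors_are_a_schema_error(self, tmp_path):
        ragged = [
            FeatureVector("a", np.zeros(5), "nv"),
            FeatureVector("b", np.zeros(6), "nv"),
        ]
        with pytest.raises(SchemaError):
            store_features(ragged, tmp_path / "f.h5")

    def test_missing_dataset_is_a_format_error(self, tmp_path):
        import h5py

        with h5py.File(tmp_path / "bad.h5", "w") as f:
            f.create_dataset("features", data=np.zeros((2, 3)))
        with pytest.raises(FormatError):
            load_features(tmp_path / "bad.h5")

    def test_stored_matrix_shape(self, tmp_path, rng):
        vectors, cfg = self._vectors(rng, n=14)
        store_features(vectors, tmp_path / "f.h5", cfg)
        import h5py

        with h5py.File(tmp_path / "f.h5", "r") as f:
            assert f["features"].shape == (14, 28)
            assert DescriptorConfig.from_json(f.attrs["descriptor_config"]) == cfg
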