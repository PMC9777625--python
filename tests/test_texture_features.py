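"""Texture feature correctness: first-order stats, GLCM/Haralick, Haar frame."""

import numpy as np
import pytest

from carotexture.features import (
    DISTANCES,
    FEATURE_NAMES,
    THETA_OFFSETS,
    THETAS,
    GlcmMatrix,
    QuantizedRoi,
    TextureParams,
    compute_glcm,
    extract_feature_vector,
    feature_table,
    first_order_stats,
    haar_frame_decompose,
    haralick_all,
    haralick_measures,
    quantize,
    wavelet_energies,
)
from carotexture.io import RoiRegion, UltrasoundImage, crop_to_roi, rasterize_roi


def make_roi(mask):
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    poly = np.array([
        (rows.min(), cols.min()), (rows.min(), cols.max()),
        (rows.max(), cols.max()), (rows.max(), cols.min()),
    ], dtype=float)
    r = RoiRegion.__new__(RoiRegion)
    r.polygon = poly
    r.mask = mask
    return r


def glcm_brute(levels, mask, ng, d, theta, directed=True):
    """Exhaustive ordered-pair enumeration; the oracle for compute_glcm."""
    dr, dc = THETA_OFFSETS[theta]
    dr, dc = dr * d, dc * d
    counts = np.zeros((ng, ng))
    nr, nc = mask.shape
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if mask[r, c] and 0 <= r2 < nr and 0 <= c2 < nc and mask[r2, c2]:
                counts[levels[r, c], levels[r2, c2]] += 1
    if not directed:
        counts = counts + counts.T
    return counts


class TestFirstOrder:
    def test_constant_roi(self):
        img = UltrasoundImage(np.full((4, 4), 7.0))
        mu, sigma = first_order_stats(img, make_roi(np.ones((4, 4))))
        assert (mu, sigma) == (7.0, 0.0)

    def test_two_value_population_formulas(self):
        # {0, 1} equally: population mean 0.5, population SD 0.5 (divisor n)
        img = UltrasoundImage(np.array([[0.0, 1.0], [0.0, 1.0]]))
        mu, sigma = first_order_stats(img, make_roi(np.ones((2, 2))))
        assert mu == 0.5 and sigma == 0.5

    def test_single_pixel(self):
        img = UltrasoundImage(np.array([[3.0, 9.0]]))
        mask = np.array([[False, True]])
        mu, sigma = first_order_stats(img, make_roi(mask))
        assert (mu, sigma) == (9.0, 0.0)


class TestQuantize:
    def test_linear_span_occupies_all_levels(self):
        img = UltrasoundImage(np.linspace(0, 1, 64).reshape(8, 8))
        q = quantize(img, make_roi(np.ones((8, 8))), ng=16)
        assert set(q.levels[q.mask]) == set(range(16))
        assert q.levels[q.mask].max() == 15  # max maps to ng-1

    def test_constant_roi_all_level_zero(self):
        img = UltrasoundImage(np.full((5, 5), 0.3))
        q = quantize(img, make_roi(np.ones((5, 5))), ng=16)
        assert np.all(q.levels[q.mask] == 0)

    def test_unit_range_mode(self):
        img = UltrasoundImage(np.full((5, 5), 0.5))
        q = quantize(img, make_roi(np.ones((5, 5))), ng=16, quant_range="unit")
        assert np.all(q.levels[q.mask] == 8)


class TestGlcm:
    def test_directed_hand_example(self):
        # 1x4 ROI, levels [0,1,0,1], d=1, theta=90 (right): ordered pairs
        # (0,1),(1,0),(0,1) -> P(0,1)=2/3, P(1,0)=1/3
        q = QuantizedRoi(levels=np.array([[0, 1, 0, 1]]),
                         mask=np.ones((1, 4), bool), ng=2, bin_edges=np.array([0, .5, 1]))
        g = compute_glcm(q, d=1, theta=90, directed=True)
        assert g.Z == 3
        np.testing.assert_allclose(g.P, [[0, 2 / 3], [1 / 3, 0]])

    def test_constant_roi_single_entry(self):
        q = QuantizedRoi(levels=np.zeros((3, 3), int), mask=np.ones((3, 3), bool),
                         ng=16, bin_edges=np.linspace(0, 1, 17))
        g = compute_glcm(q, 1, 90)
        assert g.P[0, 0] == 1.0 and g.P.sum() == 1.0

    def test_symmetric_mode_is_transpose_invariant(self, rng):
        lev = rng.integers(0, 8, size=(12, 12))
        q = QuantizedRoi(lev, rng.random((12, 12)) > 0.3, 8, np.linspace(0, 1, 9))
        for t in THETAS:
            g = compute_glcm(q, 2, t, directed=False)
            np.testing.assert_array_equal(g.P, g.P.T)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(30):
            ng = 6
            lev = rng.integers(0, ng, size=(15, 15))
            mask = rng.random((15, 15)) > 0.4
            q = QuantizedRoi(lev, mask, ng, np.linspace(0, 1, ng + 1))
            for d in DISTANCES:
                for t in THETAS:
                    counts = glcm_brute(lev, mask, ng, d, t)
                    if counts.sum() == 0:
                        with pytest.raises(ValueError):
                            compute_glcm(q, d, t)
                        continue
                    g = compute_glcm(q, d, t)
                    np.testing.assert_allclose(g.P, counts / counts.sum(), atol=1e-14)
                    assert abs(g.P.sum() - 1.0) < 1e-12

    def test_matches_skimage_on_rectangular_roi(self, rng):
        """Independent library oracle on a full-rectangle ROI.

        skimage's angle 0 is our theta=90 (right), its pi/4 our 135
        (down-right); its pi/2 and 3pi/4 are the reverses of our 0 and 45.
        Diagonals are compared at d=1 only: skimage rounds d*sin(theta)
        per axis while we step d whole pixels along the direction.
        """
        skimage_feature = pytest.importorskip("skimage.feature")
        lev = rng.integers(0, 8, size=(10, 14)).astype(np.uint8)
        q = QuantizedRoi(lev.astype(int), np.ones((10, 14), bool), 8, np.linspace(0, 1, 9))
        mapping = {90: (0.0, False), 135: (np.pi / 4, False),
                   0: (np.pi / 2, True), 45: (3 * np.pi / 4, True)}
        for d in (1, 3):
            for theta, (ang, transpose) in mapping.items():
                if d > 1 and theta in (45, 135):
                    continue
                ref = skimage_feature.graycomatrix(
                    lev, [d], [ang], levels=8, symmetric=False, normed=True)[:, :, 0, 0]
                if transpose:
                    ref = ref.T
                g = compute_glcm(q, d, theta, directed=True)
                np.testing.assert_allclose(g.P, ref, atol=1e-12)


class TestHaralick:
    def test_degenerate_single_entry_matrix(self):
        P = np.zeros((16, 16))
        P[0, 0] = 1.0
        h = haralick_measures(GlcmMatrix(P, 1, 0, 10, True))
        # H1=0, H2=0 (flagged), H3=0, H4=1, H5=1, H6=0, H7=0
        np.testing.assert_allclose(h, [0, 0, 0, 1, 1, 0, 0])

    def test_two_entry_hand_example(self):
        P = np.zeros((2, 2))
        P[0, 1] = P[1, 0] = 0.5
        h = haralick_measures(GlcmMatrix(P, 1, 0, 2, True))
        np.testing.assert_allclose(
            h, [1.0, -1.0, 1.0, 0.5, 0.5, 1.0, np.log(2)], atol=1e-12)

    def test_bounds_on_random_matrices(self, rng):
        for _ in range(20):
            P = rng.random((16, 16))
            P /= P.sum()
            h = haralick_measures(GlcmMatrix(P, 1, 0, 100, True))
            h1, h2, h3, h4, h5, h6, h7 = h
            assert 0 < h4 <= 1 and 0 < h5 <= 1
            assert h1 >= 0 and h3 >= 0 and h6 >= 0 and h7 >= 0
            assert abs(h2) <= 1 + 1e-9

    def test_haralick_all_inventory_and_decomposition(self, rng):
        lev = rng.integers(0, 16, size=(20, 20))
        mask = np.ones((20, 20), bool)
        q = QuantizedRoi(lev, mask, 16, np.linspace(0, 1, 17))
        vals = haralick_all(q)
        assert vals.shape == (140,)
        # decomposes into independent GLCM + measure calls
        idx = 0
        for d in DISTANCES:
            for t in THETAS:
                expected = haralick_measures(compute_glcm(q, d, t))
                np.testing.assert_array_equal(vals[idx:idx + 7], expected)
                idx += 7

    def test_thin_roi_imputes_long_vertical_displacement(self, rng):
        lev = rng.integers(0, 4, size=(3, 30))
        q = QuantizedRoi(lev, np.ones((3, 30), bool), 4, np.linspace(0, 1, 5))
        with pytest.warns(RuntimeWarning, match="imputed"):
            vals = haralick_all(q)
        assert vals.shape == (140,) and np.all(np.isfinite(vals))
        # d=5 theta=0 must equal the d=2 donor (largest vertical d with pairs)
        names = FEATURE_NAMES[2:142]
        v = dict(zip(names, vals))
        for a in range(1, 8):
            assert v[f"H_d5_t0_a{a}"] == v[f"H_d2_t0_a{a}"]

    def test_rotation_equivariance_symmetric_mode(self, rng):
        lev = rng.integers(0, 8, size=(16, 16))
        mask = rng.random((16, 16)) > 0.2
        rot_lev, rot_mask = np.rot90(lev), np.rot90(mask)
        for d in (1, 2):
            q = QuantizedRoi(lev, mask, 8, np.linspace(0, 1, 9))
            qr = QuantizedRoi(rot_lev.copy(), rot_mask.copy(), 8, np.linspace(0, 1, 9))
            # a CCW rotation maps right-pairs to up-pairs and 135 to 45
            for t_orig, t_rot in [(90, 0), (135, 45)]:
                a = haralick_measures(compute_glcm(q, d, t_orig, directed=False))
                b = haralick_measures(compute_glcm(qr, d, t_rot, directed=False))
                np.testing.assert_allclose(a, b, atol=1e-12)


class TestHaarFrame:
    def test_constant_image_kills_highpass(self):
        pyr = haar_frame_decompose(np.full((32, 32), 3.0), levels=3)
        np.testing.assert_allclose(pyr.f_levels[-1], 3.0, atol=1e-12)
        for band in pyr.d_bands.values():
            np.testing.assert_allclose(band, 0.0, atol=1e-12)

    def test_step_response_localized(self):
        # 1-row step: level-1 g response (-1/2, 1/2) fires only at the step
        x = np.zeros((16, 32))
        x[:, 16:] = 1.0
        pyr = haar_frame_decompose(x, levels=1, boundary="mirror")
        d1 = pyr.d_bands[(1, 1)]  # high-pass along rows: zero (rows constant)
        np.testing.assert_allclose(d1, 0.0, atol=1e-12)
        d2 = pyr.d_bands[(1, 2)]  # high-pass along columns
        nz = np.nonzero(np.abs(d2[0]) > 1e-12)[0]
        np.testing.assert_array_equal(nz, [15])
        assert d2[0, 15] == 0.5

    def test_filter_pair_is_power_complementary(self):
        w = np.linspace(0, np.pi, 101)
        H = (1 + np.exp(-1j * w)) / 2
        G = (np.exp(-1j * w) - 1) / 2
        np.testing.assert_allclose(np.abs(H) ** 2 + np.abs(G) ** 2, 1.0, atol=1e-12)

    def test_energy_conservation_periodic(self, rng):
        for _ in range(10):
            x = rng.random((32, 32))
            pyr = haar_frame_decompose(x, levels=3, boundary="periodic")
            for i in range(3):
                lhs = (pyr.f_levels[i] ** 2).sum()
                rhs = (pyr.f_levels[i + 1] ** 2).sum() + sum(
                    (pyr.d_bands[(i + 1, j)] ** 2).sum() for j in (1, 2, 3))
                np.testing.assert_allclose(lhs, rhs, atol=1e-10 * max(1, lhs))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            haar_frame_decompose(np.ones((8, 8)), levels=3)


class TestWaveletEnergies:
    def test_inventory_and_constant_image(self):
        pyr = haar_frame_decompose(np.full((32, 32), 2.0), levels=3)
        w = wavelet_energies(pyr, np.ones((32, 32), bool))
        assert len(w) == 10
        assert w["W0"] == pytest.approx(4.0)
        assert all(w[k] == pytest.approx(0.0) for k in w if k != "W0")

    def test_total_energy_telescopes_to_mean_square(self, rng):
        for _ in range(10):
            x = rng.random((32, 32))
            pyr = haar_frame_decompose(x, levels=3, boundary="periodic")
            w = wavelet_energies(pyr, np.ones((32, 32), bool))
            assert sum(w.values()) == pytest.approx(np.mean(x**2), abs=1e-10)


class TestFeatureVector:
    def test_length_and_canonical_order(self, rng):
        img = UltrasoundImage(rng.random((40, 60)))
        roi = make_roi(np.pad(np.ones((8, 30), bool), ((16, 16), (15, 15))))
        fv = extract_feature_vector(img, roi)
        assert len(fv.values) == 152
        assert list(fv.values) == FEATURE_NAMES
        assert FEATURE_NAMES[:2] == ["mu", "sigma"]
        assert FEATURE_NAMES[2] == "H_d1_t0_a1" and FEATURE_NAMES[141] == "H_d5_t135_a7"
        assert FEATURE_NAMES[142] == "W0" and FEATURE_NAMES[-1] == "W_3_3"

    def test_deterministic(self, rng):
        img = UltrasoundImage(rng.random((40, 60)))
        roi = make_roi(np.pad(np.ones((8, 30), bool), ((16, 16), (15, 15))))
        a = extract_feature_vector(img, roi).to_array()
        b = extract_feature_vector(img, roi).to_array()
        np.testing.assert_array_equal(a, b)

    def test_intensity_shift_leaves_haralick_unchanged(self, rng):
        base = rng.random((40, 60))
        roi = make_roi(np.pad(np.ones((8, 30), bool), ((16, 16), (15, 15))))
        a = extract_feature_vector(UltrasoundImage(base), roi)
        b = extract_feature_vector(UltrasoundImage(base + 0.37), roi)
        for name in FEATURE_NAMES[2:142]:
            assert a.values[name] == pytest.approx(b.values[name], abs=1e-12)
        # the shift moves mu by the constant and sigma not at all
        assert b.values["mu"] - a.values["mu"] == pytest.approx(0.37)
        assert b.values["sigma"] == pytest.approx(a.values["sigma"])

    def test_translation_invariance_with_margin(self, rng):
        patch = rng.random((140, 240))
        out = np.zeros((200, 320))
        poly = np.array([(60, 90), (60, 200), (70, 200), (70, 90)], float)

        def place(dr, dc):
            img = np.zeros((200, 320))
            img[dr:dr + 140, dc:dc + 240] = patch[:140, :240]
            roi = rasterize_roi(poly + [dr - 10, dc - 10], img.shape)
            ci, cr = crop_to_roi(UltrasoundImage(img), roi, margin_px=56)
            return extract_feature_vector(ci, cr)

        a, b = place(10, 10), place(13, 25)
        np.testing.assert_allclose(a.to_array(), b.to_array(), atol=1e-12)


class TestFeatureTable:
    def test_row_and_column_counts(self, small_cohort, small_table):
        assert small_table.shape == (small_cohort.n_images, 155)
        assert list(small_table.columns[:3]) == ["image_id", "patient_id", "group_label"]
        assert list(small_table.columns[3:]) == FEATURE_NAMES

    def test_csv_round_trip(self, small_table, tmp_path):
        import pandas as pd

        p = tmp_path / "features.csv"
        small_table.to_csv(p, index=False)
        back = pd.read_csv(p)
        pd.testing.assert_frame_equal(back, small_table, check_exact=False, rtol=1e-15)

    def test_ng_changes_values_not_inventory(self, small_cohort):
        t8 = feature_table(small_cohort, TextureParams(ng=8))
        assert t8.shape[1] == 155
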