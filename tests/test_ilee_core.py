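"""Laplacian construction, the edge-constrained solve, binarisation, K2."""

import math

import numpy as np
import pytest
from scipy import ndimage

from ilee import (
    ILEEParams,
    K2Model,
    binarize,
    build_laplacian,
    difference_and_denoise,
    estimate_k2,
    run_ilee,
    solve_threshold_surface,
)
from ilee.gradient_and_edges import EdgeSelection
from ilee.ilee_core import niblack_top_dt
from ilee.core_io import VoxelGeometry

from .conftest import grid2d, grid3d

SQRT2 = math.sqrt(2.0)


def edge_sel(mask):
    return EdgeSelection(mask=np.asarray(mask, dtype=bool), g_thres=0.0)


class TestLaplacian:
    def test_three_pixel_chain(self):
        L = build_laplacian((1, 3), "2d4").toarray()
        np.testing.assert_allclose(L, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    @pytest.mark.parametrize("shape,mode", [((5, 7), "2d4"), ((5, 7), "2d8"), ((3, 4, 5), "3d6")])
    def test_annihilates_constants(self, shape, mode):
        L = build_laplacian(shape, mode)
        np.testing.assert_allclose(L @ np.full(int(np.prod(shape)), 3.7), 0.0, atol=1e-12)

    def test_interior_row_2d8_weights(self):
        shape = (5, 5)
        L = build_laplacian(shape, "2d8").toarray()
        i = np.ravel_multi_index((2, 2), shape)
        assert L[i, i] == pytest.approx(4 + 2 * SQRT2)
        assert L[i, np.ravel_multi_index((2, 3), shape)] == pytest.approx(-1.0)
        assert L[i, np.ravel_multi_index((3, 3), shape)] == pytest.approx(-SQRT2 / 2)

    def test_symmetric_with_nonpositive_offdiagonals(self):
        L = build_laplacian((4, 6), "2d8")
        assert (abs(L - L.T) > 1e-12).nnz == 0
        dense = L.toarray()
        off = dense - np.diag(np.diag(dense))
        assert (off <= 1e-12).all()

    def test_border_rows_sum_to_zero(self):
        for mode, shape in (("2d8", (4, 5)), ("3d6", (3, 3, 3))):
            L = build_laplacian(shape, mode)
            np.testing.assert_allclose(np.asarray(L.sum(axis=1)).ravel(), 0.0, atol=1e-12)

    def test_positive_semidefinite_with_selection(self, rng):
        from scipy import sparse

        shape = (6, 6)
        L = build_laplacian(shape, "2d8")
        sel = np.zeros(36)
        sel[7] = 1.0
        A = (sparse.diags(sel) + 2.5 * L).toarray()
        x = rng.normal(size=36)
        assert x @ A @ x > 0


class TestSolve:
    @pytest.mark.parametrize("shape", [(64, 64), (16, 16, 16)])
    def test_constant_image_fixed_point(self, shape, rng):
        c = 37.5
        grid = grid2d(np.full(shape, c)) if len(shape) == 2 else grid3d(np.full(shape, c))
        sel = rng.random(shape) < 0.05
        sel.flat[0] = True
        for k in (0.5, 2.5, 100.0):
            x = solve_threshold_surface(grid, edge_sel(sel), k)
            np.testing.assert_allclose(x.values, c, atol=1e-8)

    def test_three_pixel_chain_hand_solve(self):
        grid = grid2d([[6.0, 0.0, 0.0]])
        x = solve_threshold_surface(
            grid, edge_sel([[True, False, False]]), 1.0, ILEEParams(connectivity_2d=4)
        )
        np.testing.assert_allclose(x.values, [[6.0, 6.0, 6.0]], atol=1e-9)

    def test_small_k_pins_anchors(self, rng):
        v = rng.normal(100, 20, size=(16, 16))
        sel = np.zeros((16, 16), dtype=bool)
        sel[4, 4] = sel[11, 9] = True
        x = solve_threshold_surface(grid2d(v), edge_sel(sel), 1e-6)
        assert abs(x.values[4, 4] - v[4, 4]) < 1e-3
        assert abs(x.values[11, 9] - v[11, 9]) < 1e-3

    def test_smoothing_range_monotone_in_k(self, rng):
        v = rng.normal(100, 20, size=(32, 32))
        sel = rng.random((32, 32)) < 0.1
        sel[0, 0] = True
        spans = []
        for k in (0.1, 1.0, 10.0, 100.0, 1000.0):
            x = solve_threshold_surface(grid2d(v), edge_sel(sel), k).values
            spans.append(x.max() - x.min())
        assert all(a >= b - 1e-9 for a, b in zip(spans, spans[1:]))

    def test_empty_selection_is_background(self):
        x = solve_threshold_surface(grid2d(np.ones((4, 4))), edge_sel(np.zeros((4, 4))), 2.5)
        assert np.isinf(x.values).all()

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            solve_threshold_surface(grid2d(np.ones((4, 4))), edge_sel(np.ones((4, 4))), 0.0)


class TestDifferenceAndDenoise:
    def test_identical_images_zero(self):
        g = grid2d(np.random.default_rng(0).normal(size=(8, 8)))
        out = difference_and_denoise(g, g)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_isolated_positives_reset_to_negative_mean(self):
        dif = np.full((6, 6), -5.0)
        dif[1, 1] = 3.0
        dif[4, 4] = 2.0
        pre = grid2d(dif)
        thres = grid2d(np.zeros((6, 6)))
        out = difference_and_denoise(pre, thres)
        assert out[1, 1] == pytest.approx(-5.0)
        assert out[4, 4] == pytest.approx(-5.0)

    def test_three_pixel_run_retained(self):
        dif = np.full((5, 7), -1.0)
        dif[2, 2:5] = 4.0
        out = difference_and_denoise(grid2d(dif), grid2d(np.zeros((5, 7))))
        np.testing.assert_allclose(out[2, 2:5], 4.0)

    def test_no_negative_fallback_zero(self):
        dif = np.zeros((5, 5))
        dif[2, 2] = 1.0
        out = difference_and_denoise(grid2d(dif), grid2d(np.zeros((5, 5))))
        assert out[2, 2] == 0.0


class TestBinarize:
    def test_all_negative_gives_empty_masks(self):
        masks = binarize(np.full((8, 8), -2.0), VoxelGeometry(1.0))
        assert not masks["native"].values.any()
        assert not masks["oversampled"].values.any()

    def test_native_sign_pattern_exact(self, rng):
        dif = rng.normal(size=(10, 10))
        masks = binarize(dif, VoxelGeometry(1.0))
        np.testing.assert_array_equal(masks["native"].values, dif > 0)

    def test_oversampled_plateau_area(self):
        dif = np.full((20, 20), -1.0)
        dif[5:15, 5:15] = 1.0
        masks = binarize(dif, VoxelGeometry(1.0))
        native_n = masks["native"].values.sum()
        ovsp_n = masks["oversampled"].values.sum()
        # 9x the native count up to a +-1-pixel interpolation ring
        perimeter_ring = 4 * (10 * 3 + 3)
        assert abs(ovsp_n - 9 * native_n) <= perimeter_ring

    def test_3d_produces_cubic_mask(self):
        dif = np.full((10, 8, 8), -1.0)
        dif[4:6, 2:6, 2:6] = 1.0
        masks = binarize(dif, VoxelGeometry(u_xy=0.132, u_z=0.5))
        assert masks["cubic"].provenance == "cubic"
        assert masks["cubic"].shape[0] == round(10 / 0.264)


class TestK2:
    def test_bar_dt_statistic(self):
        # a bar of half-width 6 dominating the frame (window ~33 at l=400)
        img = np.full((400, 400), 50.0)
        img[:, 194:206] = 3000.0
        stat = niblack_top_dt(grid2d(img))
        assert stat == pytest.approx(6.0, abs=1.0)

    def test_model_monotone_thicker_thicker(self):
        thin = np.full((400, 400), 50.0)
        thin[:, 198:202] = 3000.0
        thick = np.full((400, 400), 50.0)
        thick[:, 190:210] = 3000.0
        k2_thin = estimate_k2([grid2d(thin)], k1=0.0)
        k2_thick = estimate_k2([grid2d(thick)], k1=0.0)
        assert k2_thick > k2_thin

    def test_batch_of_identical_images(self):
        img = np.full((64, 64), 50.0)
        img[:, 28:36] = 3000.0
        one = estimate_k2([grid2d(img)])
        three = estimate_k2([grid2d(img)] * 3)
        assert one == pytest.approx(three)

    def test_k2_floor_at_k1(self):
        img = np.full((64, 64), 50.0)
        img[:, 31:33] = 3000.0
        assert estimate_k2([grid2d(img)], k1=500.0) == 500.0

    def test_k2_model_is_exponential_in_statistic(self):
        m = K2Model(a=0.0, b=0.5)
        assert m(2.0) == pytest.approx(10.0)
        assert m(4.0) == pytest.approx(100.0)


class TestRunILEE:
    def test_constant_image_empty_masks(self):
        res = run_ilee(grid2d(np.full((32, 32), 120.0)), mode="2d", params=ILEEParams(k2=5.0))
        assert not res.masks["native"].values.any()

    def test_union_superset_of_each_k(self, small_artificial):
        grid, _, _ = small_artificial
        res = run_ilee(grid, mode="3d", params=ILEEParams(), ks=(2.5, 20.0))
        union = res.masks["native"].values
        for k, masks in res.per_k_masks.items():
            assert not (masks["native"].values & ~union).any()

    def test_deterministic_rerun_bit_identical(self, small_artificial):
        grid, _, _ = small_artificial
        from ilee import max_project

        proj = max_project(grid)
        a = run_ilee(proj, mode="2d", params=ILEEParams(k2=5.0))
        b = run_ilee(proj, mode="2d", params=ILEEParams(k2=5.0))
        np.testing.assert_array_equal(a.masks["native"].values, b.masks["native"].values)
        np.testing.assert_array_equal(a.masks["oversampled"].values, b.masks["oversampled"].values)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            ILEEParams(k1=-1.0)
        with pytest.raises(ValueError):
            ILEEParams(k1=5.0, k2=1.0)
        with pytest.raises(ValueError):
            ILEEParams(connectivity_2d=5)
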