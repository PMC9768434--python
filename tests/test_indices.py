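"""Skeleton graph and the 12 cytoskeletal indices."""

import math

import numpy as np
import pytest
from scipy import ndimage

from ilee import BinaryMask, VoxelGeometry, compute_indices, extract_graph, local_anisotropy, skeletonize
from ilee.indices import (
    Branch,
    SkeletonGraph,
    bundling_indices,
    connectivity_branching_indices,
    density_indices,
    kernel_length_2d,
)

from .conftest import grid2d


def mask2d(values, u_xy=1.0, provenance="native"):
    return BinaryMask(values=np.asarray(values, dtype=bool), geometry=VoxelGeometry(u_xy), provenance=provenance)


def graph_from_pixels(pixels, shape):
    skel = np.zeros(shape, dtype=bool)
    for p in pixels:
        skel[p] = True
    return extract_graph(skel)


class TestSkeletonGraph:
    def test_solid_bar_single_path(self):
        bar = np.zeros((9, 204), dtype=bool)
        bar[2:7, 2:202] = True
        g = skeletonize(mask2d(bar))
        assert g.components == 1
        assert g.n_branches == 1
        degs = sorted(g.node_degrees.values())
        assert degs == [1, 1]
        assert g.total_length == pytest.approx(199.0, abs=6.0)

    def test_empty_mask(self):
        g = skeletonize(mask2d(np.zeros((10, 10))))
        assert g.n_branches == 0
        assert g.n_nodes == 0
        assert g.total_length == 0.0

    def test_plus_cross_graph(self):
        skel = np.zeros((11, 11), dtype=bool)
        skel[5, :] = True
        skel[:, 5] = True
        g = extract_graph(skel)
        assert g.n_branches == 4
        assert 4 in g.node_degrees.values()
        assert sum(1 for d in g.node_degrees.values() if d == 1) == 4
        assert g.components == 1

    def test_isolated_cycle(self):
        # diamond ring: every pixel has exactly two (diagonal) neighbours
        skel = np.zeros((9, 9), dtype=bool)
        for y in range(9):
            for x in range(9):
                if abs(y - 4) + abs(x - 4) == 3:
                    skel[y, x] = True
        g = extract_graph(skel)
        assert g.components == 1
        assert g.n_branches == 1
        assert g.total_length == pytest.approx(12 * math.sqrt(2.0))

    def test_two_components(self):
        skel = np.zeros((10, 10), dtype=bool)
        skel[1, 1:5] = True
        skel[7, 2:9] = True
        g = extract_graph(skel)
        assert g.components == 2
        assert g.n_branches == 2


class TestKernelLength:
    def test_horizontal_run(self):
        skel = np.zeros((10, 10), dtype=bool)
        skel[4, 2:7] = True
        assert kernel_length_2d(skel) == pytest.approx(4.0)

    def test_diagonal_run(self):
        skel = np.zeros((6, 6), dtype=bool)
        for i in range(3):
            skel[i + 1, i + 1] = True
        assert kernel_length_2d(skel) == pytest.approx(2 * math.sqrt(2.0))


class TestDensity:
    def test_occupancy_fraction(self):
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = m[1, 1] = m[2, 2] = m[3, 3] = True
        native = mask2d(m)
        skel = extract_graph(np.zeros((4, 4), dtype=bool))
        occ, _, _ = density_indices(native, native, skel, "2d")
        assert occ == 0.25

    def test_linear_density_horizontal_run(self):
        native = mask2d(np.zeros((10, 10), dtype=bool))
        skel = np.zeros((10, 10), dtype=bool)
        skel[4, 2:7] = True
        g = extract_graph(skel)
        work = mask2d(skel, u_xy=1.0, provenance="oversampled")
        occ, length, dens = density_indices(native, work, g, "2d")
        assert length == pytest.approx(4.0)
        assert dens == pytest.approx(0.04)


class TestBundling:
    def test_symmetric_intensities_zero_skew(self):
        raw = grid2d([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        native = mask2d([[1, 1, 1], [0, 0, 0], [0, 0, 0]])
        skel = extract_graph(np.zeros((3, 3), dtype=bool))
        skew, cv, _, _ = bundling_indices(raw, native, native, skel)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_moment_arithmetic(self):
        raw = grid2d([[1.0, 1.0], [1.0, 5.0]])
        native = mask2d([[1, 1], [1, 1]])
        skel = extract_graph(np.zeros((2, 2), dtype=bool))
        skew, cv, _, _ = bundling_indices(raw, native, native, skel)
        assert skew == pytest.approx(1.1547, abs=1e-4)
        assert cv == pytest.approx(0.8660, abs=1e-4)

    def test_constant_positives(self):
        raw = grid2d(np.full((3, 3), 9.0))
        native = mask2d(np.ones((3, 3)))
        skel = extract_graph(np.zeros((3, 3), dtype=bool))
        skew, cv, _, _ = bundling_indices(raw, native, native, skel)
        assert skew == 0.0
        assert cv == 0.0

    def test_bar_diameters_match_brute_force(self):
        w = 9
        bar = np.zeros((w + 6, 120), dtype=bool)
        bar[3 : 3 + w, 5:115] = True
        work = mask2d(bar, provenance="oversampled")
        graph = skeletonize(work)
        raw = grid2d(np.where(bar, 100.0, 0.0))
        _, _, tdt, sdt = bundling_indices(raw, work, work, graph)
        dt = ndimage.distance_transform_edt(bar)
        assert tdt == pytest.approx(4.0 * dt[bar].mean(), abs=1e-9)
        assert sdt == pytest.approx(2.0 * dt[graph.skeleton].mean(), abs=1e-9)

    def test_too_few_positives_flagged_nan(self):
        raw = grid2d(np.zeros((3, 3)))
        native = mask2d([[1, 0, 0], [0, 0, 0], [0, 0, 0]])
        skel = extract_graph(np.zeros((3, 3), dtype=bool))
        out = bundling_indices(raw, native, native, skel)
        assert all(math.isnan(v) for v in out)


class TestConnectivityBranching:
    def test_two_disjoint_segments(self):
        skel = np.zeros((20, 20), dtype=bool)
        skel[2, 2:13] = True  # kernel length 10
        skel[10, 3:9] = True  # kernel length 5
        g = extract_graph(skel)
        tce, seg_density, tb, tn, sba = connectivity_branching_indices(g, mask2d(skel), 15.0)
        assert tce == 2
        assert seg_density == pytest.approx(2 / 15)
        assert sba == 0.0

    def test_plus_cross_branching_activity(self):
        skel = np.zeros((11, 11), dtype=bool)
        skel[5, :] = True
        skel[:, 5] = True
        g = extract_graph(skel)
        _, _, tb, tn, sba = connectivity_branching_indices(g, None, 20.0)
        assert tb == 4
        assert sba == pytest.approx(4 / 20.0)

    def test_single_segment_no_branching(self):
        skel = np.zeros((10, 10), dtype=bool)
        skel[3, 1:9] = True
        g = extract_graph(skel)
        _, _, _, _, sba = connectivity_branching_indices(g, None, 7.0)
        assert sba == 0.0

    def test_zero_length_flagged(self):
        g = extract_graph(np.zeros((5, 5), dtype=bool))
        tce, seg_density, _, _, sba = connectivity_branching_indices(g, None, 0.0)
        assert math.isnan(seg_density) and math.isnan(sba)


class TestLocalAnisotropy:
    def test_parallel_chords_fully_anisotropic(self):
        skel = np.zeros((40, 40), dtype=bool)
        for r in (10, 20, 30):
            skel[r, 5:35] = True
        g = extract_graph(skel)
        value, probes = local_anisotropy(g, radius=25.0)
        assert value == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_families_isotropic(self):
        branches = []
        for i in range(10):
            path_h = np.array([[20.0, 5.0 + i], [20.0, 10.0 + i]])
            path_v = np.array([[5.0 + i, 20.0], [10.0 + i, 20.0]])
            branches.append(Branch(path=path_h, length=5.0, node_start=0, node_end=0))
            branches.append(Branch(path=path_v, length=5.0, node_start=0, node_end=0))
        g = SkeletonGraph(
            skeleton=np.zeros((40, 40), dtype=bool),
            branches=branches,
            node_degrees={0: 1},
            node_is_junction={0: False},
            components=20,
            total_length=100.0,
        )
        value, _ = local_anisotropy(g, radius=100.0, chord_len=5)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_random_orientations_tend_isotropic(self):
        rng = np.random.default_rng(3)
        branches = []
        for _ in range(500):
            theta = rng.uniform(0, np.pi)
            p0 = rng.uniform(10, 90, size=2)
            d = np.array([np.cos(theta), np.sin(theta)])
            branches.append(Branch(path=np.array([p0, p0 + 5 * d]), length=5.0, node_start=0, node_end=0))
        g = SkeletonGraph(
            skeleton=np.zeros((100, 100), dtype=bool),
            branches=branches,
            node_degrees={0: 1},
            node_is_junction={0: False},
            components=500,
            total_length=2500.0,
        )
        value, _ = local_anisotropy(g, radius=300.0)
        assert value < 0.1

    def test_empty_graph_nan(self):
        g = extract_graph(np.zeros((5, 5), dtype=bool))
        value, probes = local_anisotropy(g)
        assert math.isnan(value)
        assert probes == []


class TestComputeIndices:
    def test_rotation_robust_linear_density(self):
        def run(angle_deg):
            n = 129
            m = np.zeros((n, n), dtype=bool)
            c = n // 2
            t = np.linspace(-50, 50, 4001)
            a = math.radians(angle_deg)
            ys = np.rint(c + t * math.sin(a)).astype(int)
            xs = np.rint(c + t * math.cos(a)).astype(int)
            for y, x in zip(ys, xs):
                for dy in (-2, -1, 0, 1, 2):
                    for dx in (-2, -1, 0, 1, 2):
                        if 0 <= y + dy < n and 0 <= x + dx < n and dy * dy + dx * dx <= 4:
                            m[y + dy, x + dx] = True
            work = mask2d(m, provenance="oversampled")
            g = skeletonize(work)
            return kernel_length_2d(g.skeleton)

        lengths = [run(a) for a in (0, 30, 45)]
        # 8-connected digital length overestimates oblique lines by up to
        # (cos + (sqrt(2)-1) sin)/1 ~ 7-8% at intermediate angles
        assert max(lengths) / min(lengths) < 1.08

    def test_full_report_on_scene(self, small_artificial):
        from ilee import ILEEParams, run_ilee

        grid, truth, t = small_artificial
        res = run_ilee(grid, mode="3d", params=ILEEParams(), ks=(2.5, 10.0))
        rep = compute_indices(res.raw, res.masks, "3d")
        assert 0 <= rep.occupancy <= 1
        assert rep.occupancy == pytest.approx(t["occupancy"], rel=0.4)
        assert rep.cv >= 0
        assert 0 <= rep.local_anisotropy <= 1
        assert rep.diameter_tdt > 0
        assert rep.provenance["skeleton"] == "cubic"

    def test_intensity_scaling_invariance(self, small_artificial):
        from ilee import VoxelGrid

        grid, truth, _ = small_artificial
        g = skeletonize(truth)
        skew1, cv1, tdt1, sdt1 = bundling_indices(grid, truth, truth, g)
        scaled = VoxelGrid(values=grid.values * 3.0, geometry=grid.geometry, bit_depth=16)
        skew2, cv2, tdt2, sdt2 = bundling_indices(scaled, truth, truth, g)
        # skewness and CV are invariant under pure intensity scaling;
        # the DT diameters depend only on the mask
        assert skew2 == pytest.approx(skew1, abs=1e-9)
        assert cv2 == pytest.approx(cv1, abs=1e-9)
        assert tdt2 == tdt1 and sdt2 == sdt1

    def test_empty_mask_report(self):
        raw = grid2d(np.zeros((8, 8)))
        masks = {
            "native": mask2d(np.zeros((8, 8))),
            "oversampled": mask2d(np.zeros((24, 24)), u_xy=1 / 3, provenance="oversampled"),
        }
        rep = compute_indices(raw, masks, "2d")
        assert rep.occupancy == 0.0
        assert math.isnan(rep.linear_density)
        assert rep.flags
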