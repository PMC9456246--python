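"""Unit and property tests for the detection operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from breakfish.segmentation import (
    NucleusDetectConfig,
    _cylinder_objective,
    despeckle,
    detect_nuclei,
    detect_objects,
    fit_cylinder,
    size_filter,
)
from breakfish.stack import VoxelStack

from conftest import make_cylinder_stack

SPACING = (400.0, 200.0, 200.0)


class TestDespeckle:
    def test_constant_stack_unchanged(self):
        stack = VoxelStack(np.full((5, 4, 4), 7.0), SPACING)
        out = despeckle(stack)
        assert np.array_equal(out.values, stack.values)

    @pytest.mark.parametrize(
        "column, expected_center",
        [((0.0, 9.0, 0.0), 0.0), ((5.0, 5.0, 9.0), 5.0)],
    )
    def test_z_median_examples(self, column, expected_center):
        arr = np.zeros((3, 3, 3))
        arr[:, 1, 1] = column
        out = despeckle(VoxelStack(arr, SPACING))
        assert out.values[1, 1, 1] == expected_center

    def test_too_few_planes_warns_and_passes_through(self):
        stack = VoxelStack(np.ones((2, 4, 4)), SPACING)
        with pytest.warns(UserWarning):
            out = despeckle(stack)
        assert np.array_equal(out.values, stack.values)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_range_contained_and_speckle_suppressed(self, seed):
        rng = np.random.default_rng(seed)
        arr = rng.uniform(0, 100, (8, 6, 6))
        z, y, x = rng.integers(1, 7), rng.integers(0, 6), rng.integers(0, 6)
        arr[z, y, x] = 1000.0  # isolated speckle flanked by dimmer z-neighbors
        out = despeckle(VoxelStack(arr, SPACING)).values
        assert out.min() >= arr.min() and out.max() <= arr.max()
        assert out[z, y, x] <= max(arr[z - 1, y, x], arr[z + 1, y, x])


class TestFitCylinder:
    def test_indicator_cylinder_is_objective_optimum_on_grid(self):
        stack = make_cylinder_stack(radius=10.0, z_range=(4, 11))
        truth = (32.0, 32.0, 10.0, 4, 11)
        best, _, _ = _cylinder_objective(stack.values, *truth, beta=0.5)
        for dcy in (-2.0, 0.0, 2.0):
            for dr in (-2.0, 0.0, 2.0):
                for dz in (-2, 0, 2):
                    params = (32.0 + dcy, 32.0, 10.0 + dr, max(4 + dz, 0), 11)
                    obj, _, _ = _cylinder_objective(stack.values, *params, beta=0.5)
                    assert obj <= best + 1e-9

    def test_recovers_noise_free_cylinder(self):
        stack = make_cylinder_stack(radius=10.0, z_range=(4, 11), brightness=100.0)
        model = fit_cylinder(stack, (7, 32, 32))
        assert abs(model.center_xy[0] - 32) <= 1 and abs(model.center_xy[1] - 32) <= 1
        assert abs(model.radius - 10) <= 1.0  # within 10%
        assert model.z_range == (4, 11)
        assert model.stable

    def test_single_bright_voxel_gives_minimal_cylinder(self):
        arr = np.zeros((9, 21, 21))
        arr[4, 10, 10] = 50.0
        model = fit_cylinder(VoxelStack(arr, SPACING), (4, 10, 10))
        cfg = NucleusDetectConfig()
        assert model.radius == pytest.approx(cfg.min_radius, abs=0.5)
        assert model.z_range == (4, 4)

    def test_uniform_image_flagged_unstable(self):
        arr = np.full((8, 24, 24), 10.0)
        model = fit_cylinder(VoxelStack(arr, SPACING), (4, 12, 12))
        assert not model.stable

    def test_non_finite_rejected(self):
        arr = np.ones((4, 8, 8))
        arr[1, 1, 1] = np.nan
        with pytest.raises(ValueError):
            fit_cylinder(VoxelStack(arr, SPACING), (0, 0, 0))


class TestDetectNuclei:
    def test_empty_stack_gives_no_nuclei(self):
        assert detect_nuclei(VoxelStack(np.zeros((8, 32, 32)), SPACING)) == []

    def test_single_cylinder_recovered(self):
        stack = make_cylinder_stack(
            shape=(16, 64, 64), center_yx=(30.0, 34.0), radius=10.0, z_range=(4, 11)
        )
        cfg = NucleusDetectConfig(min_voxels=100)
        nuclei = detect_nuclei(stack, cfg)
        assert len(nuclei) == 1
        (model,) = nuclei
        assert abs(model.center_xy[0] - 30) <= 1 and abs(model.center_xy[1] - 34) <= 1
        assert abs(model.radius - 10) / 10 <= 0.10

    def test_two_separated_cylinders(self):
        a = make_cylinder_stack(shape=(16, 96, 96), center_yx=(30.0, 30.0), radius=9.0)
        b = make_cylinder_stack(shape=(16, 96, 96), center_yx=(66.0, 66.0), radius=9.0)
        stack = VoxelStack(a.values + b.values, SPACING)
        nuclei = detect_nuclei(stack, NucleusDetectConfig(min_voxels=100))
        assert len(nuclei) == 2
        centers = sorted((m.center_xy for m in nuclei))
        for got, want in zip(centers, [(30, 30), (66, 66)]):
            assert abs(got[0] - want[0]) <= 1 and abs(got[1] - want[1]) <= 1

    def test_termination_on_noise(self):
        rng = np.random.default_rng(0)
        stack = VoxelStack(rng.uniform(0, 1, (8, 48, 48)), SPACING)
        nuclei = detect_nuclei(stack, NucleusDetectConfig(max_nuclei=50))
        assert isinstance(nuclei, list)  # loop terminated


def _add_gauss_spot(arr, center_zyx, sigma_vox, amp):
    nz, ny, nx = arr.shape
    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    cz, cy, cx = center_zyx
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    arr += amp * np.exp(-d2 / (2 * sigma_vox**2))


class TestDetectObjects:
    def _nucleus(self):
        from breakfish.stack import NucleusModel

        return NucleusModel(center_xy=(20.0, 20.0), radius=15.0, z_range=(2, 13))

    def test_single_spot_one_component_centroid_close(self):
        arr = np.zeros((16, 41, 41))
        _add_gauss_spot(arr, (8, 18, 22), 1.2, 1000.0)
        objs = detect_objects(VoxelStack(arr, SPACING), self._nucleus(), "locus", top_k=40)
        assert len(objs) == 1
        w = objs[0].weights
        centroid = (objs[0].voxels * w[:, None]).sum(axis=0) / w.sum()
        assert np.all(np.abs(centroid - np.array([8, 18, 22])) <= 1.0)

    def test_two_spots_two_components(self):
        arr = np.zeros((16, 41, 41))
        _add_gauss_spot(arr, (5, 12, 12), 1.2, 1000.0)
        _add_gauss_spot(arr, (10, 28, 28), 1.2, 1000.0)
        objs = detect_objects(VoxelStack(arr, SPACING), self._nucleus(), "locus", top_k=60)
        assert len(objs) == 2

    def test_top_k_zero_gives_empty(self):
        arr = np.ones((16, 41, 41))
        assert detect_objects(VoxelStack(arr, SPACING), self._nucleus(), "locus", top_k=0) == []

    def test_top_k_exceeding_nucleus_warns(self):
        arr = np.ones((16, 41, 41))
        with pytest.warns(UserWarning):
            detect_objects(VoxelStack(arr, SPACING), self._nucleus(), "locus", top_k=10**7)

    def test_components_are_maximal_vs_flood_fill(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(0, 100, (10, 41, 41))
        objs = detect_objects(VoxelStack(arr, SPACING), self._nucleus(), "locus", top_k=60)
        selected = set()
        for o in objs:
            selected |= o.voxel_set()
        assert sum(o.n_voxels for o in objs) == len(selected)
        # brute-force flood fill over the selected set (26-connectivity)
        seen: set = set()
        comps = []
        for start in sorted(selected):
            if start in seen:
                continue
            stack_, comp = [start], set()
            while stack_:
                v = stack_.pop()
                if v in comp:
                    continue
                comp.add(v)
                z, y, x = v
                for ddz in (-1, 0, 1):
                    for ddy in (-1, 0, 1):
                        for ddx in (-1, 0, 1):
                            nb = (z + ddz, y + ddy, x + ddx)
                            if nb != v and nb in selected and nb not in comp:
                                stack_.append(nb)
            seen |= comp
            comps.append(comp)
        assert sorted(map(sorted, comps)) == sorted(
            sorted(o.voxel_set()) for o in objs
        )

    def test_territory_mode_blurs_before_selection(self):
        arr = np.zeros((16, 41, 41))
        arr[8, 20, 20] = 10000.0  # a delta: after blur, neighbors join the component
        objs = detect_objects(VoxelStack(arr, SPACING), self._nucleus(), "territory", top_k=30)
        assert len(objs) == 1 and objs[0].n_voxels == 30


class TestSizeFilter:
    def _obj(self, n):
        vox = np.array([[0, 0, i] for i in range(n)])
        from breakfish.stack import DetectedObject

        return DetectedObject(vox, np.ones(n))

    def test_enumerated_sizes(self):
        objs = [self._obj(1), self._obj(5), self._obj(500)]
        kept = size_filter(objs, 2, 100)
        assert [o.n_voxels for o in kept] == [5]

    def test_identity_bounds(self):
        objs = [self._obj(1), self._obj(5)]
        assert size_filter(objs, 1, np.inf) == objs

    def test_single_voxel_removed_at_min_two(self):
        assert size_filter([self._obj(1)], 2, 10) == []

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            size_filter([], 5, 2)
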