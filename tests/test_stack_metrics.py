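"""Structure-factor computations against brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biodisperse.stack_metrics import (
    BiofilmStructure,
    ThicknessMap,
    VoxelStack,
    binarize,
    biovolume,
    filter_small_components,
    mean_thickness,
    quantify_stack,
    roughness_coefficient,
    surface_area,
    surface_to_biovolume,
    thickness_map,
    total_biomass,
)
from conftest import brute_biovolume, brute_surface_area, brute_thickness, random_stack


def make_tm(values, include_all=True):
    L = np.asarray(values, dtype=float).reshape(1, -1)
    inc = np.ones_like(L, dtype=bool) if include_all else L > 0
    return ThicknessMap(L=L, included=inc, n=int(inc.sum()),
                        mean=float(L[inc].mean()))


class TestBinarize:
    def test_fixed_threshold_separates_two_level_stack(self):
        arr = np.zeros((3, 4, 4))
        arr[1, 1:3, 1:3] = 100.0
        vs = binarize(arr, method="fixed", threshold=50)
        assert np.array_equal(vs.mask, arr == 100.0)

    def test_all_zero_stack_fixed_threshold_gives_empty_mask(self):
        vs = binarize(np.zeros((2, 3, 3)), method="fixed", threshold=0.5)
        assert vs.mask.sum() == 0

    def test_otsu_matches_exhaustive_intraclass_variance_search(self):
        rng = np.random.default_rng(7)
        arr = np.concatenate([rng.normal(30, 5, 4000), rng.normal(120, 10, 4000)])
        arr = np.clip(arr, 0, None).reshape(20, 20, 20)
        vs = binarize(arr, method="otsu")
        # brute-force Otsu: minimize within-class weighted variance over bins
        hist, edges = np.histogram(arr.ravel(), bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        best, best_t = np.inf, None
        for i in range(1, 256):
            w0, w1 = hist[:i].sum(), hist[i:].sum()
            if w0 == 0 or w1 == 0:
                continue
            m0 = (hist[:i] * centers[:i]).sum() / w0
            m1 = (hist[i:] * centers[i:]).sum() / w1
            v0 = (hist[:i] * (centers[:i] - m0) ** 2).sum() / w0
            v1 = (hist[i:] * (centers[i:] - m1) ** 2).sum() / w1
            wcv = w0 * v0 + w1 * v1
            if wcv < best:
                best, best_t = wcv, centers[i - 1]
        oracle = binarize(arr, method="fixed", threshold=best_t)
        # thresholds from the two routes classify voxels identically
        assert np.array_equal(vs.mask, oracle.mask)

    def test_constant_stack_otsu_errors(self):
        with pytest.raises(ValueError, match="bimodal"):
            binarize(np.full((2, 2, 2), 7.0), method="otsu")

    def test_negative_intensity_errors(self):
        with pytest.raises(ValueError, match="negative"):
            binarize(np.array([[[-1.0]]]), method="fixed", threshold=0)


class TestVolumeAndBiomass:
    def test_empty_mask_zero(self):
        vs = VoxelStack(np.zeros((3, 4, 4), dtype=bool))
        assert biovolume(vs) == 0
        assert total_biomass(vs) == 0

    def test_full_block_volume(self):
        vs = VoxelStack(np.ones((3, 4, 4), dtype=bool))
        assert biovolume(vs) == pytest.approx(48.0)

    def test_slab_biomass_equals_height_regardless_of_footprint(self):
        for n in (4, 9):
            vs = VoxelStack(np.ones((10, n, n), dtype=bool), dz=0.5)
            assert total_biomass(vs) == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_count(self, seed):
        vs = random_stack(seed, shape=(10, 20, 20), p=0.3, dz=0.7)
        assert biovolume(vs) == pytest.approx(brute_biovolume(vs))
        assert total_biomass(vs) == pytest.approx(
            brute_biovolume(vs) / vs.substratum_area)


class TestThickness:
    def test_full_slab_uniform(self):
        vs = VoxelStack(np.ones((6, 3, 3), dtype=bool))
        tm = thickness_map(vs)
        assert np.all(tm.L == 6.0)
        assert mean_thickness(tm) == 6.0

    def test_interior_void_ignored(self):
        mask = np.zeros((6, 1, 1), dtype=bool)
        mask[0, 0, 0] = mask[4, 0, 0] = True  # occupied at z=0 and z=4 only
        tm = thickness_map(VoxelStack(mask))
        assert tm.L[0, 0] == 5.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_column_scan(self, seed):
        vs = random_stack(seed, shape=(8, 12, 12), p=0.4, dz=1.3)
        tm = thickness_map(vs)
        assert np.allclose(tm.L, brute_thickness(vs))

    def test_exclude_empty_policy_changes_n(self):
        mask = np.zeros((4, 2, 2), dtype=bool)
        mask[:2, 0, 0] = True
        inc = thickness_map(VoxelStack(mask), include_empty=True)
        exc = thickness_map(VoxelStack(mask), include_empty=False)
        assert inc.n == 4 and exc.n == 1
        assert mean_thickness(exc) == 2.0 and mean_thickness(inc) == 0.5

    def test_exclude_empty_on_empty_stack_errors(self):
        with pytest.raises(ValueError, match="no biomass"):
            thickness_map(VoxelStack(np.zeros((2, 2, 2), dtype=bool)),
                          include_empty=False)


class TestRoughness:
    def test_uniform_film_zero(self):
        assert roughness_coefficient(make_tm([6, 6, 6, 6])) == 0.0

    def test_half_covered_binary_film(self):
        # half the columns at 2 um, half empty: mean 1, Ra* = 1
        assert roughness_coefficient(make_tm([2, 2, 0, 0])) == pytest.approx(1.0)

    def test_direct_formula_example(self):
        assert roughness_coefficient(make_tm([1, 2, 3, 4])) == pytest.approx(0.4)

    def test_mean_values(self):
        assert mean_thickness(make_tm([1, 2, 3, 4])) == pytest.approx(2.5)
        assert mean_thickness(make_tm([2, 2, 0, 0])) == pytest.approx(1.0)

    def test_empty_film_undefined(self):
        with pytest.raises(ValueError, match="roughness undefined"):
            roughness_coefficient(make_tm([0.0, 0.0]))

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=50))
    @settings(deadline=None)
    def test_bounded_by_two_and_zero_iff_uniform(self, values):
        if sum(values) <= 0:
            return
        ra = roughness_coefficient(make_tm(values))
        assert 0 <= ra <= 2
        if len(set(values)) == 1:
            assert ra == pytest.approx(0.0, abs=1e-12)

    def test_approaches_binary_film_bound(self):
        # binary-height film: Ra* = 2(1 - coverage)
        for cov in (0.1, 0.25, 0.5, 0.9):
            n = 200
            k = int(round(cov * n))
            vals = [5.0] * k + [0.0] * (n - k)
            assert roughness_coefficient(make_tm(vals)) == pytest.approx(
                2 * (1 - k / n))


class TestSurfaceArea:
    def test_single_voxel_on_substratum(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 1, 1] = True
        assert surface_area(VoxelStack(mask)) == pytest.approx(5.0)
        assert surface_to_biovolume(VoxelStack(mask)) == pytest.approx(5.0)

    def test_solid_slab_only_top_exposed(self, slab):
        assert surface_area(slab) == pytest.approx(64.0)
        assert surface_to_biovolume(slab) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_six_neighbor_scan(self, seed):
        vs = random_stack(seed, shape=(6, 10, 10), p=0.35, dx=1.1, dy=0.9, dz=0.5)
        assert surface_area(vs) == pytest.approx(brute_surface_area(vs))

    def test_splitting_a_blob_never_decreases_sbr(self):
        joined = np.zeros((4, 4, 8), dtype=bool)
        joined[:2, 1:3, 1:5] = True  # one 2x2x4 blob
        split = np.zeros((4, 4, 8), dtype=bool)
        split[:2, 1:3, 1:3] = True   # two 2x2x2 blobs, separated
        split[:2, 1:3, 5:7] = True
        assert biovolume(VoxelStack(split)) == biovolume(VoxelStack(joined))
        assert (surface_to_biovolume(VoxelStack(split))
                >= surface_to_biovolume(VoxelStack(joined)))

    def test_empty_mask_sbr_undefined(self):
        with pytest.raises(ValueError, match="SBR undefined"):
            surface_to_biovolume(VoxelStack(np.zeros((2, 2, 2), dtype=bool)))


class TestQuantifyStack:
    def test_solid_slab_closed_forms(self, slab):
        s = quantify_stack(slab)
        assert s == BiofilmStructure(10.0, 0.1, 10.0, 0.0)

    def test_fields_equal_standalone_operations(self):
        vs = random_stack(11, shape=(8, 16, 16), p=0.4)
        s = quantify_stack(vs)
        tm = thickness_map(vs)
        assert s.total_biomass == total_biomass(vs)
        assert s.sbr == surface_to_biovolume(vs)
        assert s.mean_thickness == mean_thickness(tm)
        assert s.roughness == roughness_coefficient(tm)

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError):
            quantify_stack(VoxelStack(np.zeros((2, 2, 2), dtype=bool)))


class TestInvariants:
    def test_translation_and_rotation_invariance(self):
        # blob kept off the lateral boundary: shifting it cannot change
        # which faces touch the (unexposed) stack edge
        rng = np.random.default_rng(5)
        mask = np.zeros((6, 12, 12), dtype=bool)
        mask[:, 2:7, 2:7] = rng.random((6, 5, 5)) < 0.5
        vs = VoxelStack(mask)
        s0 = quantify_stack(vs)
        rolled = VoxelStack(np.roll(vs.mask, (3, 4), axis=(1, 2)))
        rotated = VoxelStack(np.rot90(vs.mask, axes=(1, 2)).copy())
        for other in (rolled, rotated):
            s1 = quantify_stack(other)
            assert s1.total_biomass == pytest.approx(s0.total_biomass)
            assert s1.sbr == pytest.approx(s0.sbr)
            assert s1.mean_thickness == pytest.approx(s0.mean_thickness)
            assert s1.roughness == pytest.approx(s0.roughness)

    def test_hollowing_raises_sbr_and_preserves_thickness(self):
        solid = np.ones((8, 10, 10), dtype=bool)
        hollow = solid.copy()
        hollow[2:6, 2:8, 2:8] = False  # interior cavity below the top
        s_solid, s_hollow = VoxelStack(solid), VoxelStack(hollow)
        assert (surface_to_biovolume(s_hollow) > surface_to_biovolume(s_solid))
        assert np.array_equal(thickness_map(s_hollow).L, thickness_map(s_solid).L)

    @pytest.mark.parametrize("seed", range(4))
    def test_biomass_bounded_by_mean_thickness(self, seed):
        vs = random_stack(seed, shape=(10, 12, 12), p=0.5)
        if biovolume(vs) == 0:
            return
        s = quantify_stack(vs, include_empty=True)
        assert s.total_biomass <= s.mean_thickness + 1e-12


def test_component_filter_removes_small_blobs():
    mask = np.zeros((4, 8, 8), dtype=bool)
    mask[:3, 0:4, 0:4] = True       # 48-voxel blob
    mask[0, 6, 6] = True            # singleton
    out = filter_small_components(VoxelStack(mask), min_volume_um3=2.0)
    assert out.mask.sum() == 48
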