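"""Boundary sets, laminar splitting, slices, resampling, thickness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cartiq import (
    CartilageMask,
    Grid,
    boundary_sets,
    laminar_split,
    regional_thickness,
    resample_mask,
    select_loadbearing_slices,
)
from cartiq.images import LAMINA_DEEP, LAMINA_SUPERFICIAL
from cartiq.phantom import PhantomSpec, generate_phantom

from conftest import make_slab_mask


def brute_force_boundaries(labels2d, region):
    """Exhaustive in-plane 4-adjacency scan."""
    art = np.zeros_like(labels2d, dtype=bool)
    bone = np.zeros_like(labels2d, dtype=bool)
    n_rows, n_cols = labels2d.shape
    for r in range(n_rows):
        for c in range(n_cols):
            if labels2d[r, c] != region:
                continue
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                if labels2d[rr, cc] == 0:
                    art[r, c] = True
                if labels2d[rr, cc] == 1:
                    bone[r, c] = True
    return art, bone


def brute_force_laminae(labels2d, region, s):
    """O(N*M) nearest-boundary comparison, ties superficial."""
    art, bone = brute_force_boundaries(labels2d, region)
    art_pts = np.argwhere(art) * s
    bone_pts = np.argwhere(bone) * s
    codes = np.zeros_like(labels2d, dtype=np.int8)
    for r, c in np.argwhere(labels2d == region):
        p = np.array([r, c]) * s
        d_art = np.min(np.linalg.norm(art_pts - p, axis=1))
        d_bone = np.min(np.linalg.norm(bone_pts - p, axis=1))
        codes[r, c] = LAMINA_SUPERFICIAL if d_art <= d_bone else LAMINA_DEEP
    return codes


class TestBoundarySets:
    def test_slab_top_and_bottom_rows(self, slab_mask):
        mask = slab_mask(k=10)
        art, bone = boundary_sets(mask, 2)
        core = mask.labels == 2
        rows = np.argwhere(core[0])[:, 0]
        top, bottom = rows.min(), rows.max()
        assert art[0, top].all() and art[0].sum() == mask.labels.shape[2]
        assert bone[0, bottom].all() and bone[0].sum() == mask.labels.shape[2]

    def test_single_voxel_sheet_in_both_sets(self, slab_mask):
        mask = slab_mask(k=1)
        art, bone = boundary_sets(mask, 2)
        core = mask.labels == 2
        assert (art[core] & bone[core]).all()

    def test_annulus_matches_exhaustive_scan(self, noiseless_phantom):
        _, _, mask, _ = noiseless_phantom
        art, bone = boundary_sets(mask, 2)
        bf_art, bf_bone = brute_force_boundaries(mask.labels[0], 2)
        np.testing.assert_array_equal(art[0], bf_art)
        np.testing.assert_array_equal(bone[0], bf_bone)

    def test_degenerate_geometry_rejected(self):
        labels = np.zeros((1, 6, 6), dtype=np.int16)
        labels[0, 2:4, 2:4] = 2  # cartilage floating in background, no bone
        with pytest.raises(ValueError, match="bone"):
            boundary_sets(CartilageMask(labels, Grid(0.5, 3.0)), 2)

    def test_absent_region_rejected(self, slab_mask):
        with pytest.raises(ValueError, match="not present"):
            boundary_sets(slab_mask(), 5)


class TestLaminarSplit:
    def test_even_slab_splits_in_half(self, slab_mask):
        mask = slab_mask(k=6)
        lam = laminar_split(mask, 2)
        per_row = [
            set(np.unique(lam.codes[0, r, :]))
            for r in range(mask.labels.shape[1])
            if (mask.labels[0, r] == 2).all()
        ]
        assert per_row == [{1}, {1}, {1}, {2}, {2}, {2}]

    def test_single_row_slab_all_superficial_by_tie_rule(self, slab_mask):
        mask = slab_mask(k=1)
        lam = laminar_split(mask, 2)
        core = mask.labels == 2
        assert (lam.codes[core] == LAMINA_SUPERFICIAL).all()

    def test_partition_is_disjoint_and_exhaustive(self, noiseless_phantom):
        _, _, mask, _ = noiseless_phantom
        lam = laminar_split(mask, 2)
        core = mask.labels == 2
        assert np.isin(lam.codes[core], [LAMINA_SUPERFICIAL, LAMINA_DEEP]).all()
        assert (lam.codes[~core] == 0).all()

    def test_annulus_matches_brute_force_oracle(self, noiseless_phantom):
        _, _, mask, _ = noiseless_phantom
        lam = laminar_split(mask, 2)
        oracle = brute_force_laminae(mask.labels[0], 2, mask.grid.pixel_size)
        np.testing.assert_array_equal(lam.codes[0], oracle)

    def test_equidistance_rule_holds_voxelwise(self, noiseless_phantom):
        _, _, mask, _ = noiseless_phantom
        from cartiq.geometry import _boundary_distances

        d_art, d_bone = _boundary_distances(mask, 2)
        lam = laminar_split(mask, 2)
        sup = lam.codes == LAMINA_SUPERFICIAL
        deep = lam.codes == LAMINA_DEEP
        assert (d_art[sup] <= d_bone[sup]).all()
        assert (d_art[deep] > d_bone[deep]).all()


class TestSliceSelection:
    @pytest.mark.parametrize(
        "central, n, expected",
        [(15, 3, [14, 15, 16]), (15, 7, [12, 13, 14, 15, 16, 17, 18])],
    )
    def test_centred_ranges(self, central, n, expected):
        assert list(select_loadbearing_slices(31, central, n)) == expected

    @pytest.mark.parametrize("central, n", [(0, 3), (30, 3), (15, 40)])
    def test_out_of_volume_rejected(self, central, n):
        with pytest.raises(ValueError):
            select_loadbearing_slices(31, central, n)

    def test_even_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            select_loadbearing_slices(31, 15, 4)


class TestResampleMask:
    def test_identity_on_identical_grids(self, noiseless_phantom):
        _, _, mask, _ = noiseless_phantom
        out = resample_mask(mask, mask.grid, mask.labels.shape)
        np.testing.assert_array_equal(out.labels, mask.labels)

    def test_twofold_upsampling_preserves_area(self, slab_mask):
        mask = slab_mask(k=6, pixel_size=0.5)
        fine = mask.grid.with_pixel_size(0.25)
        shape = (1, mask.labels.shape[1] * 2, mask.labels.shape[2] * 2)
        out = resample_mask(mask, fine, shape)
        src_area = (mask.labels == 2).sum() * 0.5**2
        tgt_area = (out.labels == 2).sum() * 0.25**2
        assert abs(src_area - tgt_area) <= 0.5**2  # within one source voxel

    def test_round_trip_on_commensurate_grids(self, noiseless_phantom):
        _, _, mask, _ = noiseless_phantom
        fine = mask.grid.with_pixel_size(mask.grid.pixel_size / 2)
        shape = (mask.labels.shape[0], mask.labels.shape[1] * 2, mask.labels.shape[2] * 2)
        up = resample_mask(mask, fine, shape)
        back = resample_mask(up, mask.grid, mask.labels.shape)
        np.testing.assert_array_equal(back.labels, mask.labels)

    def test_empty_mask_stays_empty(self):
        mask = CartilageMask(np.zeros((1, 8, 8), dtype=np.int16), Grid(0.5, 3.0))
        out = resample_mask(mask, mask.grid.with_pixel_size(0.25), (1, 16, 16))
        assert (out.labels == 0).all()

    def test_singular_affine_rejected(self, slab_mask):
        mask = slab_mask()
        bad = Grid(0.5, 3.0, np.zeros((4, 4)))
        with pytest.raises(ValueError, match="singular"):
            resample_mask(mask, bad, mask.labels.shape)


class TestThickness:
    @given(
        k=st.integers(min_value=1, max_value=14),
        s=st.floats(min_value=0.1, max_value=1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_slab_thickness_is_k_times_s(self, k, s):
        mask = make_slab_mask(k=k, pixel_size=s)
        out = regional_thickness(mask, 2)
        assert out.mean_thickness == pytest.approx(k * s, rel=1e-12)

    def test_single_voxel_sheet_measures_one_pixel(self, slab_mask):
        mask = slab_mask(k=1, pixel_size=0.365)
        assert regional_thickness(mask, 2).mean_thickness == pytest.approx(0.365)

    def test_annulus_matches_analytic_ring_width(self):
        # ring width 6 px at s=0.365 -> 2.19 mm within half a pixel
        spec = PhantomSpec(shape=(1, 64, 64), shell_thickness=2.19, pixel_size=0.365)
        _, mask, _ = generate_phantom(spec, seed=1)
        out = regional_thickness(mask, 2)
        assert abs(out.mean_thickness - 2.19) <= 0.365 / 2

    def test_invariant_under_rotation_and_translation(self, slab_mask):
        mask = slab_mask(k=8, pixel_size=0.4, n_cols=16)
        base = regional_thickness(mask, 2).mean_thickness
        rot = CartilageMask(np.rot90(mask.labels, axes=(1, 2)).copy(), mask.grid)
        assert regional_thickness(rot, 2).mean_thickness == pytest.approx(base)
        shifted = CartilageMask(np.roll(mask.labels, 2, axis=1), mask.grid)
        assert regional_thickness(shifted, 2).mean_thickness == pytest.approx(base)

    def test_empty_region_on_range_rejected(self, slab_mask):
        mask = slab_mask(k=5, n_slices=3)
        labels = mask.labels.copy()
        labels[2] = 0
        mask2 = CartilageMask(labels, mask.grid)
        with pytest.raises(ValueError, match="empty"):
            regional_thickness(mask2, 2, range(2, 3))
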