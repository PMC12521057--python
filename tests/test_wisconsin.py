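"""Wisconsin method: slice subtraction, ROI grid, per-ROI SD summaries."""

import numpy as np
import pytest

from ctnoise import (
    CTVolume,
    PhantomSpec,
    build_roi_grid,
    make_mask,
    make_phantom,
    roi_sds,
    subtract_adjacent,
    wisconsin_slice_gn,
    wisconsin_volume_gn,
)


def _volume_from_slices(*slices):
    arr = np.stack([np.asarray(s, dtype=float) for s in slices])
    return CTVolume(arr, (1.0, 1.0), 1.0, np.arange(arr.shape[0], dtype=float))


class TestSubtractAdjacent:
    def test_identical_slices_cancel(self):
        v = _volume_from_slices(np.full((8, 8), 30.0), np.full((8, 8), 30.0))
        assert np.all(subtract_adjacent(v, 0) == 0.0)

    def test_constant_difference(self):
        v = _volume_from_slices(np.full((8, 8), 10.0), np.full((8, 8), 4.0))
        assert np.all(subtract_adjacent(v, 0) == 6.0)

    def test_last_slice_uses_previous_neighbor(self):
        v = _volume_from_slices(np.full((8, 8), 1.0), np.full((8, 8), 5.0))
        assert np.all(subtract_adjacent(v, 1) == 4.0)

    def test_variance_addition(self, rng):
        """Independent sigma=10 slices: difference SD ~ 10*sqrt(2)."""
        a = rng.normal(0, 10, (200, 200))
        b = rng.normal(0, 10, (200, 200))
        v = _volume_from_slices(a, b)
        sd = subtract_adjacent(v, 0).std(ddof=1)
        assert sd == pytest.approx(10 * np.sqrt(2), rel=0.05)

    def test_out_of_range_index(self, white_phantom):
        vol, _ = white_phantom
        with pytest.raises(IndexError):
            subtract_adjacent(vol, vol.n_slices)


class TestRoiGrid:
    @pytest.mark.parametrize(
        "shape,roi_mm,spacing,roi_px,n_rois",
        [
            ((512, 512), 7.0, 0.7, 10, 51 * 51),
            ((100, 100), 7.0, 1.0, 7, 14 * 14),
            ((64, 96), 8.0, 1.0, 8, 8 * 12),
        ],
    )
    def test_examples(self, shape, roi_mm, spacing, roi_px, n_rois):
        g = build_roi_grid(shape, roi_mm, spacing)
        assert g.roi_px == roi_px
        assert g.n_rois == n_rois

    def test_degenerate_roi_rejected(self):
        with pytest.raises(ValueError, match="< 2"):
            build_roi_grid((100, 100), 7.0, 10.0)

    def test_roi_exceeding_slice_rejected(self):
        with pytest.raises(ValueError, match="exceeds slice"):
            build_roi_grid((5, 5), 7.0, 1.0)

    def test_origins_disjoint_and_inside(self):
        g = build_roi_grid((23, 17), 5.0, 1.0)
        origins = g.origins
        assert len(set(origins)) == g.n_rois
        for r, c in origins:
            assert r + g.roi_px <= 23 and c + g.roi_px <= 17


class TestRoiSds:
    def test_mask_monotonicity(self, white_phantom):
        """Shrinking the mask never adds valid ROIs."""
        vol, _ = white_phantom
        diff = subtract_adjacent(vol, 0)
        grid = build_roi_grid(diff.shape, 7.0, 1.0)
        mask = make_mask(vol.slice_hu(0), "tissue", use_median_filter=True).mask
        n_full = roi_sds(diff, mask, grid).size
        shrunk = mask.copy()
        shrunk[::3, :] = False
        assert roi_sds(diff, shrunk, grid).size <= n_full
        assert n_full > 0

    def test_empty_mask_no_rois(self):
        diff = np.zeros((20, 20))
        grid = build_roi_grid(diff.shape, 5.0, 1.0)
        assert roi_sds(diff, np.zeros((20, 20), bool), grid).size == 0


class TestWisconsinSliceGn:
    def test_zero_difference_gives_zero_noise(self):
        s = np.full((64, 64), 50.0)
        v = _volume_from_slices(s, s)
        r = wisconsin_slice_gn(v, 0, "tissue")
        assert r.mean_gn == 0.0 and r.mode_gn == 0.0
        assert r.n_rois == len(r.roi_sds)

    def test_recovers_sigma_with_correction(self, white_phantom):
        vol, truth = white_phantom
        for comp in ("tissue", "air"):
            r = wisconsin_slice_gn(vol, 0, comp)
            assert r.mean_gn == pytest.approx(truth.sigma_hu, rel=0.10)
            assert r.mode_gn == pytest.approx(truth.sigma_hu, rel=0.10)

    def test_without_correction_reads_sqrt2_higher(self, white_phantom):
        vol, truth = white_phantom
        r = wisconsin_slice_gn(vol, 0, "tissue", sqrt2_correction=False)
        assert r.mean_gn == pytest.approx(truth.sigma_hu * np.sqrt(2), rel=0.10)

    def test_sparse_mask_gives_no_value(self, white_phantom):
        vol, _ = white_phantom
        assert wisconsin_slice_gn(vol, 0, "tissue", min_valid_rois=10**6) is None

    def test_mean_mode_within_support(self, white_phantom):
        vol, _ = white_phantom
        r = wisconsin_slice_gn(vol, 0, "air")
        assert r.roi_sds.min() <= r.mean_gn <= r.roi_sds.max()
        assert r.roi_sds.min() - 0.25 <= r.mode_gn <= r.roi_sds.max() + 0.25

    def test_tissue_air_consistency(self, white_phantom):
        """Same sigma everywhere: tissue and air means agree within 10%."""
        vol, _ = white_phantom
        t = wisconsin_slice_gn(vol, 0, "tissue")
        a = wisconsin_slice_gn(vol, 0, "air")
        assert t.mean_gn == pytest.approx(a.mean_gn, rel=0.10)

    def test_structure_suppression_exact(self):
        """An insert replicated on adjacent slices cancels exactly."""
        from ctnoise import Insert

        kw = dict(shape=(4, 160, 160), pixel_spacing_mm=1.0,
                  body_semi_axes_mm=(50.0, 65.0), sigma_hu=10.0, seed=5)
        plain, _ = make_phantom(PhantomSpec(**kw))
        insert = Insert("ellipse", hu=65.0, center_mm=(5.0, -8.0), size_mm=(12.0, 9.0))
        with_ins, _ = make_phantom(PhantomSpec(inserts=(insert,), **kw))
        for comp in ("tissue", "air"):
            r0 = wisconsin_slice_gn(plain, 1, comp)
            r1 = wisconsin_slice_gn(with_ins, 1, comp)
            assert np.array_equal(r0.roi_sds, r1.roi_sds)
            assert r0.mean_gn == r1.mean_gn and r0.mode_gn == r1.mode_gn

    def test_volume_returns_one_result_per_slice(self, white_phantom):
        vol, _ = white_phantom
        results = wisconsin_volume_gn(vol, "tissue")
        assert len(results) == vol.n_slices
        assert all(r is not None for r in results)
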