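"""Thermal response, depth masking, latitudinal profiles, and range shifts."""

import numpy as np
import pytest
import xarray as xr

from kelppop.paleocover import (
    CoverScenario,
    LatProfile,
    ResponseFunction,
    depth_mask,
    latitudinal_profile,
    predict_cover_grid,
    range_shift,
    response_cover,
)
from kelppop.synthetic import GridSpec, simulate_grids


@pytest.fixture(scope="module")
def default_grids():
    sst, bathy = simulate_grids(GridSpec())
    return sst, bathy


def _scenario(sst, bathy, **kw):
    return CoverScenario(sst=sst, bathymetry=bathy, **kw)


class TestResponseFunction:
    def test_peak_at_optimum(self):
        rf = ResponseFunction()
        assert response_cover(23.0, rf) == rf.peak_cover

    def test_zero_at_and_beyond_threshold(self):
        rf = ResponseFunction()
        for t in (26.0, 27.5, 40.0, 20.0, 5.0):
            assert response_cover(t, rf) == 0.0

    def test_symmetric_and_bounded(self):
        rf = ResponseFunction()
        for delta in (0.5, 1.0, 2.0, 2.9):
            lo, hi = response_cover(23 - delta, rf), response_cover(23 + delta, rf)
            assert lo == pytest.approx(hi)
            assert 0 <= lo <= rf.peak_cover

    def test_continuity_at_threshold(self):
        rf = ResponseFunction()
        assert response_cover(25.999, rf) < 1e-3 * rf.peak_cover

    def test_tabulated_curve_interpolates(self):
        rf = ResponseFunction(table=((20.0, 0.0), (23.0, 40.0), (26.0, 0.0)))
        assert response_cover(21.5, rf) == pytest.approx(20.0)
        assert response_cover(30.0, rf) == 0.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ResponseFunction(t_opt=26, t_max=23)
        with pytest.raises(ValueError):
            ResponseFunction(peak_cover=0.0)


class TestDepthMask:
    def test_present_day_selects_habitat_band(self, default_grids):
        sst, bathy = default_grids
        mask = depth_mask(_scenario(sst, bathy))
        sel = bathy.values[mask.values]
        assert sel.size > 0 and sel.min() >= 0 and sel.max() <= 80

    def test_lgm_offset_selects_present_120_to_200(self, default_grids):
        sst, bathy = default_grids
        mask = depth_mask(_scenario(sst, bathy, sea_level_offset=120.0))
        expected = (bathy >= 120) & (bathy <= 200)
        assert bool((mask == expected).all())

    def test_shallow_shelf_under_lgm_offset_warns_empty(self, default_grids):
        sst, bathy = default_grids
        shallow = xr.zeros_like(bathy) + 50.0
        with pytest.warns(UserWarning, match="empty"):
            mask = depth_mask(_scenario(sst, shallow, sea_level_offset=120.0))
        assert int(mask.sum()) == 0

    def test_latitude_window_applies(self, default_grids):
        sst, bathy = default_grids
        mask = depth_mask(_scenario(sst, bathy, lat_range=(-30.0, -25.0)))
        lats = np.broadcast_to(sst["lat"].values[:, None], mask.shape)[mask.values]
        assert lats.min() >= -30 and lats.max() <= -25

    def test_shape_mismatch_is_error(self, default_grids):
        sst, bathy = default_grids
        with pytest.raises(ValueError):
            CoverScenario(sst=sst, bathymetry=bathy.isel(lon=slice(0, 3)))


class TestPredictCoverGrid:
    def test_uniform_sst_at_optimum_gives_uniform_peak(self, default_grids):
        sst, bathy = default_grids
        rf = ResponseFunction()
        cover, _ = predict_cover_grid(_scenario(xr.zeros_like(sst) + 23.0, bathy), rf)
        assert np.allclose(cover.values, rf.peak_cover)

    def test_cover_peaks_where_sst_crosses_optimum(self, default_grids):
        sst, bathy = default_grids
        cover, _ = predict_cover_grid(_scenario(sst, bathy), ResponseFunction())
        # analytic: SST = 23 at lat = -30 on the 0.8 deg C per degree gradient
        peak_lat = float(cover["lat"][int(np.argmax(cover.mean("lon").values))])
        assert peak_lat == pytest.approx(-30.0, abs=0.1)

    def test_all_land_grid_has_empty_mask(self, default_grids):
        sst, bathy = default_grids
        land = xr.zeros_like(bathy) - 5.0
        with pytest.warns(UserWarning):
            _, mask = predict_cover_grid(_scenario(sst, land), ResponseFunction())
        assert int(mask.sum()) == 0


class TestLatitudinalProfile:
    def test_uniform_cover_gives_uniform_bins(self, default_grids):
        sst, bathy = default_grids
        scn = _scenario(sst, bathy)
        cover = xr.zeros_like(sst) + 50.0
        prof = latitudinal_profile(cover, depth_mask(scn), 0.5)
        filled = prof.mean_cover[prof.n_cells > 0]
        assert filled.size > 0 and np.allclose(filled, 50.0)

    def test_empty_bins_are_nan_not_zero(self, default_grids):
        sst, bathy = default_grids
        scn = _scenario(sst, bathy, lat_range=(-30.0, -29.0))
        prof = latitudinal_profile(xr.zeros_like(sst) + 10.0, depth_mask(scn), 0.5)
        assert np.isnan(prof.mean_cover[prof.n_cells == 0]).all()
        assert not np.any(prof.mean_cover[prof.n_cells == 0] == 0.0)

    def test_matches_naive_per_bin_mean(self, default_grids):
        sst, bathy = default_grids
        rng = np.random.default_rng(2)
        cover = xr.DataArray(
            rng.uniform(0, 50, sst.shape), coords=sst.coords, dims=sst.dims
        )
        mask = depth_mask(_scenario(sst, bathy))
        prof = latitudinal_profile(cover, mask, 0.5)
        lats = sst["lat"].values
        for b, center in enumerate(prof.lat_centers):
            rows = (lats >= center - 0.25) & (lats < center + 0.25)
            vals = [
                cover.values[i, j]
                for i in np.flatnonzero(rows)
                for j in range(sst.sizes["lon"])
                if mask.values[i, j]
            ]
            if vals:
                assert prof.mean_cover[b] == pytest.approx(np.mean(vals))
                assert prof.n_cells[b] == len(vals)
            else:
                assert prof.n_cells[b] == 0

    def test_mask_cell_count_is_conserved(self, default_grids):
        sst, bathy = default_grids
        mask = depth_mask(_scenario(sst, bathy))
        prof = latitudinal_profile(xr.zeros_like(sst), mask, 0.5)
        assert int(prof.n_cells.sum()) == int(mask.sum())


@pytest.fixture(scope="module")
def profiles():
    rf = ResponseFunction()
    sst_p, bathy = simulate_grids(GridSpec())
    sst_l, _ = simulate_grids(GridSpec(cooling=4.0))
    present = CoverScenario(sst=sst_p, bathymetry=bathy)
    lgm = CoverScenario(sst=sst_l, bathymetry=bathy, sea_level_offset=120.0)
    prof_p = latitudinal_profile(*predict_cover_grid(present, rf), 0.5)
    prof_l = latitudinal_profile(*predict_cover_grid(lgm, rf), 0.5)
    return prof_p, prof_l


class TestRangeShift:
    def test_identical_profiles_shift_zero(self, profiles):
        prof_p, _ = profiles
        for metric in ("peak", "centroid", "threshold-crossing"):
            assert range_shift(prof_p, prof_p, metric) == 0.0

    @pytest.mark.parametrize("metric", ["peak", "centroid", "threshold-crossing"])
    def test_four_degree_cooling_on_0p8_gradient_shifts_five_degrees(self, profiles, metric):
        prof_p, prof_l = profiles
        assert range_shift(prof_p, prof_l, metric) == pytest.approx(5.0, abs=0.5)

    def test_cooling_moves_peak_equatorward_monotonically(self):
        rf = ResponseFunction()
        _, bathy = simulate_grids(GridSpec())
        shifts = []
        base = None
        for cooling in (0.0, 1.0, 2.0, 3.0, 4.0):
            sst, _ = simulate_grids(GridSpec(cooling=cooling))
            scn = CoverScenario(sst=sst, bathymetry=bathy)
            prof = latitudinal_profile(*predict_cover_grid(scn, rf), 0.5)
            if base is None:
                base = prof
            shifts.append(range_shift(base, prof, "peak"))
        assert all(a < b for a, b in zip(shifts, shifts[1:]))

    def test_flat_profile_has_no_feature(self, default_grids):
        sst, bathy = default_grids
        mask = depth_mask(_scenario(sst, bathy))
        flat = latitudinal_profile(xr.zeros_like(sst) + 10.0, mask, 0.5)
        with pytest.raises(ValueError, match="flat"):
            range_shift(flat, flat, "peak")

    def test_mismatched_binning_is_error(self, profiles, default_grids):
        prof_p, _ = profiles
        sst, bathy = default_grids
        other = latitudinal_profile(xr.zeros_like(sst), depth_mask(_scenario(sst, bathy)), 1.0)
        with pytest.raises(ValueError):
            range_shift(prof_p, other, "peak")
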