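"""SST-driven kelp-cover hindcasting with sea-level-adjusted depth masking.

Predicts percentage kelp cover from mean annual sea-surface temperature via
a pluggable thermal response curve, restricts the prediction to the depth
band the species occupies below *scenario* sea level (present day: 0 m
offset; Last Glacial Maximum: ~120 m lower, so the 0-80 m habitat band maps
onto shelf that is 120-200 m deep today), averages cover latitudinally, and
quantifies how far distributional features shift toward the equator between
scenarios.

Latitudes follow the geographic convention: negative in the southern
hemisphere, increasing northward. "Equatorward" displacement is positive
when a feature moves toward 0 deg latitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "ResponseFunction",
    "CoverScenario",
    "LatProfile",
    "response_cover",
    "depth_mask",
    "predict_cover_grid",
    "latitudinal_profile",
    "range_shift",
]


@dataclass(frozen=True)
class ResponseFunction:
    """Thermal response of kelp cover to mean annual SST.

    The default form is a symmetric smooth bump: cover peaks at ``t_opt``
    (deg C) and falls continuously to zero at ``t_max`` (the upper thermal
    threshold) and at the mirrored point below the optimum,

        cover(T) = peak_cover * cos^2( pi/2 * (T - t_opt) / (t_max - t_opt) )

    for |T - t_opt| < t_max - t_opt, else 0. Supply ``table`` (temperature,
    cover) pairs to use a tabulated empirical curve instead (linearly
    interpolated, zero outside its range).
    """

    t_opt: float = 23.0
    t_max: float = 26.0
    peak_cover: float = 50.0
    table: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.table is None:
            if not self.t_opt < self.t_max:
                raise ValueError("t_opt must be below t_max")
            if not 0.0 < self.peak_cover <= 100.0:
                raise ValueError("peak_cover must be in (0, 100]")
        else:
            temps = [t for t, _ in self.table]
            if sorted(temps) != temps or len(set(temps)) != len(temps):
                raise ValueError("tabulated temperatures must be strictly increasing")

    def __call__(self, sst):
        return response_cover(sst, self)


def response_cover(sst, rf: ResponseFunction):
    """Predicted percent cover at the given SST (scalar or array)."""
    t = np.asarray(sst, dtype=float)
    if rf.table is not None:
        xs = np.array([x for x, _ in rf.table])
        ys = np.array([y for _, y in rf.table])
        out = np.interp(t, xs, ys, left=0.0, right=0.0)
    else:
        width = rf.t_max - rf.t_opt
        z = (t - rf.t_opt) / width
        out = np.where(np.abs(z) < 1.0, rf.peak_cover * np.cos(np.pi / 2.0 * z) ** 2, 0.0)
    return float(out) if np.isscalar(sst) else out


@dataclass(frozen=True)
class CoverScenario:
    """One hindcast scenario: SST + bathymetry grids and habitat constraints.

    ``sst`` (deg C) and ``bathymetry`` (m, positive down) are co-registered
    2-D DataArrays with ``lat``/``lon`` coordinates. ``sea_level_offset`` is
    how far sea level sat below present (m): 0 for the present day, ~120 for
    the LGM. ``depth_band`` is the habitat depth range below scenario sea
    level; ``lat_range`` the latitudes analysed (southern-hemisphere values
    are negative, e.g. 18-38 deg S is (-38, -18)).
    """

    sst: xr.DataArray
    bathymetry: xr.DataArray
    sea_level_offset: float = 0.0
    depth_band: tuple[float, float] = (0.0, 80.0)
    lat_range: tuple[float, float] = (-38.0, -18.0)

    def __post_init__(self) -> None:
        if self.sst.shape != self.bathymetry.shape:
            raise ValueError(
                f"sst shape {self.sst.shape} != bathymetry shape {self.bathymetry.shape}"
            )
        for da in (self.sst, self.bathymetry):
            if set(da.dims) != {"lat", "lon"}:
                raise ValueError("grids must have dims ('lat', 'lon')")
        if not np.allclose(self.sst["lat"], self.bathymetry["lat"]) or not np.allclose(
            self.sst["lon"], self.bathymetry["lon"]
        ):
            raise ValueError("sst and bathymetry grids are not co-registered")
        if not self.depth_band[0] < self.depth_band[1]:
            raise ValueError("depth_band min must be < max")
        if not self.lat_range[0] < self.lat_range[1]:
            raise ValueError("lat_range min must be < max")


def depth_mask(scn: CoverScenario) -> xr.DataArray:
    """Boolean grid of cells inside the habitat depth band below scenario sea level.

    A cell qualifies iff ``depth_band.min <= bathymetry - sea_level_offset <=
    depth_band.max`` and its latitude lies within ``lat_range``. Warns when
    the mask is empty (e.g. an LGM offset on a shelf that never reaches it).
    """
    depth = scn.bathymetry - scn.sea_level_offset
    lo, hi = scn.depth_band
    mask = (depth >= lo) & (depth <= hi)
    lat_ok = (scn.bathymetry["lat"] >= scn.lat_range[0]) & (
        scn.bathymetry["lat"] <= scn.lat_range[1]
    )
    mask = mask & lat_ok
    if not bool(mask.any()):
        warnings.warn(
            "depth mask is empty: no cells in the depth band at this sea-level offset",
            stacklevel=2,
        )
    return mask


def predict_cover_grid(
    scn: CoverScenario, rf: ResponseFunction
) -> tuple[xr.DataArray, xr.DataArray]:
    """Cell-wise cover prediction over the whole grid plus the habitat mask.

    Cover is evaluated everywhere (for full-shelf maps); the depth/latitude
    mask is returned separately for profile computation.
    """
    cover = xr.DataArray(
        response_cover(scn.sst.values, rf),
        coords=scn.sst.coords,
        dims=scn.sst.dims,
        name="cover",
        attrs={"units": "%"},
    )
    return cover, depth_mask(scn)


@dataclass(frozen=True)
class LatProfile:
    """Latitudinally averaged cover: bin centres, mean % cover, cell counts.

    Bins with no eligible cells carry NaN mean cover (flagged via
    ``n_cells == 0``), never a filled-in zero.
    """

    lat_centers: np.ndarray
    mean_cover: np.ndarray
    n_cells: np.ndarray
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lat_bin": self.lat_centers, "mean_cover": self.mean_cover, "n_cells": self.n_cells}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def latitudinal_profile(cover: xr.DataArray, mask: xr.DataArray, bin_width: float = 0.5) -> LatProfile:
    """Unweighted mean cover of masked cells within each latitude bin."""
    if cover.shape != mask.shape:
        raise ValueError("cover and mask are not co-registered")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lats = np.asarray(cover["lat"].values, dtype=float)
    lo = np.floor(lats.min() / bin_width) * bin_width
    hi = np.ceil(lats.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0

    cov = np.asarray(cover.values, dtype=float)
    msk = np.asarray(mask.values, dtype=bool)
    lat_axis = cover.dims.index("lat")
    if lat_axis != 0:
        cov, msk = cov.T, msk.T

    which = np.clip(np.digitize(lats, edges) - 1, 0, len(centers) - 1)
    means = np.full(len(centers), np.nan)
    counts = np.zeros(len(centers), dtype=int)
    for b in range(len(centers)):
        rows = which == b
        if not rows.any():
            continue
        sel = msk[rows]
        counts[b] = int(sel.sum())
        if counts[b]:
            means[b] = float(cov[rows][sel].mean())
    return LatProfile(lat_centers=centers, mean_cover=means, n_cells=counts, bin_width=bin_width)


def _feature_latitude(profile: LatProfile, metric: str, threshold_frac: float) -> float:
    cover = profile.mean_cover
    lat = profile.lat_centers
    valid = ~np.isnan(cover)
    if not valid.any():
        raise ValueError("profile has no eligible bins")
    c, la = cover[valid], lat[valid]
    if np.allclose(c, c[0]):
        raise ValueError(f"profile is flat; {metric!r} feature undefined")
    if metric == "peak":
        return float(la[np.argmax(c)])
    if metric == "centroid":
        total = c.sum()
        if total <= 0:
            raise ValueError("profile has zero total cover")
        return float((c * la).sum() / total)
    if metric == "threshold-crossing":
        thr = threshold_frac * np.max(c)
        qual = la[c >= thr]
        # equatorward edge of the high-cover band: the qualifying latitude
        # closest to the equator
        return float(qual[np.argmin(np.abs(qual))])
    raise ValueError(f"unknown metric {metric!r}")


def range_shift(
    profile_a: LatProfile,
    profile_b: LatProfile,
    metric: str = "peak",
    threshold_frac: float = 0.5,
) -> float:
    """Signed equatorward displacement (degrees) of a profile feature, a -> b.

    Positive values mean the feature in ``profile_b`` lies closer to the
    equator than in ``profile_a``. Metrics: "peak" (argmax bin), "centroid"
    (cover-weighted mean latitude), "threshold-crossing" (equatorward edge of
    the band at ``threshold_frac`` of the profile maximum).
    """
    if profile_a.bin_width != profile_b.bin_width or len(profile_a.lat_centers) != len(
        profile_b.lat_centers
    ):
        raise ValueError("profiles must share binning")
    if not np.allclose(profile_a.lat_centers, profile_b.lat_centers):
        raise ValueError("profiles must share bin centres")
    a = _feature_latitude(profile_a, metric, threshold_frac)
    b = _feature_latitude(profile_b, metric, threshold_frac)
    return float(abs(a) - abs(b))
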