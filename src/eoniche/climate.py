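"""Harmonization and classification of monthly climate fields.

The workflow mirrors how multi-GCM paleoclimate fields are prepared for
site-level and niche-model use: each model's monthly temperature,
precipitation and evaporation fields (plus orography) are bilinearly
regridded to a common lon/lat grid, reduced to 22 bioclimatic summary
variables (Var1..Var22), averaged across models into ensemble means, sampled
at site coordinates, and classified into Koppen-Geiger classes (rule set of
the Beck et al. translation) and Nix thermal regimes.

Unit conventions: temperatures are carried in kelvin throughout the variable
derivation (Var definitions below are in K); the conversion to degrees
Celsius happens only inside the classifiers.  Seasonal aggregates JJA/DJF are
fixed calendar windows globally — months {6,7,8} and {12,1,2} of the 12-band
stack — while the classifiers use hemisphere-aware summer/winter.  These are
distinct conventions, both intentional.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "BIOCLIM_VARS",
    "regrid_bilinear",
    "regrid_fields",
    "derive_bioclim",
    "ensemble_mean",
    "extract_at",
    "koppen_classify",
    "nix_classify",
    "KOPPEN_CLASSES",
    "write_netcdf",
    "read_netcdf",
]

_JJA = [6, 7, 8]
_DJF = [12, 1, 2]

BIOCLIM_VARS: dict[str, str] = {
    "Var1": "Mean annual temperature (K)",
    "Var2": "Temperature range (Tmax - Tmin) x 10 (K)",
    "Var3": "JJA mean temperature (K)",
    "Var4": "DJF mean temperature (K)",
    "Var5": "Annual precipitation (mm)",
    "Var6": "JJA precipitation (mm)",
    "Var7": "DJF precipitation (mm)",
    "Var8": "Annual evaporation (mm)",
    "Var9": "JJA evaporation (mm)",
    "Var10": "DJF evaporation (mm)",
    "Var11": "Annual hydric balance, evaporation - precipitation (mm)",
    "Var12": "JJA hydric balance (mm)",
    "Var13": "DJF hydric balance (mm)",
    "Var14": "Orography (m a.s.l.)",
    "Var15": "Temperature of the warmest month (K)",
    "Var16": "Temperature of the coolest month (K)",
    "Var17": "Precipitation of the wettest month (mm)",
    "Var18": "Precipitation of the driest month (mm)",
    "Var19": "Evaporation of the warmest month (mm)",
    "Var20": "Evaporation of the coolest month (mm)",
    "Var21": "EP max, Var19 - Var17 (mm)",
    "Var22": "EP min, Var20 - Var18 (mm)",
}


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def regrid_bilinear(
    field: xr.DataArray,
    target_lon: np.ndarray,
    target_lat: np.ndarray,
) -> xr.DataArray:
    """Bilinear interpolation of a regular lon/lat field onto target centers.

    Longitude wraps at +/-180 deg (the source is padded with its opposite
    edge); target latitudes outside the source coverage become NaN.  When the
    target grid coincides with the source, values are reproduced exactly.
    """
    lon = np.asarray(field["lon"].values, dtype=float)
    lat = np.asarray(field["lat"].values, dtype=float)
    extra_dims = [d for d in field.dims if d not in ("lat", "lon")]
    data = field.transpose(*extra_dims, "lat", "lon").values
    flat = data.reshape((-1, lat.size, lon.size))

    # pad longitudes cyclically so interpolation crosses the dateline
    lon_pad = np.concatenate([[lon[-1] - 360.0], lon, [lon[0] + 360.0]])
    out = np.empty((flat.shape[0], target_lat.size, target_lon.size))
    tg_lat, tg_lon = np.meshgrid(target_lat, target_lon, indexing="ij")
    pts = np.column_stack([tg_lat.ravel(), tg_lon.ravel()])
    for k in range(flat.shape[0]):
        padded = np.concatenate(
            [flat[k][:, -1:], flat[k], flat[k][:, :1]], axis=1
        )
        interp = RegularGridInterpolator(
            (lat, lon_pad), padded, method="linear",
            bounds_error=False, fill_value=np.nan,
        )
        out[k] = interp(pts).reshape(target_lat.size, target_lon.size)

    shape = [field.sizes[d] for d in extra_dims] + [target_lat.size, target_lon.size]
    coords = {d: field.coords[d] for d in extra_dims if d in field.coords}
    coords["lat"] = target_lat
    coords["lon"] = target_lon
    return xr.DataArray(
        out.reshape(shape), dims=extra_dims + ["lat", "lon"], coords=coords,
        name=field.name, attrs=field.attrs,
    )


def regrid_fields(
    fields: xr.Dataset, target_lon: np.ndarray, target_lat: np.ndarray
) -> xr.Dataset:
    """Regrid every variable of a monthly field set onto the common grid."""
    out = {
        name: regrid_bilinear(da, target_lon, target_lat)
        for name, da in fields.data_vars.items()
    }
    return xr.Dataset(out, attrs=fields.attrs)


# ---------------------------------------------------------------------------
# Bioclim derivation
# ---------------------------------------------------------------------------

def _season_sel(da: xr.DataArray, months: list[int]) -> xr.DataArray:
    return da.sel(month=months)


def derive_bioclim(fields: xr.Dataset) -> xr.Dataset:
    """Derive the 22 bioclimatic variables from a monthly field set.

    Expects variables ``temp`` (K), ``precip``/``evap`` (mm/month) on
    (month, lat, lon) with month coordinate 1..12, and ``orog`` on (lat, lon).
    Cells missing any month are NaN in every derived layer.
    """
    for req in ("temp", "precip", "evap", "orog"):
        if req not in fields:
            raise KeyError(f"monthly field set lacks {req!r}")
    t, p, e = fields["temp"], fields["precip"], fields["evap"]
    if t.sizes.get("month") != 12:
        raise ValueError("temperature must have 12 monthly bands")

    warm = t.fillna(-9.0e30).argmax("month")
    cool = t.fillna(9.0e30).argmin("month")
    v = {}
    v["Var1"] = t.mean("month")
    v["Var15"] = t.max("month")
    v["Var16"] = t.min("month")
    v["Var2"] = (v["Var15"] - v["Var16"]) * 10.0
    v["Var3"] = _season_sel(t, _JJA).mean("month")
    v["Var4"] = _season_sel(t, _DJF).mean("month")
    v["Var5"] = p.sum("month", skipna=False)
    v["Var6"] = _season_sel(p, _JJA).sum("month", skipna=False)
    v["Var7"] = _season_sel(p, _DJF).sum("month", skipna=False)
    v["Var8"] = e.sum("month", skipna=False)
    v["Var9"] = _season_sel(e, _JJA).sum("month", skipna=False)
    v["Var10"] = _season_sel(e, _DJF).sum("month", skipna=False)
    v["Var11"] = v["Var8"] - v["Var5"]
    v["Var12"] = v["Var9"] - v["Var6"]
    v["Var13"] = v["Var10"] - v["Var7"]
    v["Var14"] = fields["orog"]
    v["Var17"] = p.max("month")
    v["Var18"] = p.min("month")
    v["Var19"] = e.isel(month=warm)
    v["Var20"] = e.isel(month=cool)
    v["Var21"] = v["Var19"] - v["Var17"]
    v["Var22"] = v["Var20"] - v["Var18"]

    # propagate missing months into every derived layer
    bad = t.isnull().any("month") | p.isnull().any("month") | e.isnull().any("month")
    out = {}
    for name in BIOCLIM_VARS:
        da = v[name].where(~bad)
        da.attrs["long_name"] = BIOCLIM_VARS[name]
        out[name] = da.drop_vars("month", errors="ignore")
    return xr.Dataset(out, attrs=dict(fields.attrs))


def ensemble_mean(stacks: list[xr.Dataset]) -> xr.Dataset:
    """Cell-wise arithmetic mean of bioclim stacks on a shared grid."""
    if not stacks:
        raise ValueError("need at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        if not (
            np.array_equal(s["lon"].values, first["lon"].values)
            and np.array_equal(s["lat"].values, first["lat"].values)
        ):
            raise ValueError("stacks are not on a common grid")
    stacked = xr.concat(stacks, dim="model")
    return stacked.mean("model", skipna=False)


# ---------------------------------------------------------------------------
# Site extraction
# ---------------------------------------------------------------------------

def _nearest_index(centers: np.ndarray, coord: float) -> int:
    # containing-cell rule; exact ties go to the smaller index (argmin is
    # first-wins on ties)
    return int(np.argmin(np.abs(centers - coord)))


def extract_at(stack: xr.Dataset, sites: pd.DataFrame) -> pd.DataFrame:
    """Values of every stack variable at each site's containing grid cell.

    ``sites`` needs columns lon, lat (and optionally name).  Sites farther
    than half a cell outside the grid get NaN with a warning.
    """
    lon = stack["lon"].values
    lat = stack["lat"].values
    dlon = np.median(np.diff(lon)) if lon.size > 1 else 360.0
    dlat = np.median(np.diff(lat)) if lat.size > 1 else 180.0
    rows = []
    for _, site in sites.iterrows():
        rec = {"name": site.get("name", f"site{len(rows) + 1}"),
               "lon": site["lon"], "lat": site["lat"]}
        i = _nearest_index(lon, site["lon"])
        j = _nearest_index(lat, site["lat"])
        outside = (
            abs(lon[i] - site["lon"]) > dlon / 2 + 1e-9
            or abs(lat[j] - site["lat"]) > dlat / 2 + 1e-9
        )
        if outside:
            warnings.warn(
                f"site at ({site['lon']}, {site['lat']}) lies outside the grid",
                stacklevel=2,
            )
        for name, da in stack.data_vars.items():
            rec[name] = np.nan if outside else float(da.values[j, i])
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Koppen-Geiger classification
# ---------------------------------------------------------------------------

KOPPEN_CLASSES: tuple[str, ...] = (
    "Af", "Am", "Aw",
    "BWh", "BWk", "BSh", "BSk",
    "Csa", "Csb", "Csc", "Cwa", "Cwb", "Cwc", "Cfa", "Cfb", "Cfc",
    "Dsa", "Dsb", "Dsc", "Dsd", "Dwa", "Dwb", "Dwc", "Dwd",
    "Dfa", "Dfb", "Dfc", "Dfd",
    "ET", "EF",
)

_KOPPEN_CODE = {name: i + 1 for i, name in enumerate(KOPPEN_CLASSES)}


def _maybe_kelvin_to_celsius(t: np.ndarray) -> np.ndarray:
    # monthly means above 150 in any real climate only occur on the kelvin scale
    if np.nanmean(t) > 150.0:
        return t - 273.15
    return t


def koppen_classify_series(t_c: np.ndarray, p_mm: np.ndarray, lat: float) -> str:
    """Koppen-Geiger class of one 12-month series (T in degC, P in mm/month)."""
    labels = _koppen_vectorized(
        np.asarray(t_c, dtype=float)[:, None],
        np.asarray(p_mm, dtype=float)[:, None],
        np.asarray([lat], dtype=float),
    )
    return labels[0]


def _koppen_vectorized(t: np.ndarray, p: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Classify columns of (12, ncell) temperature (degC) / precipitation arrays."""
    ncell = t.shape[1]
    labels = np.full(ncell, "", dtype=object)
    valid = np.isfinite(t).all(axis=0) & np.isfinite(p).all(axis=0)

    mat = t.mean(axis=0)
    thot = t.max(axis=0)
    tcold = t.min(axis=0)
    tmon10 = (t > 10.0).sum(axis=0)
    pann = p.sum(axis=0)
    pdry = p.min(axis=0)

    # warm half-year: AMJJAS in the north, ONDJFM in the south
    amjjas = np.zeros(12, dtype=bool)
    amjjas[3:9] = True
    north = lat >= 0
    summer_mask = np.where(north[None, :], amjjas[:, None], ~amjjas[:, None])
    p_summer = np.where(summer_mask, p, np.nan)
    p_winter = np.where(~summer_mask, p, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        psdry = np.nanmin(p_summer, axis=0)
        pswet = np.nanmax(p_summer, axis=0)
        pwdry = np.nanmin(p_winter, axis=0)
        pwwet = np.nanmax(p_winter, axis=0)
        psum_tot = np.nansum(p_summer, axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac_summer = np.where(pann > 0, psum_tot / pann, 0.5)
    pthresh = np.where(
        frac_summer >= 0.7,
        2.0 * mat + 28.0,
        np.where(frac_summer <= 0.3, 2.0 * mat, 2.0 * mat + 14.0),
    )

    is_b = valid & (pann < 10.0 * pthresh) & (pthresh > 0)
    is_a = valid & ~is_b & (tcold >= 18.0)
    is_e = valid & ~is_b & ~is_a & (thot <= 10.0)
    is_c = valid & ~is_b & ~is_a & ~is_e & (tcold > 0.0)
    is_d = valid & ~is_b & ~is_a & ~is_e & ~is_c

    # B
    bw = pann < 5.0 * pthresh
    hot = mat >= 18.0
    for mask, lab in (
        (is_b & bw & hot, "BWh"), (is_b & bw & ~hot, "BWk"),
        (is_b & ~bw & hot, "BSh"), (is_b & ~bw & ~hot, "BSk"),
    ):
        labels[mask] = lab

    # A
    af = pdry >= 60.0
    am = ~af & (pdry >= 100.0 - pann / 25.0)
    labels[is_a & af] = "Af"
    labels[is_a & am] = "Am"
    labels[is_a & ~af & ~am] = "Aw"

    # E
    labels[is_e & (thot > 0.0)] = "ET"
    labels[is_e & (thot <= 0.0)] = "EF"

    # C and D share the precipitation suffix and summer-heat suffix
    with np.errstate(invalid="ignore"):
        suff_s = (psdry < 40.0) & (psdry < pwwet / 3.0)
        suff_w = ~suff_s & (pwdry < pswet / 10.0)
    second = np.where(suff_s, "s", np.where(suff_w, "w", "f"))
    third_c = np.where(thot >= 22.0, "a", np.where(tmon10 >= 4, "b", "c"))
    third_d = np.where(
        thot >= 22.0, "a",
        np.where(tmon10 >= 4, "b", np.where(tcold < -38.0, "d", "c")),
    )
    for idx in np.nonzero(is_c)[0]:
        labels[idx] = "C" + second[idx] + third_c[idx]
    for idx in np.nonzero(is_d)[0]:
        labels[idx] = "D" + second[idx] + third_d[idx]

    return labels


def koppen_classify(fields: xr.Dataset) -> xr.DataArray:
    """Koppen-Geiger class map from monthly temperature and precipitation.

    Temperatures may be in kelvin (auto-converted) or degC.  Cells with any
    missing month are left unclassified (empty string).  The integer code
    table is attached as ``class_codes``.
    """
    t = _maybe_kelvin_to_celsius(fields["temp"].values.astype(float))
    p = fields["precip"].values.astype(float)
    nlat, nlon = t.shape[1], t.shape[2]
    lat = np.repeat(fields["lat"].values, nlon)
    labels = _koppen_vectorized(
        t.reshape(12, -1), p.reshape(12, -1), lat
    ).reshape(nlat, nlon)
    da = xr.DataArray(
        labels, dims=("lat", "lon"),
        coords={"lat": fields["lat"].values, "lon": fields["lon"].values},
        name="koppen",
    )
    da.attrs["class_codes"] = str(_KOPPEN_CODE)
    return da


# ---------------------------------------------------------------------------
# Nix thermal regimes
# ---------------------------------------------------------------------------

def nix_classify(mat_c, map_mm):
    """Nix thermal regime from mean annual temperature (degC) and precipitation (mm).

    megathermal: MAT >= 22 and MAP > 549; mesothermal: 14 <= MAT < 22 and
    MAP > 549; microthermal: MAT < 14 and 719 <= MAP <= 3000; otherwise
    unclassified.  Boundaries are half-open so the regimes are disjoint.
    """
    mat = np.asarray(mat_c, dtype=float)
    pr = np.asarray(map_mm, dtype=float)
    out = np.full(mat.shape, "unclassified", dtype=object)
    out[(mat >= 22.0) & (pr > 549.0)] = "megathermal"
    out[(mat >= 14.0) & (mat < 22.0) & (pr > 549.0)] = "mesothermal"
    out[(mat < 14.0) & (pr >= 719.0) & (pr <= 3000.0)] = "microthermal"
    if out.ndim == 0:
        return str(out[()])
    return out


# ---------------------------------------------------------------------------
# NetCDF I/O (CF-style lat/lon coordinates, NetCDF3 via the scipy engine)
# ---------------------------------------------------------------------------

def write_netcdf(ds: xr.Dataset | xr.DataArray, path) -> None:
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    ds = ds.copy()
    for name, da in ds.data_vars.items():
        if da.dtype == object:  # class labels -> byte codes for NetCDF3
            codes = np.zeros(da.shape, dtype=np.int32)
            for lab, code in _KOPPEN_CODE.items():
                codes[da.values == lab] = code
            ds[name] = xr.DataArray(codes, dims=da.dims, coords=da.coords,
                                    attrs={"class_codes": str(_KOPPEN_CODE)})
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()
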