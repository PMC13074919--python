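"""Synthetic assemblages, climate grids, and occurrence sets with known truth.

Every downstream stage (rarefaction inference, bioclim derivation, climate
classification, niche modeling) is exercised against data produced here, so
each generator exposes the ground truth it embeds: the species pool size and
abundance distribution, the closed-form latitudinal/seasonal climate surfaces,
and the suitability function that drove occurrence sampling.

Conventions: temperature in kelvin, precipitation and evaporation in
mm/month, orography in m a.s.l.; monthly stacks hold 12 bands, January first;
longitudes in [-180, 180], latitudes in [-90, 90] (WGS84 degrees).  The
seasonal cycle is a pure cosine peaking in July north of the equator and in
January south of it, so the warmest-month index shifts by six months across
the equator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .diversity import AbundanceTable

__all__ = [
    "SADSpec",
    "ClimateGridSpec",
    "TrueSuitability",
    "gen_abundance",
    "gen_climate_grid",
    "gen_occurrences",
    "djf_minus_jja_amplitude",
]

_SAD_DISTRIBUTIONS = ("lognormal", "logseries", "uniform")


@dataclass(frozen=True)
class SADSpec:
    """Species-abundance distribution for one synthetic assemblage.

    ``shape`` is the lognormal sigma (on the log relative-abundance scale) or
    the log-series parameter in (0, 1); it is ignored for ``uniform``.
    """

    true_richness: int
    total_individuals: int
    distribution: str = "lognormal"
    shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_richness < 1:
            raise ValueError("true_richness must be >= 1")
        if self.total_individuals < 1:
            raise ValueError("total_individuals must be >= 1")
        if self.distribution not in _SAD_DISTRIBUTIONS:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; "
                f"choose one of {_SAD_DISTRIBUTIONS}"
            )
        if self.distribution == "lognormal" and self.shape <= 0:
            raise ValueError("lognormal shape (sigma) must be positive")
        if self.distribution == "logseries" and not 0 < self.shape < 1:
            raise ValueError("logseries shape must lie in (0, 1)")


def _relative_abundances(spec: SADSpec, rng: np.random.Generator) -> np.ndarray:
    s = spec.true_richness
    if spec.distribution == "uniform":
        p = np.ones(s)
    elif spec.distribution == "lognormal":
        p = np.exp(spec.shape * rng.standard_normal(s))
    else:  # logseries: iid abundances from the log-series distribution
        from scipy.stats import logser

        p = logser.rvs(spec.shape, size=s, random_state=rng).astype(float)
    return p / p.sum()


def gen_abundance(spec: SADSpec, name: str | None = None) -> AbundanceTable:
    """One multinomial assemblage drawn from the spec's species pool.

    The pool's relative abundances are drawn once per spec (seed-determined),
    then ``total_individuals`` individuals are sampled multinomially — the
    same scheme the bootstrap uses downstream.  Observed richness can fall
    below ``true_richness`` when rare species are missed.
    """
    rng = np.random.default_rng(spec.seed)
    p = _relative_abundances(spec, rng)
    counts = rng.multinomial(spec.total_individuals, p)
    taxa = tuple(f"sp{i + 1:03d}" for i in range(spec.true_richness))
    return AbundanceTable(name or f"synthetic_{spec.seed}", counts, taxa)


@dataclass(frozen=True)
class ClimateGridSpec:
    """Regular lon/lat grid of monthly temperature/precipitation/evaporation.

    Mean annual temperature declines linearly with |latitude| from
    ``t_equator_k``; a cosine seasonal cycle of amplitude ``seasonal_amplitude_k``
    is added with hemisphere-dependent phase.  Precipitation follows a
    cos^2(latitude) profile between ``p_pole_mm`` and ``p_equator_mm``.
    Evaporation is a deterministic linear function of monthly temperature
    (plus noise) so hydric-balance variables are non-degenerate.  Orography is
    a smooth deterministic ridge.  Defaults sketch a weak-gradient hothouse
    world rather than the modern climate.
    """

    resolution_arcmin: float = 120.0
    lon_range: tuple[float, float] = (-180.0, 180.0)
    lat_range: tuple[float, float] = (-90.0, 90.0)
    t_equator_k: float = 301.0
    t_lat_gradient_k_per_deg: float = 0.35
    seasonal_amplitude_k: float = 6.0
    p_equator_mm: float = 150.0
    p_pole_mm: float = 40.0
    evap_slope_mm_per_k: float = 2.2
    evap_offset_k: float = 273.15
    evap_base_mm: float = 10.0
    orography_amplitude_m: float = 400.0
    noise_sd_t: float = 0.0
    noise_sd_p: float = 0.0
    noise_sd_e: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution_arcmin <= 0:
            raise ValueError("resolution must be positive")
        lon0, lon1 = self.lon_range
        lat0, lat1 = self.lat_range
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValueError("empty grid: ranges must have positive extent")

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Cell-center coordinates (lon, lat) for the declared resolution."""
        step = self.resolution_arcmin / 60.0
        lon = np.arange(self.lon_range[0] + step / 2, self.lon_range[1], step)
        lat = np.arange(self.lat_range[0] + step / 2, self.lat_range[1], step)
        if lon.size == 0 or lat.size == 0:
            raise ValueError("grid has zero cells at this resolution")
        return lon, lat

    def mean_temperature(self, lat: np.ndarray) -> np.ndarray:
        return self.t_equator_k - self.t_lat_gradient_k_per_deg * np.abs(lat)

    def mean_precipitation(self, lat: np.ndarray) -> np.ndarray:
        c2 = np.cos(np.deg2rad(lat)) ** 2
        return self.p_pole_mm + (self.p_equator_mm - self.p_pole_mm) * c2


def _seasonal_phase(lat: np.ndarray, month_index: np.ndarray) -> np.ndarray:
    """cos term of the annual cycle; peak month 7 (July) for lat >= 0, else 1."""
    peak = np.where(lat >= 0, 6.0, 0.0)  # zero-based month of maximum
    return np.cos(2.0 * np.pi * (month_index - peak) / 12.0)


def djf_minus_jja_amplitude(amplitude_k: float, southern: bool = True) -> float:
    """Closed-form DJF minus JJA mean temperature difference of the generator.

    Averaging the cosine over three months centered on its extremes gives
    2 * A * (1 + 2 cos 30deg) / 3; positive in the Southern Hemisphere.
    """
    factor = (1.0 + 2.0 * np.cos(np.pi / 6.0)) / 3.0
    diff = 2.0 * amplitude_k * factor
    return diff if southern else -diff


def gen_climate_grid(spec: ClimateGridSpec) -> xr.Dataset:
    """Monthly temperature/precipitation/evaporation plus orography.

    Returns an xarray Dataset with variables ``temp`` (K), ``precip`` and
    ``evap`` (mm/month) on dims (month, lat, lon), and ``orog`` (m) on
    (lat, lon); month coordinate 1..12, January first.
    """
    rng = np.random.default_rng(spec.seed)
    lon, lat = spec.grid()
    months = np.arange(12)
    lat2 = lat[None, :, None]  # (1, nlat, 1)
    m3 = months[:, None, None].astype(float)

    base_t = spec.mean_temperature(lat)[None, :, None]
    temp = base_t + spec.seasonal_amplitude_k * _seasonal_phase(lat2, m3)
    temp = np.broadcast_to(temp, (12, lat.size, lon.size)).copy()
    if spec.noise_sd_t > 0:
        temp += rng.normal(0.0, spec.noise_sd_t, temp.shape)

    precip = np.broadcast_to(
        spec.mean_precipitation(lat)[None, :, None], (12, lat.size, lon.size)
    ).copy()
    if spec.noise_sd_p > 0:
        precip += rng.normal(0.0, spec.noise_sd_p, precip.shape)
    precip = np.clip(precip, 0.0, None)

    evap = spec.evap_base_mm + spec.evap_slope_mm_per_k * np.clip(
        temp - spec.evap_offset_k, 0.0, None
    )
    if spec.noise_sd_e > 0:
        evap += rng.normal(0.0, spec.noise_sd_e, evap.shape)
    evap = np.clip(evap, 0.0, None)

    lon_rad = np.deg2rad(lon)[None, :]
    lat_rad = np.deg2rad(lat)[:, None]
    orog = spec.orography_amplitude_m * (np.cos(lon_rad) ** 2) * (np.cos(lat_rad) ** 2)
    orog = np.broadcast_to(orog, (lat.size, lon.size)).copy()

    return xr.Dataset(
        data_vars={
            "temp": (("month", "lat", "lon"), temp),
            "precip": (("month", "lat", "lon"), precip),
            "evap": (("month", "lat", "lon"), evap),
            "orog": (("lat", "lon"), orog),
        },
        coords={"month": np.arange(1, 13), "lat": lat, "lon": lon},
        attrs={"units_temp": "K", "units_precip": "mm/month", "units_evap": "mm/month"},
    )


@dataclass(frozen=True)
class TrueSuitability:
    """Known suitability response to one bioclimatic driver, mapped into [0, 1].

    ``logistic``: 1 / (1 + exp(-slope * (x - center)));
    ``gaussian``: exp(-0.5 * ((x - center) / width)^2).
    """

    var: str
    form: str = "logistic"
    center: float = 0.0
    width: float = 1.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "gaussian"):
            raise ValueError("form must be 'logistic' or 'gaussian'")
        if self.form == "gaussian" and self.width <= 0:
            raise ValueError("gaussian width must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "logistic":
            return 1.0 / (1.0 + np.exp(-self.slope * (x - self.center)))
        return np.exp(-0.5 * ((x - self.center) / self.width) ** 2)


def gen_occurrences(
    suitability: TrueSuitability,
    stack: xr.Dataset,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Presence points sampled cell-wise in proportion to true suitability.

    Cells are drawn with replacement (duplicates are legitimate; spatial
    thinning removes them downstream) and each point sits at its cell center.
    Returns a frame with columns lon, lat.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if suitability.var not in stack.data_vars:
        raise KeyError(f"driver {suitability.var!r} not in stack")
    rng = np.random.default_rng(seed)
    driver = stack[suitability.var].values
    weights = suitability(driver).ravel()
    weights = np.where(np.isfinite(weights), weights, 0.0)
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability surface is zero everywhere")
    idx = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    lat_idx, lon_idx = np.unravel_index(idx, driver.shape)
    return pd.DataFrame(
        {
            "lon": stack["lon"].values[lon_idx],
            "lat": stack["lat"].values[lat_idx],
        }
    )
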