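import numpy as np
import pytest
import xarray as xr

import eoniche as eo


@pytest.fixture(scope="session")
def small_fields():
    """Noise-free 3-degree monthly field set with the default climate shape."""
    spec = eo.ClimateGridSpec(resolution_arcmin=180.0, seed=11)
    return eo.gen_climate_grid(spec)


@pytest.fixture(scope="session")
def small_stack(small_fields):
    return eo.derive_bioclim(small_fields)


@pytest.fixture(scope="session")
def driver_stack():
    """Single-driver stack: Var1 plus three independent noise predictors."""
    rng = np.random.default_rng(77)
    spec = eo.ClimateGridSpec(resolution_arcmin=240.0, noise_sd_t=1.0, seed=77)
    full = eo.derive_bioclim(eo.gen_climate_grid(spec))
    ds = xr.Dataset({"Var1": full["Var1"]})
    for i in range(3):
        ds[f"noise{i + 1}"] = xr.DataArray(
            rng.normal(0.0, 1.0, full["Var1"].shape),
            dims=("lat", "lon"),
            coords={"lat": full["lat"], "lon": full["lon"]},
        )
    return ds


def random_table(rng, max_n=12):
    """Random small abundance table for oracle checks."""
    n = int(rng.integers(2, max_n + 1))
    k = int(rng.integers(1, min(n, 6) + 1))
    cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
    counts = np.diff(np.concatenate([[0], cuts, [n]]))
    return eo.AbundanceTable("t", counts)
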