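import numpy as np
import pytest

from windcross.wind_model import WindField, analysis_times


def make_constant_field(
    u: float,
    v: float,
    lat0: float = -1.0,
    lat1: float = 3.0,
    lon0: float = -1.0,
    lon1: float = 3.0,
    levels=(925.0, 850.0),
    t_start="2016-04-01T00:00",
    n_times: int = 8,
    resolution: float = 0.4,
) -> WindField:
    """A spatially/temporally constant wind field over a small box."""
    times = analysis_times(t_start, n_times)
    lats = np.round(np.arange(lat0, lat1 + resolution / 2, resolution), 6)
    lons = np.round(np.arange(lon0, lon1 + resolution / 2, resolution), 6)
    levels = np.asarray(sorted(levels, reverse=True), dtype=float)
    shape = (len(times), len(levels), len(lats), len(lons))
    return WindField(
        times=times, levels=levels, lats=lats, lons=lons,
        u=np.full(shape, float(u)), v=np.full(shape, float(v)),
    )


@pytest.fixture
def constant_field():
    return make_constant_field


@pytest.fixture(scope="session")
def small_cohort():
    """A shared 2-cycle cohort with deaths, fixes and truth table."""
    from windcross.synthetic_data import (
        CohortConfig, generate_cohort, generate_seasonal_scenario,
    )

    cfg = CohortConfig(n_individuals=30, n_years=2, seed=3)
    fields = generate_seasonal_scenario(cfg)
    fixes, truth = generate_cohort(cfg, fields)
    return cfg, fields, fixes, truth
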