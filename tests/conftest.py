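import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import Polygon

import sekrige as sk

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def district_polygon():
    """50 x 50 km square study area."""
    return sk.square_district(50.0)


@pytest.fixture(scope="session")
def clustered_survey(district_polygon):
    """One simulated stratum under the default study conditions:
    exponential field (c0=40, c1=120, a=5 km), 25 EAs x 10 households."""
    field = sk.FieldSpec(mean=40.0, family="exponential", c0=40.0, c1=120.0,
                         a=5.0, seed=11)
    sampling = sk.SamplingSpec(polygon=district_polygon, n_clusters=25,
                               per_cluster=10, seed=12)
    coords = sk.sample_locations(sampling)
    values = sk.simulate_grf(coords, field)
    return coords, values, field


@pytest.fixture(scope="session")
def small_records():
    """Tiny deterministic record list with inflammation markers."""
    rng = np.random.default_rng(5)
    n = 40
    xs, ys = rng.uniform(0, 10, n), rng.uniform(0, 10, n)
    se = rng.normal(50, 10, n)
    return [
        sk.SurveyRecord(id=f"r{i:02d}", group="wra", district="D", x=float(xs[i]),
                        y=float(ys[i]), se=float(se[i]),
                        crp=float(rng.lognormal(0, 1)),
                        agp=float(rng.lognormal(-0.2, 0.3)))
        for i in range(n)
    ]
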