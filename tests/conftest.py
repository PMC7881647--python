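"""Shared fixtures: a small synthetic survey and fitted models reused across
test modules (session-scoped, so the MCMC cost is paid once)."""

import numpy as np
import pandas as pd
import pytest

from geoprev.inference import ModelSpec, SamplerConfig, fit
from geoprev.model import TemporalSpec
from geoprev.spde import build_mesh
from geoprev.synthetic import SimulationConfig, simulate_survey

DOMAIN = (0.0, 0.0, 120.0, 120.0)
KNOTS = (2007.0, 2010.5, 2014.0)


@pytest.fixture(scope="session")
def small_survey():
    config = SimulationConfig(
        bounds=DOMAIN,
        n_clusters_per_year=60,
        seed=11,
        repeat_locations=True,
        rho=0.0,
        years=(2007.0, 2011.0, 2014.0),
    )
    return simulate_survey(config)


@pytest.fixture(scope="session")
def coarse_mesh():
    corners = np.array([[0.0, 0.0], [120.0, 0.0], [0.0, 120.0], [120.0, 120.0]])
    return build_mesh(corners, max_edge=28.0, extension=30.0)


@pytest.fixture(scope="session")
def fitted_result(small_survey, coarse_mesh):
    spec = ModelSpec(
        covariates=("cov1", "cov2"),
        temporal=TemporalSpec(knots=KNOTS, mode="exchangeable"),
    )
    sampler = SamplerConfig(n_chains=1, n_warmup=150, n_keep=300, seed=5)
    return fit(small_survey.clusters, spec, sampler, mesh=coarse_mesh)


@pytest.fixture(scope="session")
def nofield_data():
    rng = np.random.default_rng(42)
    n = 150
    return pd.DataFrame(
        {
            "cluster_id": [f"c{i}" for i in range(n)],
            "year": 2007.0,
            "x_km": rng.uniform(0, 100, n),
            "y_km": rng.uniform(0, 100, n),
            "n": 40,
            "y": rng.binomial(40, 0.5, n),
        }
    )


@pytest.fixture(scope="session")
def nofield_spec():
    return ModelSpec(
        covariates=(),
        temporal=TemporalSpec(knots=(2007.0,), mode="exchangeable"),
        use_field=False,
        use_lambda=False,
    )
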