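import warnings

import pytest

from urbexpo.fe_model import ModelSpec
from urbexpo.pipeline import MODEL_COVARIATES
from urbexpo.synthetic_city import CityConfig, DGPParams, generate_city

MASTER_SEED = 11


@pytest.fixture(scope="session")
def city():
    """Default-scale synthetic study (33 areas, 147 subzones, 784 women)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_city(CityConfig(seed=MASTER_SEED),
                             DGPParams(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def analysis_table(city):
    return city.to_analysis_frame()


@pytest.fixture(scope="session")
def spec_subzone():
    """Fine-grained fixed effects, planning-area clusters (the main model)."""
    return ModelSpec("PFBS", "exposure_k", MODEL_COVARIATES,
                     fe_level="subzone_id", cluster_level="planning_area_id")


@pytest.fixture(scope="session")
def spec_planning_area():
    return ModelSpec("PFBS", "exposure_k", MODEL_COVARIATES,
                     fe_level="planning_area_id",
                     cluster_level="planning_area_id")
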