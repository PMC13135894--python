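import numpy as np
import pytest

from thermshift import (
    SyntheticClimateSpec,
    SyntheticTPCSpec,
    generate_tpc_observations,
    list_model_forms,
)
from thermshift.fitting import FittedTPC, derive_parameters


@pytest.fixture(scope="session")
def registry():
    return list_model_forms()


def make_fitted(form_name: str, params, t_obs_min: float, t_obs_max: float,
                species: str = "sp", realm: str = "marine") -> FittedTPC:
    """FittedTPC built directly from known parameters (bypasses fitting)."""
    form = list_model_forms()[form_name]
    traits = derive_parameters(form, params, t_obs_min, t_obs_max)
    return FittedTPC(
        species=species, realm=realm, form_name=form_name,
        params=np.asarray(params, float), aicc=0.0, rss=0.0, converged=True,
        rmax=traits.rmax, topt=traits.topt, ctmin=traits.ctmin,
        ctmax=traits.ctmax, q10=traits.q10,
        t_obs_min=t_obs_min, t_obs_max=t_obs_max,
    )


@pytest.fixture(scope="session")
def gaussian_fit():
    """Gaussian curve rmax=1, Topt=20, width=5 as a selected fit."""
    return make_fitted("gaussian", (1.0, 20.0, 5.0), 5.0, 35.0)


@pytest.fixture(scope="session")
def quadratic_fit():
    """-0.01 (T-10)(T-30): vertex (20, 1), roots 10 and 30."""
    return make_fitted("quadratic", (-3.0, 0.4, -0.01), 10.0, 30.0)


@pytest.fixture(scope="session")
def clean_gaussian_obs():
    spec = SyntheticTPCSpec(
        "gaussian", (1.0, 20.0, 5.0), n_temperatures=15,
        temperature_range=(5.0, 35.0), noise_cv=0.0,
    )
    return generate_tpc_observations(spec)


@pytest.fixture()
def small_climate_spec():
    return SyntheticClimateSpec(n_lat=12, n_lon=24, warming_offset=2.0, seed=11)
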