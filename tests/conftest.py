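import numpy as np
import pytest

from twinace.fitting import CorrelatedFactorsParam, FitOptions, fit_model
from twinace.simulate import SimConfig, TraitSpec, simulate_twin_cohort
from twinace.structure import TraitDef

# Generating values for the bivariate continuous-OCS / binary-attempt model:
# heritabilities 0.37 and 0.61, attempt prevalence 6%, aetiological
# correlations rA = 0.42 and rE = 0.13.
BIV_GEN = {
    "a2_ocs": 0.37,
    "a2_att": 0.61,
    "prev_att": 0.06,
    "rA": 0.42,
    "rE": 0.13,
}


def bivariate_config(n_mz: int, n_dz: int, seed: int) -> SimConfig:
    g = BIV_GEN
    traits = [
        TraitSpec("ocs", a2=g["a2_ocs"], e2=1 - g["a2_ocs"]),
        TraitSpec.binary_from_prevalence(
            "att", g["prev_att"], a2=g["a2_att"], e2=1 - g["a2_att"]
        ),
    ]
    r = lambda v: np.array([[1.0, v], [v, 1.0]])
    return SimConfig(n_mz, n_dz, traits, rA=r(g["rA"]), rE=r(g["rE"]), seed=seed)


BIV_TRAITS = [TraitDef("ocs", "continuous"), TraitDef("att", "ordinal")]


@pytest.fixture(scope="session")
def big_bivariate_fit():
    """One large bivariate AE fit at the generating values, shared by the
    recovery and decomposition checks (expensive to build)."""
    data = simulate_twin_cohort(bivariate_config(20000, 20000, seed=1))
    param = CorrelatedFactorsParam(BIV_TRAITS, components="AE")
    fit = fit_model(param, data, FitOptions(n_starts=1))
    assert fit.converged
    return fit
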