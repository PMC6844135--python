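import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from costpaf import cost_models, synthetic
from costpaf.cost_models import DesignInfo, FittedCostModel


@pytest.fixture(scope="session")
def small_config():
    """Three linked cycles at reduced n for fast fitting tests."""
    return synthetic.GeneratorConfig(
        n_per_cycle=2500,
        cycle_years=[2003, 2005, 2007],
        linked_cycle_years=[2003, 2005, 2007],
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort(small_config, seed=11)


@pytest.fixture(scope="session")
def hospital_models(small_cohort):
    """Primary-attribution hospital models for both sexes."""
    return {
        sex: cost_models.fit_cost_model(small_cohort, sex, "hospital", 3)
        for sex in ("male", "female")
    }


def make_toy_model(
    variable="smoking",
    levels=("non", "heavy"),
    coefs=None,
    intercept=0.0,
    sex="male",
    sector="hospital",
):
    """Hand-built single-variable cost model for closed-form PAF checks."""
    coefs = coefs or {}
    levels = list(levels)
    columns = [f"{variable}[{l}]" for l in levels[1:]]
    info = DesignInfo(
        variables=[variable], levels={variable: levels}, columns=columns
    )
    coefficients = {"Intercept": float(intercept)}
    for l in levels[1:]:
        coefficients[f"{variable}[{l}]"] = float(coefs.get(l, 0.0))
    return FittedCostModel(
        sex=sex, sector=sector, step=3,
        coefficients=coefficients, dispersion=1.0, design=info,
    )


def toy_cohort(levels, weights=None, sex="male", variable="smoking"):
    """Minimal cohort frame for toy-model PAF computations."""
    n = len(levels)
    return pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": [sex] * n,
            variable: list(levels),
            "weight": weights if weights is not None else np.ones(n),
            "person_years": np.ones(n),
        }
    )
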