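import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ordsmooth import BpdLikeConfig, ModelSpec, OrdinalTerm, generate_bpd_like

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CONFOUNDERS = ("weight_g", "sga", "sex_male", "multiples", "steroid_days", "antibiotic_days")


@pytest.fixture(scope="session")
def bpd_null_table():
    """BPD-like cohort with no ordinal effects (all three predictors null)."""
    config = BpdLikeConfig(
        n=100, seed=42,
        ordinal_effects={"gram_neg": "null", "gram_pos": "null", "pathogenic": "null"},
    )
    table, truth = generate_bpd_like(config)
    return table, truth


@pytest.fixture(scope="session")
def confounder_spec():
    return ModelSpec("bpd", "binomial", CONFOUNDERS, ())


@pytest.fixture(scope="session")
def full_spec():
    """Model shape of the motivating cohort analysis: six confounders plus
    three 7-level ordinal smooths with the second-order penalty."""
    return ModelSpec(
        "bpd", "binomial", CONFOUNDERS,
        (OrdinalTerm("gram_neg", 7, 2), OrdinalTerm("gram_pos", 7, 2),
         OrdinalTerm("pathogenic", 7, 2)),
    )


@pytest.fixture(scope="session")
def simple_glm_table():
    """Small well-conditioned binomial dataset: one 5-level ordinal
    predictor with a linear effect plus one continuous covariate."""
    from ordsmooth import generate_ordinal_glm

    table, truth = generate_ordinal_glm(300, 5, "binomial", "linear", seed=3, amplitude=1.5)
    rng = np.random.default_rng(99)
    table["z1"] = rng.normal(size=len(table))
    return table, truth
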