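import numpy as np
import pytest

from chfpheno.cohort import ScreeningGroup
from chfpheno.synth_ehr import GeneratorConfig, generate_cohort


def make_config(**overrides) -> GeneratorConfig:
    """Small, class-balanced generator config for fast unit tests.

    Uses equal group weights and annotated-sample-like prevalences so tiny
    cohorts still contain both classes; short notes keep text processing
    cheap.  Population-mix defaults are exercised in the acceptance tests.
    """
    base = dict(
        n_patients=300,
        group_weights={g: 0.25 for g in ScreeningGroup},
        positive_prevalence_per_group={
            ScreeningGroup.ICD_POS_MED_POS: 0.45,
            ScreeningGroup.ICD_POS_MED_NEG: 0.50,
            ScreeningGroup.ICD_NEG_MED_POS: 0.15,
            ScreeningGroup.ICD_NEG_MED_NEG: 0.12,
        },
        note_length_range=(300, 900),
        seed=123,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def enriched_cohort():
    return generate_cohort(make_config())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
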