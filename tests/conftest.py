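import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from beefdmi import Dataset, GeneratorConfig, generate_dataset
from beefdmi.simulate import StageConfig, VariableSpec

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

#: coefficients of the fitted direct-DMI model (stage, NEm, SBW^0.75, intercept)
DMI_TRUTH = {"stage": 3.27, "nem": 9.21, "mbw": 0.133, "intercept": -14.38}
#: coefficients of the fitted NEMI model
NEMI_TRUTH = {"nem": 0.224, "stage": 0.0346, "intercept": -0.142}


def scaled_config(n_nonlactating, n_lactating, **kwargs) -> GeneratorConfig:
    """Default study conditions with the per-stage counts rescaled."""
    base = GeneratorConfig()
    return GeneratorConfig(
        nonlactating=StageConfig(
            n=n_nonlactating, sbw=base.nonlactating.sbw, nem=base.nonlactating.nem,
            bcs=base.nonlactating.bcs,
        ),
        lactating=StageConfig(
            n=n_lactating, sbw=base.lactating.sbw, nem=base.lactating.nem,
            bcs=base.lactating.bcs, milk=base.lactating.milk,
        ),
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_dataset() -> Dataset:
    """One paper-sized synthetic dataset (53 + 32 means) under the defaults."""
    return generate_dataset(GeneratorConfig(), seed=20240104)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(8675309)
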