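import pytest

from cvdprev.domain import RiskLevel
from cvdprev.synthetic import SyntheticSpec, generate_parameter_set


@pytest.fixture(scope="session")
def params_high():
    """Synthetic high-risk CVD (no diabetes) parameter set."""
    return generate_parameter_set(SyntheticSpec(seed=7, model="cvd", risk_level=RiskLevel.high))


@pytest.fixture(scope="session")
def params_diab_moderate():
    """Synthetic moderate-risk diabetes-model parameter set."""
    return generate_parameter_set(
        SyntheticSpec(seed=7, model="cvd_with_diabetes", risk_level=RiskLevel.moderate)
    )


@pytest.fixture()
def params_high_copy(params_high):
    return params_high.copy()
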