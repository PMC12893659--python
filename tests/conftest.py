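import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

from doadapt import ModelParams


@pytest.fixture
def linear_params() -> ModelParams:
    """Linear DO model (no saturations, no learning transfer): the regime
    with exact closed forms."""
    return ModelParams(K=0.25, F=0.7, psi0=1.0, b_w=0.0, A_f=0.9,
                       A_fn=0.95, L0=1.1, b_f=0.0, L_f=0.0, F_n=1.0)
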