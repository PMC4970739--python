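import pytest
from hypothesis import settings

from cdxcea import evaluate
from cdxcea.synthetic_data import build_reference_study

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref_study():
    """Synthetic reference study: validated config + curves per branch."""
    return build_reference_study()


@pytest.fixture(scope="session")
def base_result(ref_study):
    cfg, curves = ref_study
    return evaluate(cfg, curves)
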