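import pytest

from habitpoints import ModelParams


@pytest.fixture
def params():
    """The example application's parameters: alpha=0.1, theta=0.9, M=13."""
    return ModelParams()
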