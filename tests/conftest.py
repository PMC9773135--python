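import pytest

from escc_cea import load_parameters


@pytest.fixture(scope="session")
def ps():
    """The packaged base-case parameter set (session-wide, treated read-only)."""
    return load_parameters("builtin")
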