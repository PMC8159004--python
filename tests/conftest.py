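import pytest

from cvdshock import fixture_bundle


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic input set shared across the suite."""
    return fixture_bundle(seed=1)


@pytest.fixture(scope="session")
def base_case_result(bundle):
    """Base-case analysis at default settings, computed once."""
    from cvdshock import run_analysis

    return run_analysis(bundle, "base_case")
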