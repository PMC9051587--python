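import pytest
from hypothesis import settings

from genora.synthetic import vitamin_cakut_fixture

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """File-based synthetic study fixture, written once per session."""
    out = tmp_path_factory.mktemp("study_fixture")
    return vitamin_cakut_fixture(seed=12345, out_dir=out)
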