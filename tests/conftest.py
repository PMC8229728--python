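import pytest
from hypothesis import HealthCheck, settings

from si_karyosim.genetics import Locus

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def biallelic():
    """The canonical uniform biallelic incompatibility locus."""
    return Locus.uniform("X", 2)


@pytest.fixture
def triallelic():
    """The canonical uniform triallelic incompatibility locus."""
    return Locus.uniform("X", 3)
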