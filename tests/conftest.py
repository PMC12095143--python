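import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dosagenet import ComponentMap, chong_he_fixture  # noqa: E402


@pytest.fixture(scope="session")
def chong_he():
    return chong_he_fixture()


@pytest.fixture
def simple_map():
    """Two drugs with disjoint metabolite sets (no sharing)."""
    return ComponentMap(
        drug_to_metabolites={"drugA": {"m1", "m2"}, "drugB": {"m3"}},
        metabolite_to_targets={
            "m1": {"T1", "T2"},
            "m2": {"T2"},
            "m3": {"T3"},
        },
    )
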