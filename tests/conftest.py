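import pytest
from hypothesis import HealthCheck, settings

from cazhotspot.observation import ObservationInstance, ObservationKey, normalize_ec
from cazhotspot.substrate import SubstrateMap, SubstrateMapEntry

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def key(ec: str, family: str) -> ObservationKey:
    return ObservationKey(normalize_ec(ec), family)


def inst(genome: str, protein: str, ec: str, family: str) -> ObservationInstance:
    return ObservationInstance(genome, protein, key(ec, family))


@pytest.fixture
def tiny_map() -> SubstrateMap:
    """A small hand-checkable map exercising every specificity tier and the
    half-count rule."""
    return SubstrateMap(
        [
            SubstrateMapEntry("3.2.1.4", "*", frozenset({"cellulose"})),
            SubstrateMapEntry("3.2.1.4", "GH12", frozenset({"cellulose"})),
            SubstrateMapEntry("3.2.1.8", "*", frozenset({"xylan"})),
            SubstrateMapEntry("3.2.1.15", "*", frozenset({"pectin"})),
            SubstrateMapEntry("1.10.3.2", "*", frozenset({"lignin"})),
            SubstrateMapEntry("3.1.1.73", "*", frozenset({"xylan", "pectin"})),
            SubstrateMapEntry("*", "GH28", frozenset({"pectin"})),
        ]
    )
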