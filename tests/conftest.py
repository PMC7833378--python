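import pytest
from hypothesis import HealthCheck, settings

from coulombgas import ValencyPair
from coulombgas.surface.actions import ActionEngine

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ALL_PAIRS = [(1, 1), (2, 1), (3, 1), (4, 1), (3, 2)]

_ENGINES: dict[tuple[int, int], ActionEngine] = {}


@pytest.fixture
def engine_for():
    """Session-cached action engines: continuations accumulate across tests."""

    def get(pair) -> ActionEngine:
        pair = tuple(pair)
        if pair not in _ENGINES:
            _ENGINES[pair] = ActionEngine(ValencyPair(*pair))
        return _ENGINES[pair]

    return get


@pytest.fixture(params=ALL_PAIRS, ids=lambda p: f"{p[0]}{p[1]}")
def valency_pair(request) -> ValencyPair:
    return ValencyPair(*request.param)
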