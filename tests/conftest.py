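from __future__ import annotations

from datetime import date, datetime, timezone

import pytest

from nomenreg.acts import Code, Registry
from nomenreg.fixtures import FixtureSpec, generate_manuscript
from nomenreg.registry import Clock, RegistryStore
from nomenreg.taxpub import parse_manuscript

PUB_DAY = datetime(2016, 1, 7, tzinfo=timezone.utc)
PUB_DATE = date(2016, 1, 7)
ARTICLE_LINK = "https://journals.example.org/article/1"


def make_store(registry: Registry = Registry.ZOOBANK, seed: int = 0, path=None) -> RegistryStore:
    """Store with a clock already standing on publication day, so release
    timing is not what an unrelated test exercises."""
    return RegistryStore(registry, clock=Clock(PUB_DAY), seed=seed, path=path)


@pytest.fixture
def zoobank() -> RegistryStore:
    return make_store(Registry.ZOOBANK)


@pytest.fixture
def mycobank() -> RegistryStore:
    return make_store(Registry.MYCOBANK)


def gen(spec: FixtureSpec):
    xml, manifest = generate_manuscript(spec)
    return xml, manifest, parse_manuscript(xml)


@pytest.fixture(scope="session")
def seeded_fixtures():
    """One small manuscript per seed, shared by the round-trip suites."""
    out = []
    for seed in range(100):
        spec = FixtureSpec(n_acts=1 + seed % 6, seed=seed, code=Code.ICZN)
        out.append((spec, *gen(spec)))
    return out
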