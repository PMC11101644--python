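import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from emtmap import infer_rules, emt_core_fixture
from emtmap.map_model import Interaction, RegulatoryMap, SpeciesNode
from emtmap.phenotype import default_marker_config


def build_map(edges, nodes=None, kinds=None):
    """Small-map builder: edges as (source, sign, target) triples."""
    if nodes is None:
        nodes = sorted({n for s, _, t in edges for n in (s, t)})
    kinds = kinds or {}
    species = [SpeciesNode(n, n, kinds.get(n, "unknown")) for n in nodes]
    interactions = [
        Interaction(f"e{i + 1:03d}", (s,), t, sign=sg) for i, (s, sg, t) in enumerate(edges)
    ]
    return RegulatoryMap(species, interactions)


@pytest.fixture(scope="session")
def emt_map():
    return emt_core_fixture()


@pytest.fixture(scope="session")
def emt_model(emt_map):
    return infer_rules(emt_map)


@pytest.fixture(scope="session")
def markers():
    return default_marker_config()
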