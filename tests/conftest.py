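import random

import pytest
from hypothesis import HealthCheck, settings

from coalearn import AssociationNetwork, LearningModel, MergeRule, PairList

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def halfway_rule():
    return MergeRule(name="halfway", sigma0=0.5)


@pytest.fixture
def rw_rule():
    return MergeRule(name="rescorla_wagner", default_alpha=0.3, beta=1.0, lam=1.0)


@pytest.fixture
def halfway_model(halfway_rule):
    return LearningModel(merge=halfway_rule)


def random_pairlist(rng: random.Random, n: int, n_vocab: int = 8) -> PairList:
    """A random elemental pair list over small cue/target vocabularies."""
    cues = [f"c{i}" for i in range(n_vocab)]
    targets = [f"t{i}" for i in range(n_vocab)]
    return PairList.from_pairs(
        (rng.choice(cues), rng.choice(targets)) for _ in range(n)
    )


def random_network(rng: random.Random, n_edges: int = 5) -> AssociationNetwork:
    edges = {}
    for _ in range(n_edges):
        s = f"v{rng.randrange(6)}"
        t = f"w{rng.randrange(6)}"
        edges[(s, t)] = (rng.random(), rng.randrange(1, 4))
    return AssociationNetwork.from_edges(
        (s, t, sigma, count) for (s, t), (sigma, count) in edges.items()
    )
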