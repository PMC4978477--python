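"""Built-in worked examples and a seeded generator of list-learning conditions.

The fixtures are the small training lists used throughout the package's
documentation and tests: the three-pair bread/butter list, the two
word→shape rote-learning maps ws1 and ws2, the colour×shape configural
discrimination ca (an XOR over two binary attributes, learnable only when
conjunction vertices are representable), and species-typed network types
modelling narrow learning selectivity (rats: odour→food but not
colour→food; quail: colour-based but not odour-based aversion; pigeons:
colour→food and tone→shock-avoidance but not the crossed signatures).

Shape and suit glyphs are kept verbatim as Unicode vertex ids — they
exercise the Unicode-id contract — with ASCII aliases in the fixture
metadata.  Every ``expected`` block is documentation, not the source of
truth: the test suite re-derives edge counts and recall tables from the
pair list via the learning models.

``generate_pairlist`` produces the two classical two-list rote-learning
designs: [AB, CD] (second list entirely fresh) and [AB, ABr] (second list
re-pairs the first list's cues and targets under a derangement, so no pair
repeats).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .learning import PairList, TrainingEvent, conjunction_id, encode_trial
from .network import NetworkType

__all__ = [
    "Fixture",
    "available_fixtures",
    "fixture",
    "generate_pairlist",
]


@dataclass(frozen=True)
class Fixture:
    name: str
    pair_list: PairList
    network_type: NetworkType
    expected: Mapping[str, object] = field(default_factory=dict)
    aliases: Mapping[str, str] = field(default_factory=dict)
    description: str = ""


# ---------------------------------------------------------------------------
# Network types
# ---------------------------------------------------------------------------

_WORDS = frozenset(
    {"bell", "kite", "tent", "yacht", "goat", "lion", "mule", "toad"}
)
_SHAPES = frozenset({"□", "△", "♡", "◇", "▴", "◾", "♣", "♠"})

#: Word→shape networks shared by ws1 and ws2 (the list type G_WS).
WORD_SHAPE_TYPE = NetworkType(
    name="word_shape",
    classes={"word": _WORDS, "shape": _SHAPES},
    allowed_signatures={("word", "shape")},
)

#: Free association over an open item vocabulary (bread/butter example).
FREE_TYPE = NetworkType(
    name="free",
    classes={"item": frozenset()},
    allowed_signatures={("item", "item")},
    configural=True,
    default_class="item",
)

_CA_MAP: tuple[tuple[tuple[str, str], str], ...] = (
    (("black", "square"), "+"),
    (("black", "triangle"), "−"),
    (("white", "square"), "−"),
    (("white", "triangle"), "+"),
)

_CA_CONJUNCTIONS = frozenset(conjunction_id(attrs) for attrs, _ in _CA_MAP)

#: Elemental colour/shape→response networks: no conjunction vertices.
ELEMENTAL_TYPE = NetworkType(
    name="G_E",
    classes={
        "colour": frozenset({"black", "white"}),
        "shape": frozenset({"square", "triangle"}),
        "response": frozenset({"+", "−"}),
    },
    allowed_signatures={("colour", "response"), ("shape", "response")},
    configural=False,
)

#: Configural variant: conjunction vertices representable.
CONFIGURAL_TYPE = NetworkType(
    name="G_C",
    classes={
        "colour": frozenset({"black", "white"}),
        "shape": frozenset({"square", "triangle"}),
        "response": frozenset({"+", "−"}),
        "conjunction": _CA_CONJUNCTIONS,
    },
    allowed_signatures={
        ("colour", "response"),
        ("shape", "response"),
        ("conjunction", "response"),
    },
    configural=True,
)

_OPEN_STIMULI = {
    "odour": frozenset(),
    "colour": frozenset(),
    "tone": frozenset(),
    "food": frozenset(),
    "illness": frozenset(),
    "shock_avoidance": frozenset(),
}

#: Rats: odour→food associations learnable, colour→food and tone→food not.
RAT_TYPE = NetworkType(
    name="G_Rat",
    classes=_OPEN_STIMULI,
    allowed_signatures={("odour", "food")},
)

#: Quail: colour-based (not odour-based) learning — colour→food and the
#: coloured-water→illness aversion; odour signatures absent.
QUAIL_TYPE = NetworkType(
    name="G_Quail",
    classes=_OPEN_STIMULI,
    allowed_signatures={("colour", "food"), ("colour", "illness")},
)

#: Pigeons: colour→food and tone→shock-avoidance, never the crossed pairs.
PIGEON_TYPE = NetworkType(
    name="G_Pigeon",
    classes=_OPEN_STIMULI,
    allowed_signatures={("colour", "food"), ("tone", "shock_avoidance")},
)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

_SHAPE_ALIASES = {
    "□": "white_square",
    "△": "white_triangle",
    "♡": "heart",
    "◇": "diamond",
    "▴": "black_triangle",
    "◾": "black_square",
    "♣": "club",
    "♠": "spade",
    "∧": "AND",
    "−": "minus",
}


def _build_fixtures() -> dict[str, Fixture]:
    fixtures: dict[str, Fixture] = {}

    fixtures["bread_butter"] = Fixture(
        name="bread_butter",
        pair_list=PairList.from_pairs(
            [("bread", "butter"), ("knife", "fork"), ("knife", "butter")]
        ),
        network_type=FREE_TYPE,
        expected={
            "snapshots": 3,
            "g1_edges": 1,
            "final_edges": 3,
            "knife_out_degree": 2,
            "recall": {"bread": "butter"},
            "knife_tie_set": {"fork", "butter"},
        },
        description="Three-pair free-association list; the canonical "
        "external-memory learning trace [g1, g2, g3].",
    )

    ws1_pairs = [("bell", "□"), ("kite", "△"), ("tent", "♡"), ("yacht", "◇")]
    fixtures["ws1"] = Fixture(
        name="ws1",
        pair_list=PairList.from_pairs(ws1_pairs),
        network_type=WORD_SHAPE_TYPE,
        expected={
            "snapshots": 4,
            "final_edges": 4,
            "recall": dict(ws1_pairs),
        },
        aliases=_SHAPE_ALIASES,
        description="First word→shape rote-learning map (training order: "
        "the mapping's printed order, from the partially printed list).",
    )

    # training order partially printed as [(toad, ♠), (lion, ◾), ...];
    # the remainder follows the mapping's printed order (goat, mule)
    ws2_pairs = [("toad", "♠"), ("lion", "◾"), ("goat", "▴"), ("mule", "♣")]
    fixtures["ws2"] = Fixture(
        name="ws2",
        pair_list=PairList.from_pairs(ws2_pairs),
        network_type=WORD_SHAPE_TYPE,
        expected={
            "snapshots": 4,
            "final_edges": 4,
            "recall": {"goat": "▴", "lion": "◾", "mule": "♣", "toad": "♠"},
        },
        aliases=_SHAPE_ALIASES,
        description="Second word→shape map; structurally equivalent to ws1 "
        "with entirely fresh cues and targets.",
    )

    ca_events = tuple(
        ev
        for attrs, out in _CA_MAP
        for ev in encode_trial("configural", attrs, out, CONFIGURAL_TYPE)
    )
    fixtures["configural_ca"] = Fixture(
        name="configural_ca",
        pair_list=PairList(ca_events, schema="configural"),
        network_type=CONFIGURAL_TYPE,
        expected={
            "snapshots": 4,
            "final_edges": 4,
            "mapping": _CA_MAP,
            "recall": {conjunction_id(attrs): out for attrs, out in _CA_MAP},
        },
        aliases=_SHAPE_ALIASES,
        description="Colour×shape→response discrimination (an XOR): no "
        "single attribute predicts the response, only the conjunction.",
    )

    fixtures["rat_odour_food"] = Fixture(
        name="rat_odour_food",
        pair_list=PairList.from_pairs(
            [("odour:almond", "food:pellet"), ("odour:banana", "food:pellet")]
        ),
        network_type=RAT_TYPE,
        expected={"snapshots": 2, "final_edges": 2},
        description="Rat-typed networks: odour→food learnable; colour→food "
        "and tone→food signatures are absent, so such lists are refused.",
    )

    fixtures["quail_colour_water"] = Fixture(
        name="quail_colour_water",
        pair_list=PairList.from_pairs(
            [("colour:blue", "illness:nausea")]
        ),
        network_type=QUAIL_TYPE,
        expected={"snapshots": 1, "final_edges": 1},
        description="Quail-typed networks: colour-based aversion (coloured "
        "water followed by illness) learnable; odour-based is not.",
    )

    fixtures["pigeon_selectivity"] = Fixture(
        name="pigeon_selectivity",
        pair_list=PairList.from_pairs(
            [("colour:red", "food:grain"), ("tone:buzzer", "shock_avoidance:jump")]
        ),
        network_type=PIGEON_TYPE,
        expected={"snapshots": 2, "final_edges": 2},
        description="Pigeon-typed networks: colour→food and "
        "tone→shock-avoidance learnable, but not tone→food or "
        "colour→shock-avoidance.",
    )

    return fixtures


_FIXTURES = _build_fixtures()


def available_fixtures() -> tuple[str, ...]:
    return tuple(sorted(_FIXTURES))


def fixture(name: str) -> Fixture:
    """Look up a built-in fixture by name.

    Raises ``KeyError`` listing the available names on an unknown name.
    """
    try:
        return _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        ) from None


# ---------------------------------------------------------------------------
# Synthetic list-learning conditions
# ---------------------------------------------------------------------------


def _derangement(n: int, rng: random.Random) -> list[int]:
    """A permutation of range(n) with no fixed point, seeded and total.

    Rejection-samples shuffles (expected ~e attempts); falls back to a
    rotation after 200 rejections so the function always terminates.
    n == 1 has no derangement and is rejected by the caller.
    """
    idx = list(range(n))
    for _ in range(200):
        perm = idx[:]
        rng.shuffle(perm)
        if all(perm[i] != i for i in range(n)):
            return perm
    return [(i + 1) % n for i in range(n)]


def generate_pairlist(
    cues: Sequence[str],
    targets: Sequence[str],
    n_pairs: int,
    condition: str,
    seed: int = 0,
) -> tuple[PairList, PairList]:
    """Generate the two lists of a two-list rote-learning design.

    ``AB_CD``: the second list draws entirely fresh cues and targets
    (requires vocabularies of at least 2·n_pairs).  ``AB_ABr``: the second
    list re-pairs the first list's cues and targets under a derangement, so
    the vertex sets coincide but no (cue, target) pair repeats (requires
    n_pairs ≥ 2 and vocabularies of at least n_pairs).  Deterministic under
    ``seed``.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be positive")
    if condition not in ("AB_CD", "AB_ABr"):
        raise ValueError(f"unknown condition {condition!r}; use AB_CD or AB_ABr")
    cues = list(dict.fromkeys(cues))
    targets = list(dict.fromkeys(targets))
    need = 2 * n_pairs if condition == "AB_CD" else n_pairs
    if len(cues) < need or len(targets) < need:
        raise ValueError(
            f"condition {condition} with n_pairs={n_pairs} needs at least "
            f"{need} distinct cues and targets (got {len(cues)} cues, "
            f"{len(targets)} targets)"
        )
    if condition == "AB_ABr" and n_pairs < 2:
        raise ValueError("AB_ABr requires n_pairs >= 2 (no derangement of 1)")
    rng = random.Random(seed)
    chosen_cues = rng.sample(cues, need)
    chosen_targets = rng.sample(targets, need)
    c1, t1 = chosen_cues[:n_pairs], chosen_targets[:n_pairs]
    list1 = PairList.from_pairs(zip(c1, t1))
    if condition == "AB_CD":
        c2, t2 = chosen_cues[n_pairs:], chosen_targets[n_pairs:]
        list2 = PairList.from_pairs(zip(c2, t2))
    else:
        perm = _derangement(n_pairs, rng)
        list2 = PairList.from_pairs((c1[i], t1[perm[i]]) for i in range(n_pairs))
    return list1, list2
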