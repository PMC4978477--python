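"""Associative-learning anamorphisms, trial encodings and rote-learning loops.

The external-memory model ``learn_ext`` treats the association network as an
explicit input: it builds the coalgebra whose halting predicate is "the pair
list is empty", whose emission is the merge μ of the first pair into the
current network, and whose next-state map is ν = ⟨τ, μ⟩ (drop the head of
the pair list, keep the merged network), then unfolds it.  The result is the
temporal snapshot stream [g1, ..., gn] — one network per training event,
with the initial network g0 excluded (it is the caller's input).

The internal-memory model ``learn_int`` is the exponential transpose of
``learn_ext``: a function from pair lists to network-transformers, extension-
ally equal to the external model by the currying bijection.

``rlearn_fold`` and ``ilearn_loop`` are the classical recursive/iterative
productions of the same computation; they only expose the *final* network
and serve as independent equivalence oracles for the anamorphism.

``encode_trial`` mediates the elemental/configural contrast: an elemental
encoding of a multi-attribute stimulus emits one event per attribute (each
cue independently predictive), while a configural encoding builds a single
conjunction vertex — which requires a network type where conjunctions are
representable.  ``train_to_criterion`` runs rote-learning blocks until the
recall test passes a criterion, with recall ties counting as incorrect so
chance behaviour can never pass.
"""

from __future__ import annotations

import functools
import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .corecursion import Coalgebra, Stream, transpose, unfold
from .network import (
    AssociationNetwork,
    MergeRule,
    NetworkType,
    TypeViolationError,
    apply_merge,
    recall,
    validate_pair,
)

__all__ = [
    "AblatedModelError",
    "CONJUNCTION_SEP",
    "LearningModel",
    "PairList",
    "TrainingEvent",
    "TrainingResult",
    "ablate_common_component",
    "conjunction_id",
    "encode_trial",
    "ilearn_loop",
    "learn_ext",
    "learn_int",
    "rlearn_fold",
    "train_to_criterion",
]

#: Separator used to build configural conjunction vertex ids.
CONJUNCTION_SEP = "∧"


class AblatedModelError(RuntimeError):
    """The common learning component was ablated: no learn_* call can run."""


@dataclass(frozen=True)
class TrainingEvent:
    """One training event: cue(s), a target, and an optional asymptote λ.

    ``cues`` is a non-empty tuple of vertex ids.  Under the halfway rule an
    event must carry exactly one cue; the Rescorla–Wagner rule treats the
    whole tuple as the compound of cues present on the trial.
    """

    cues: tuple[str, ...]
    target: str
    lam: float | None = None

    def __post_init__(self):
        if isinstance(self.cues, str):
            object.__setattr__(self, "cues", (self.cues,))
        else:
            object.__setattr__(self, "cues", tuple(self.cues))
        if not self.cues:
            raise ValueError("training event requires a non-empty cue spec")

    @classmethod
    def pair(cls, cue: str, target: str, lam: float | None = None) -> "TrainingEvent":
        return cls((cue,), target, lam)


@dataclass(frozen=True)
class PairList:
    """Ordered finite list of training events (the object P)."""

    events: tuple[TrainingEvent, ...]
    schema: str = "elemental"

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        if self.schema not in ("elemental", "configural"):
            raise ValueError(f"unknown schema {self.schema!r}")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], schema: str = "elemental"
    ) -> "PairList":
        return cls(tuple(TrainingEvent.pair(c, t) for c, t in pairs), schema)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return PairList(self.events[i], self.schema)
        return self.events[i]


@dataclass(frozen=True)
class LearningModel:
    """Merge rule + network type + step budget, optionally ablated."""

    merge: MergeRule = field(default_factory=MergeRule)
    network_type: NetworkType | None = None
    budget: int = 10_000
    ablated: bool = False


def _merge_event(
    event: TrainingEvent, network: AssociationNetwork, rule: MergeRule
) -> AssociationNetwork:
    if rule.name == "halfway":
        if len(event.cues) != 1:
            raise ValueError(
                f"halfway rule takes one cue per event, got {event.cues!r}"
            )
        return apply_merge((event.cues[0], event.target), network, rule)
    return apply_merge((event.cues, event.target, event.lam), network, rule)


def _check_events(model: LearningModel, pairs: PairList) -> None:
    if model.ablated:
        raise AblatedModelError(
            "common component unavailable: the merge morphism was ablated, so "
            "no associative learning capacity factoring through it remains"
        )
    for i, ev in enumerate(pairs):
        for cue in ev.cues:
            result = validate_pair(model.network_type, (cue, ev.target))
            if not result:
                raise TypeViolationError(f"event {i}: {result.message}")


def learn_ext(
    model: LearningModel, pairs: PairList, g0: AssociationNetwork
) -> Stream:
    """External-memory learning anamorphism.

    Unfolds the coalgebra (halt = e?, emit = μ(firstpair, g), ν = ⟨τ, μ⟩)
    from (pairs, g0) and returns the snapshot stream [g1, ..., gn], one
    network per event, g0 excluded.  Snapshot k depends only on the first
    k events.  Type-violating lists are refused up front — partial learning
    would misstate what "no merge function defined" means — and an ablated
    model refuses every list.
    """
    _check_events(model, pairs)
    if model.budget < len(pairs):
        raise ValueError(
            f"budget {model.budget} below pair-list length {len(pairs)}"
        )
    rule = model.merge

    def halt(state) -> bool:
        remaining, _g = state
        return len(remaining) == 0

    def emit(state) -> AssociationNetwork:
        remaining, g = state
        return _merge_event(remaining[0], g, rule)

    def next_state(state):
        remaining, g = state
        return (remaining[1:], _merge_event(remaining[0], g, rule))

    coalg = Coalgebra(halt=halt, emit=emit, next_state=next_state, name="learn_ext")
    return unfold(coalg, (tuple(pairs.events), g0), max_steps=model.budget)


def learn_int(model: LearningModel, pairs: PairList):
    """Internal-memory model: the exponential transpose of :func:`learn_ext`.

    ``learn_int(model, pairs)(g0)`` equals ``learn_ext(model, pairs, g0)``
    elementwise for every initial network g0.  Validation still happens at
    call time, before the curried function is returned.
    """
    _check_events(model, pairs)
    m_ext = functools.partial(learn_ext, model)
    return transpose(m_ext)(pairs)


# ---------------------------------------------------------------------------
# Trial encoding: elemental vs configural
# ---------------------------------------------------------------------------


def conjunction_id(attributes: Sequence[str]) -> str:
    """Canonical conjunction vertex id for a tuple of attribute values.

    Values are joined with ``∧`` in sorted order, so any presentation order
    of the same attributes yields the same vertex (e.g. ("square", "black")
    and ("black", "square") both give ``black∧square``).
    """
    return CONJUNCTION_SEP.join(sorted(attributes))


def encode_trial(
    schema: str,
    stimulus: str | Sequence[str],
    outcome: str,
    network_type: NetworkType | None = None,
    lam: float | None = None,
) -> tuple[TrainingEvent, ...]:
    """Encode one stimulus→outcome trial into training events.

    Elemental: a single-id stimulus gives one event; a multi-attribute
    stimulus gives one event per attribute, each cue independently
    predictive of the outcome.  Configural: the attribute tuple becomes a
    single conjunction vertex, which requires ``network_type.configural``
    when a type is supplied.
    """
    if schema not in ("elemental", "configural"):
        raise ValueError(f"unknown schema {schema!r}")
    attrs = (stimulus,) if isinstance(stimulus, str) else tuple(stimulus)
    if not attrs:
        raise ValueError("empty stimulus")
    if schema == "elemental":
        return tuple(TrainingEvent.pair(a, outcome, lam) for a in attrs)
    if network_type is not None and not network_type.configural:
        raise TypeViolationError(
            f"unrepresentable conjunction: network type {network_type.name!r} "
            "has no conjunction vertices (configural=False)"
        )
    return (TrainingEvent.pair(conjunction_id(attrs), outcome, lam),)


# ---------------------------------------------------------------------------
# Rote learning to criterion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingResult:
    network: AssociationNetwork
    blocks_used: int | None  # None when the criterion was never reached
    accuracy: float  # fraction correct on the last test block

    @property
    def succeeded(self) -> bool:
        return self.blocks_used is not None


def train_to_criterion(
    model: LearningModel,
    mapping: Sequence[tuple[str | Sequence[str], str]],
    criterion: float = 1.0,
    max_blocks: int = 25,
    seed: int = 0,
    schema: str = "elemental",
    g0: AssociationNetwork | None = None,
) -> TrainingResult:
    """Rote-learn a functional stimulus→outcome mapping in shuffled blocks.

    Each block presents every mapping entry once (order shuffled by the
    seeded generator), learning with :func:`learn_ext` from the network
    accumulated so far, then runs a full recall test: every encoded cue must
    predict its outcome outright — a tie counts as incorrect, so chance
    behaviour cannot pass.  Stops when the fraction correct reaches
    ``criterion`` or after ``max_blocks`` blocks.
    """
    stimuli = [s for s, _ in mapping]
    if len({tuple(s) if not isinstance(s, str) else s for s in stimuli}) != len(stimuli):
        raise ValueError("mapping must be functional: each stimulus one outcome")
    encoded = [
        encode_trial(schema, stim, out, model.network_type) for stim, out in mapping
    ]
    test_items = [
        (cue, out)
        for events, (_stim, out) in zip(encoded, mapping)
        for ev in events
        for cue in ev.cues
    ]
    rng = random.Random(seed)
    network = g0 if g0 is not None else AssociationNetwork.empty()
    accuracy = 0.0
    for block in range(1, max_blocks + 1):
        order = list(range(len(encoded)))
        rng.shuffle(order)
        events = tuple(ev for i in order for ev in encoded[i])
        stream = learn_ext(model, PairList(events, schema), network)
        if len(stream):
            network = stream[-1]
        correct = 0
        for cue, expected in test_items:
            r = recall(network, cue)
            if r.prediction == expected and not r.is_tie:
                correct += 1
        accuracy = correct / len(test_items) if test_items else 1.0
        if accuracy >= criterion:
            return TrainingResult(network, block, accuracy)
    return TrainingResult(network, None, accuracy)


# ---------------------------------------------------------------------------
# Classical productions: recursive and iterative learning oracles
# ---------------------------------------------------------------------------


def rlearn_fold(
    pairs: PairList, network: AssociationNetwork, update: MergeRule
) -> AssociationNetwork:
    """Recursive production: (emptylist, g) ↦ g; else recurse on
    (tail, update(firstpair, g)).  Right-recursive, incremental; its result
    equals the last snapshot of :func:`learn_ext` on the same input.
    """
    events = tuple(pairs.events) if isinstance(pairs, PairList) else tuple(pairs)

    def go(remaining: tuple, g: AssociationNetwork) -> AssociationNetwork:
        if not remaining:
            return g
        return go(remaining[1:], _merge_event(remaining[0], g, update))

    return go(events, network)


def ilearn_loop(
    pairs: PairList, network: AssociationNetwork, update: MergeRule
) -> AssociationNetwork:
    """Iterative production: while the pair list is non-empty, merge the
    head into the network and drop it.  Agrees with :func:`rlearn_fold` on
    every finite input.
    """
    remaining = tuple(pairs.events) if isinstance(pairs, PairList) else tuple(pairs)
    g = network
    while remaining:
        g = _merge_event(remaining[0], g, update)
        remaining = remaining[1:]
    return g


def ablate_common_component(model: LearningModel) -> LearningModel:
    """Remove the shared merge morphism from a model.

    The returned model refuses every learn_* call — all learning capacities
    factoring through the common component are lost together — while recall
    on previously built networks is untouched (representability survives
    ablation of the learning process).
    """
    return replace(model, ablated=True)
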