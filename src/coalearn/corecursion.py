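"""Generic recursion-scheme machinery: unfold (anamorphism), fold
(catamorphism), product pairing and exponential transpose.

A coalgebra here is a state space together with a halting predicate, an
emit map (one output per non-halting state) and a next-state map.  The
anamorphism :func:`unfold` runs the coalgebra from an initial state,
collecting outputs head-first in temporal order.  Streams are conceptually
infinite, so evaluation always carries a mandatory step budget; the
:class:`Stream` result records whether the halting predicate or the budget
ended the run.  Productivity holds by construction: the k-th output is
fully determined by the first k steps.

The module also ships the toy coalgebras used throughout the literature on
corecursion — *repeat* (emit 1 while decrementing a counter) and *count*
(emit a running count while consuming a list) — which double as test
oracles for the learning models built on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

__all__ = [
    "ABSENT",
    "Coalgebra",
    "CoalgebraStepError",
    "EmptyReductionError",
    "Stream",
    "count_coalgebra",
    "fold",
    "pair_fn",
    "repeat_coalgebra",
    "transpose",
    "unfold",
    "untranspose",
]

#: Default step budget: large enough for every finite example in scope,
#: finite so a non-halting coalgebra can never hang the caller.
DEFAULT_BUDGET = 10_000


class _Absent:
    """Sentinel distinguishing "no initial value" from ``None``."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"


ABSENT = _Absent()


class EmptyReductionError(ValueError):
    """Raised by :func:`fold` on an empty list with no initial value."""


class CoalgebraStepError(RuntimeError):
    """A coalgebra's emit/next map raised; carries the failing step index."""

    def __init__(self, step: int, phase: str, original: Exception):
        self.step = step
        self.phase = phase
        self.original = original
        super().__init__(
            f"coalgebra {phase} failed at step {step}: {original!r}"
        )


@dataclass(frozen=True)
class Coalgebra:
    """Halting predicate plus one-step observation/transition maps.

    For any state exactly one branch applies: ``halt(state)`` true means the
    run stops emitting nothing further (the terminal output is the empty
    tail); false means one output ``emit(state)`` and one successor
    ``next_state(state)``.  ``emit`` and ``next_state`` must be pure.
    """

    halt: Callable[[Any], bool]
    emit: Callable[[Any], Any]
    next_state: Callable[[Any], Any]
    name: str = "coalgebra"


@dataclass(frozen=True)
class Stream:
    """Finite prefix of a (conceptually infinite) output stream.

    ``terminated`` is true when the halting predicate fired, false when the
    step budget cut evaluation short.
    """

    elements: tuple
    terminated: bool

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i):
        return self.elements[i]


def unfold(coalg: Coalgebra, state: Any, max_steps: int = DEFAULT_BUDGET) -> Stream:
    """Run the anamorphism of ``coalg`` from ``state``.

    Repeatedly tests ``halt``; while false, appends ``emit(state)`` and
    replaces the state by ``next_state(state)``.  Stops at the halting
    predicate or after ``max_steps`` emissions, whichever comes first.
    Outputs are collected head-first, in emission (temporal) order.
    """
    if max_steps < 0:
        raise ValueError(f"max_steps must be >= 0, got {max_steps}")
    elements: list = []
    for step in range(max_steps):
        if coalg.halt(state):
            return Stream(tuple(elements), terminated=True)
        try:
            out = coalg.emit(state)
        except Exception as exc:  # noqa: BLE001 - re-raised with step index
            raise CoalgebraStepError(step, "emit", exc) from exc
        try:
            state = coalg.next_state(state)
        except Exception as exc:  # noqa: BLE001
            raise CoalgebraStepError(step, "next", exc) from exc
        elements.append(out)
    # budget exhausted: one last chance for a clean halt at the boundary
    return Stream(tuple(elements), terminated=bool(coalg.halt(state)))


def pair_fn(f: Callable, g: Callable) -> Callable:
    """Product pairing ⟨f, g⟩ : x ↦ (f(x), g(x))."""

    def paired(x):
        return (f(x), g(x))

    paired.__name__ = f"pair({getattr(f, '__name__', 'f')},{getattr(g, '__name__', 'g')})"
    return paired


def fold(combine: Callable[[Any, Any], Any], initial: Any, items: Sequence) -> Any:
    """Right-associated reduction of ``items`` by ``combine``.

    ``fold(op, z, [a, b, c])`` computes ``op(a, op(b, op(c, z)))``.  Pass
    :data:`ABSENT` as ``initial`` to reduce over the list alone (requires a
    non-empty list); right association makes the choice irrelevant for
    associative ``combine`` and is the safe general convention otherwise.
    """
    items = list(items)
    if initial is ABSENT:
        if not items:
            raise EmptyReductionError("fold of empty list with no initial value")
        acc = items[-1]
        rest = items[:-1]
    else:
        acc = initial
        rest = items
    for item in reversed(rest):
        acc = combine(item, acc)
    return acc


def transpose(f: Callable[[Any, Any], Any]) -> Callable[[Any], Callable[[Any], Any]]:
    """Exponential transpose (currying): (a, b) → c becomes a → (b → c).

    This is the operational content of the product-exponential adjunction:
    ``transpose(f)(a)(b) == f(a, b)`` for all inputs, and
    :func:`untranspose` inverts it pointwise.
    """

    def curried(a):
        def inner(b):
            return f(a, b)

        return inner

    return curried


def untranspose(g: Callable[[Any], Callable[[Any], Any]]) -> Callable[[Any, Any], Any]:
    """Inverse of :func:`transpose`: a → (b → c) becomes (a, b) → c."""

    def uncurried(a, b):
        return g(a)(b)

    return uncurried


# ---------------------------------------------------------------------------
# Toy coalgebras
# ---------------------------------------------------------------------------

def _is_zero(n: int) -> bool:
    return n == 0


def _const_one(_state) -> int:
    return 1


def _dec(n: int) -> int:
    return n - 1


#: Repeat: from counter n, emit 1 n times.  unfold(0? → I*, ⟨1, dec⟩).
repeat_coalgebra = Coalgebra(
    halt=_is_zero, emit=_const_one, next_state=_dec, name="repeat"
)


def _list_empty(state) -> bool:
    _n, lst = state
    return len(lst) == 0


def incl(state) -> int:
    """(n, l) ↦ n + 1 — increment the counter, ignore the list."""
    n, _lst = state
    return n + 1


def tailr(state):
    """(n, h·t) ↦ (n + 1, t) — keep the new count, drop the counted item."""
    n, lst = state
    return (n + 1, tuple(lst[1:]))


#: Count: from (0, items), emit the running count 1, 2, ..., len(items).
#: unfold(e? → I*, ⟨incl, tailr⟩).
count_coalgebra = Coalgebra(
    halt=_list_empty, emit=incl, next_state=tailr, name="count"
)
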