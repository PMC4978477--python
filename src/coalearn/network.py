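"""Typed directed-graph association networks and merge (update) rules.

An association network is a directed graph whose vertices are representable
items and whose edges carry a real-valued associative strength σ together
with a co-occurrence count.  Networks are value-semantic: every merge
returns a new network and leaves its input untouched, which keeps snapshot
histories cheap (the graphs in scope are tiny).

Two families of merge rule are provided:

* the *halfway* rule — on each co-occurrence of a pair the edge strength is
  updated σ ← (1 + σ)/2 (created at σ0 on first occurrence), which climbs
  monotonically from σ0 toward the fixed point 1;
* a *Rescorla–Wagner* rule for compound trials —
  ΔV_X = α_X · β · (λ − Σ_present V), distributing the prediction error
  over the cues present on a trial; strengths are deliberately not clipped
  to [0, 1] so conditioned inhibition stays representable.

A :class:`NetworkType` captures species- or schema-specific constraints on
which associations are representable at all (e.g. a rat type allowing
odour→food edges but no colour→food edges); :func:`validate_pair` is the
operational form of "no merge function is defined over such networks".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "AssociationNetwork",
    "MergeRule",
    "NetworkType",
    "RecallResult",
    "TypeViolationError",
    "ValidationResult",
    "apply_type_map",
    "merge_halfway",
    "merge_rescorla_wagner",
    "recall",
    "validate_pair",
]


class TypeViolationError(ValueError):
    """A training event is not representable under the given network type."""


# ---------------------------------------------------------------------------
# AssociationNetwork
# ---------------------------------------------------------------------------


class AssociationNetwork:
    """Directed graph with per-edge strength σ and co-occurrence count.

    Vertex ids are case-sensitive Unicode strings.  At most one edge exists
    per ordered (source, target) pair.  Backed by a :class:`networkx.DiGraph`
    but exposed with value semantics: mutating operations are module-level
    functions returning new networks.
    """

    __slots__ = ("_g",)

    def __init__(self, graph: nx.DiGraph | None = None):
        self._g = graph if graph is not None else nx.DiGraph()

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls) -> "AssociationNetwork":
        return cls()

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str, float]] | Iterable[tuple[str, str, float, int]]
    ) -> "AssociationNetwork":
        g = nx.DiGraph()
        for edge in edges:
            if len(edge) == 3:
                s, t, sigma = edge
                count = 1
            else:
                s, t, sigma, count = edge
            g.add_edge(s, t, strength=float(sigma), count=int(count))
        return cls(g)

    # -- views --------------------------------------------------------
    @property
    def vertices(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> dict[tuple[str, str], float]:
        """Mapping (source, target) → strength σ."""
        return {(s, t): d["strength"] for s, t, d in self._g.edges(data=True)}

    @property
    def occurrence_counts(self) -> dict[tuple[str, str], int]:
        """Mapping (source, target) → number of co-occurrences seen."""
        return {(s, t): d["count"] for s, t, d in self._g.edges(data=True)}

    def strength(self, source: str, target: str, default: float = 0.0) -> float:
        if self._g.has_edge(source, target):
            return self._g[source][target]["strength"]
        return default

    def has_edge(self, source: str, target: str) -> bool:
        return self._g.has_edge(source, target)

    def out_degree(self, vertex: str) -> int:
        return self._g.out_degree(vertex) if vertex in self._g else 0

    def successors(self, vertex: str) -> dict[str, float]:
        """Outgoing edges of ``vertex`` as target → strength."""
        if vertex not in self._g:
            return {}
        return {t: self._g[vertex][t]["strength"] for t in self._g.successors(vertex)}

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def copy(self) -> "AssociationNetwork":
        return AssociationNetwork(self._g.copy())

    def graph(self) -> nx.DiGraph:
        """The underlying DiGraph (a defensive copy)."""
        return self._g.copy()

    # -- value semantics ----------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, AssociationNetwork):
            return NotImplemented
        return (
            self.vertices == other.vertices
            and self.edges == other.edges
            and self.occurrence_counts == other.occurrence_counts
        )

    def __hash__(self):
        return hash(
            (
                self.vertices,
                frozenset(self.edges.items()),
                frozenset(self.occurrence_counts.items()),
            )
        )

    def __repr__(self) -> str:
        return (
            f"AssociationNetwork({len(self.vertices)} vertices, "
            f"{self.n_edges} edges)"
        )

    # -- serialization (schema shared with coalearn.io) ----------------
    def to_dict(self) -> dict:
        return {
            "vertices": sorted(self.vertices),
            "edges": [
                {"source": s, "target": t, "strength": d["strength"], "count": d["count"]}
                for s, t, d in sorted(self._g.edges(data=True))
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "AssociationNetwork":
        g = nx.DiGraph()
        g.add_nodes_from(data.get("vertices", []))
        for e in data.get("edges", []):
            g.add_edge(
                e["source"],
                e["target"],
                strength=float(e["strength"]),
                count=int(e.get("count", 1)),
            )
        return cls(g)


# ---------------------------------------------------------------------------
# NetworkType
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkType:
    """Vertex vocabulary partitioned into classes plus allowed edge signatures.

    ``classes`` maps a class name (word, shape, colour, odour, food,
    conjunction, response, ...) to its declared vocabulary; an empty
    vocabulary marks an open-ended class whose members are identified by the
    ``"class:value"`` id prefix convention.  ``allowed_signatures`` lists the
    (source-class, target-class) pairs over which a merge function exists.
    ``configural`` says whether conjunction vertices are representable.
    ``default_class``, when set, is the class assigned to any vertex that
    neither belongs to a declared vocabulary nor carries a class prefix —
    this is how a fully permissive type classifies everything.
    """

    name: str
    classes: Mapping[str, frozenset[str]]
    allowed_signatures: frozenset[tuple[str, str]]
    configural: bool = False
    default_class: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self,
            "classes",
            {k: frozenset(v) for k, v in dict(self.classes).items()},
        )
        object.__setattr__(
            self, "allowed_signatures", frozenset(self.allowed_signatures)
        )
        vocabs = [v for v in self.classes.values() if v]
        seen: set[str] = set()
        for v in vocabs:
            if seen & v:
                raise ValueError(
                    f"network type {self.name!r}: class vocabularies overlap on "
                    f"{sorted(seen & v)}"
                )
            seen |= v
        for src, tgt in self.allowed_signatures:
            for c in (src, tgt):
                if c not in self.classes:
                    raise ValueError(
                        f"network type {self.name!r}: signature references "
                        f"undeclared class {c!r}"
                    )
        if self.default_class is not None and self.default_class not in self.classes:
            raise ValueError(
                f"network type {self.name!r}: default_class "
                f"{self.default_class!r} is not a declared class"
            )

    def classify(self, vertex: str) -> str | None:
        """Class of ``vertex``, or None if unrepresentable under this type."""
        for cname, vocab in self.classes.items():
            if vertex in vocab:
                return cname
        # open-vocabulary convention: "class:value"
        if ":" in vertex:
            prefix = vertex.split(":", 1)[0]
            if prefix in self.classes and not self.classes[prefix]:
                return prefix
        return self.default_class


def permissive_type(name: str = "permissive") -> NetworkType:
    """A fully permissive type: one open class, every signature allowed."""
    return NetworkType(
        name=name,
        classes={"item": frozenset()},
        allowed_signatures=frozenset({("item", "item")}),
        configural=True,
        default_class="item",
    )


@dataclass(frozen=True)
class ValidationResult:
    ok: bool
    message: str = ""

    def __bool__(self) -> bool:
        return self.ok


def validate_pair(ntype: NetworkType | None, event: tuple[str, str]) -> ValidationResult:
    """Check whether a (cue, target) event is representable under ``ntype``.

    ok iff both vertices classify under the type and the (cue-class,
    target-class) signature is allowed.  ``ntype=None`` means untyped: always
    ok.  A cue that is itself a collection (compound trial) is validated
    cue-by-cue against the same target.
    """
    if ntype is None:
        return ValidationResult(True)
    cue, target = event
    cues = [cue] if isinstance(cue, str) else list(cue)
    tclass = ntype.classify(target)
    if tclass is None:
        return ValidationResult(
            False,
            f"unrepresentable vertex: {target!r} has no class under type "
            f"{ntype.name!r}",
        )
    for c in cues:
        cclass = ntype.classify(c)
        if cclass is None:
            return ValidationResult(
                False,
                f"unrepresentable vertex: {c!r} has no class under type "
                f"{ntype.name!r}",
            )
        if (cclass, tclass) not in ntype.allowed_signatures:
            return ValidationResult(
                False,
                f"no merge function defined over {ntype.name!r} networks for "
                f"signature {cclass!r}→{tclass!r} (event {c!r}→{target!r})",
            )
    return ValidationResult(True)


# ---------------------------------------------------------------------------
# Merge rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergeRule:
    """Named, parameterized update μ : (event, network) → network.

    Parameters
    ----------
    name:
        ``"halfway"`` or ``"rescorla_wagner"``.
    sigma0:
        Initial strength on first occurrence of a pair (halfway rule),
        in (0, 1).  Default 0.5, putting the repeated-update trajectory on
        σ_n = 1 − 2^{−n}.
    alpha:
        Per-cue salience map for the RW rule, values in [0, 1]; cues absent
        from the map fall back to ``default_alpha``.
    beta:
        RW learning rate in [0, 1].
    lam:
        Default asymptote λ of the RW rule (a trial may override it).
    decay:
        Multiplicative decay applied to every edge strength before each
        merge; 1.0 means no decay.
    """

    name: str = "halfway"
    sigma0: float = 0.5
    alpha: Mapping[str, float] = field(default_factory=dict)
    default_alpha: float = 0.3
    beta: float = 1.0
    lam: float = 1.0
    decay: float = 1.0

    def __post_init__(self):
        if self.name not in ("halfway", "rescorla_wagner"):
            raise ValueError(f"unknown merge rule {self.name!r}")
        if not 0.0 < self.sigma0 < 1.0:
            raise ValueError(f"sigma0 must be in (0,1), got {self.sigma0}")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError(f"decay must be in (0,1], got {self.decay}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must be in [0,1], got {self.beta}")
        if not 0.0 <= self.default_alpha <= 1.0:
            raise ValueError(f"default_alpha must be in [0,1], got {self.default_alpha}")
        for cue, a in dict(self.alpha).items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"alpha[{cue!r}] must be in [0,1], got {a}")
        object.__setattr__(self, "alpha", dict(self.alpha))

    def salience(self, cue: str) -> float:
        return self.alpha.get(cue, self.default_alpha)


def _decayed(network: AssociationNetwork, decay: float) -> nx.DiGraph:
    g = network._g.copy()
    if decay < 1.0:
        for _s, _t, d in g.edges(data=True):
            d["strength"] *= decay
    return g


def merge_halfway(
    event: tuple[str, str], network: AssociationNetwork, rule: MergeRule
) -> AssociationNetwork:
    """One halfway-rule co-occurrence update; returns a new network.

    Absent edge → created at σ0 with count 1 (endpoints added as needed);
    present edge → σ ← (1 + σ)/2, count incremented.
    """
    if rule.name != "halfway":
        raise ValueError(f"merge_halfway requires a halfway rule, got {rule.name!r}")
    cue, target = event
    if not isinstance(cue, str):
        raise TypeError("halfway rule takes a single cue per event")
    g = _decayed(network, rule.decay)
    if g.has_edge(cue, target):
        d = g[cue][target]
        d["strength"] = (1.0 + d["strength"]) / 2.0
        d["count"] += 1
    else:
        g.add_edge(cue, target, strength=rule.sigma0, count=1)
    return AssociationNetwork(g)


def merge_rescorla_wagner(
    trial: tuple,
    network: AssociationNetwork,
    rule: MergeRule,
) -> AssociationNetwork:
    """One Rescorla–Wagner compound-trial update; returns a new network.

    ``trial`` is ``(cues, outcome)`` or ``(cues, outcome, lam)`` where
    ``cues`` is the non-empty collection of cues present on the trial.  The
    summed prediction ΣV runs over the present cues' strengths toward the
    outcome (absent edges count as V = 0), then every present cue X gets
    V_X ← V_X + α_X·β·(λ − ΣV).  Strengths may leave [0, 1] (inhibition).
    """
    if rule.name != "rescorla_wagner":
        raise ValueError(
            f"merge_rescorla_wagner requires a rescorla_wagner rule, got {rule.name!r}"
        )
    if len(trial) == 2:
        cues, outcome = trial
        lam = rule.lam
    else:
        cues, outcome, lam = trial
        if lam is None:
            lam = rule.lam
    cues = [cues] if isinstance(cues, str) else list(cues)
    if not cues:
        raise ValueError("rescorla_wagner trial requires a non-empty cue set")
    g = _decayed(network, rule.decay)
    total_v = sum(
        g[c][outcome]["strength"] if g.has_edge(c, outcome) else 0.0 for c in cues
    )
    error = lam - total_v
    for c in cues:
        delta = rule.salience(c) * rule.beta * error
        if g.has_edge(c, outcome):
            d = g[c][outcome]
            d["strength"] += delta
            d["count"] += 1
        else:
            g.add_edge(c, outcome, strength=delta, count=1)
    return AssociationNetwork(g)


def apply_merge(event, network: AssociationNetwork, rule: MergeRule) -> AssociationNetwork:
    """Dispatch a training event to the merge rule named by ``rule``."""
    if rule.name == "halfway":
        return merge_halfway(event, network, rule)
    return merge_rescorla_wagner(event, network, rule)


# ---------------------------------------------------------------------------
# Recall and type maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecallResult:
    """Outcome of cueing a network: winner, full tie-set, winning strength."""

    prediction: str | None
    tie_set: frozenset[str]
    strength: float | None

    @property
    def is_tie(self) -> bool:
        return len(self.tie_set) > 1


def recall(network: AssociationNetwork, cue: str) -> RecallResult:
    """Strongest associate of ``cue``.

    Returns the target(s) of maximal outgoing strength; the tie-set holds
    all maximizers and the prediction is the lexicographically least of
    them (deterministic, documented tie-break).  A cue with no outgoing
    edges yields an absent prediction and an empty tie-set.
    """
    out = network.successors(cue)
    if not out:
        return RecallResult(None, frozenset(), None)
    best = max(out.values())
    ties = frozenset(t for t, s in out.items() if s == best)
    return RecallResult(min(ties), ties, best)


def apply_type_map(
    vmap: Mapping[str, str], network: AssociationNetwork
) -> AssociationNetwork:
    """Rename vertices along ``vmap`` (a graph homomorphism on vertices).

    ``vmap`` must be total on the network's vertices.  Edge structure and
    strengths are preserved; when the map collapses two edges onto one, the
    resulting edge keeps the maximum strength and the summed count.
    """
    missing = sorted(v for v in network.vertices if v not in vmap)
    if missing:
        raise KeyError(f"type map undefined on vertices: {missing}")
    g = nx.DiGraph()
    g.add_nodes_from(vmap[v] for v in network.vertices)
    for (s, t), sigma in network.edges.items():
        ns, nt = vmap[s], vmap[t]
        count = network.occurrence_counts[(s, t)]
        if g.has_edge(ns, nt):
            d = g[ns][nt]
            d["strength"] = max(d["strength"], sigma)
            d["count"] += count
        else:
            g.add_edge(ns, nt, strength=sigma, count=count)
    return AssociationNetwork(g)
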