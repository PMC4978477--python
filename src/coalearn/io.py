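"""File formats and run configuration.

Pair lists travel as TSV (tab-separated, header row: ``cue``, ``target``,
optional ``lambda`` and ``context``; multi-attribute cues are pipe-
separated).  TSV rather than CSV avoids quoting trouble with Unicode glyph
vertex ids.  Networks travel as JSON objects and snapshot streams as JSON
lines, one network per line in temporal order.  All JSON is written with
sorted keys and floats in shortest round-trip form, so identical runs
produce byte-identical output and read(write(x)) == x exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .learning import PairList, TrainingEvent, encode_trial
from .network import AssociationNetwork, NetworkType

__all__ = [
    "PairListParseError",
    "RunConfig",
    "export_dot",
    "network_from_json",
    "network_to_json",
    "read_network",
    "read_pairlist",
    "read_snapshots",
    "write_network",
    "write_snapshots",
]


class PairListParseError(ValueError):
    """A pair-list TSV failed to parse; message carries the row number."""


# ---------------------------------------------------------------------------
# Pair lists (TSV)
# ---------------------------------------------------------------------------


def read_pairlist(
    path: str | Path,
    schema: str = "elemental",
    network_type: NetworkType | None = None,
) -> PairList:
    """Read a TSV pair list, preserving row order.

    Columns: ``cue`` (attributes pipe-separated for multi-attribute
    stimuli), ``target``, optional ``lambda`` (numeric asymptote) and
    ``context`` (treated as an extra stimulus attribute).  Rows are routed
    through the trial encoder, so configural rows become conjunction-vertex
    events.  Parse errors name the offending row (1-based, excluding the
    header).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise PairListParseError(f"{path}: empty file (expected a header row)")
    missing = {"cue", "target"} - set(df.columns)
    if missing:
        raise PairListParseError(
            f"{path}: missing required column(s): {', '.join(sorted(missing))}"
        )
    events: list[TrainingEvent] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        cue_field = str(row["cue"]).strip()
        target = str(row["target"]).strip()
        if not cue_field:
            raise PairListParseError(f"{path}: row {i}: empty cue")
        if not target:
            raise PairListParseError(f"{path}: row {i}: empty target")
        attrs = [a.strip() for a in cue_field.split("|") if a.strip()]
        context = str(row.get("context", "")).strip()
        if context:
            attrs.append(context)
        lam = None
        raw = str(row.get("lambda", "")).strip()
        if raw:
            try:
                lam = float(raw)
            except ValueError:
                raise PairListParseError(
                    f"{path}: row {i}: non-numeric lambda {raw!r}"
                ) from None
        events.extend(encode_trial(schema, attrs, target, network_type, lam))
    return PairList(tuple(events), schema)


def write_pairlist(pairs: PairList, path: str | Path) -> None:
    """Write a pair list as TSV (one row per event, cues pipe-joined)."""
    rows = []
    for ev in pairs:
        row = {"cue": "|".join(ev.cues), "target": ev.target}
        if ev.lam is not None:
            row["lambda"] = repr(ev.lam)
        rows.append(row)
    cols = ["cue", "target"] + (["lambda"] if any("lambda" in r for r in rows) else [])
    df = pd.DataFrame(rows, columns=cols).fillna("")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Networks (JSON) and snapshot streams (JSON lines)
# ---------------------------------------------------------------------------


def network_to_json(
    network: AssociationNetwork, network_type_name: str | None = None
) -> str:
    data = network.to_dict()
    if network_type_name is not None:
        data["network_type"] = network_type_name
    return json.dumps(data, sort_keys=True, ensure_ascii=False)


def network_from_json(text: str) -> AssociationNetwork:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed network JSON: {exc}") from exc
    if not isinstance(data, dict) or "edges" not in data:
        raise ValueError("network JSON must be an object with an 'edges' list")
    for e in data["edges"]:
        for key in ("source", "target", "strength"):
            if key not in e:
                raise ValueError(f"network JSON edge missing {key!r}: {e}")
    return AssociationNetwork.from_dict(data)


def write_network(network: AssociationNetwork, path: str | Path, **kw) -> None:
    Path(path).write_text(network_to_json(network, **kw) + "\n", encoding="utf-8")


def read_network(path: str | Path) -> AssociationNetwork:
    return network_from_json(Path(path).read_text(encoding="utf-8"))


def write_snapshots(stream: Iterable[AssociationNetwork], path: str | Path) -> None:
    """Write a snapshot stream as JSON lines, one network per time step."""
    with open(path, "w", encoding="utf-8") as fh:
        for g in stream:
            fh.write(network_to_json(g) + "\n")


def read_snapshots(path: str | Path) -> tuple[AssociationNetwork, ...]:
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            out.append(network_from_json(line))
    return tuple(out)


def export_dot(network: AssociationNetwork, path: str | Path | None = None) -> str:
    """Render a network in DOT, edge labels = strength to 3 decimals."""
    lines = ["digraph association_network {"]
    for v in sorted(network.vertices):
        lines.append(f'  "{v}";')
    for (s, t), sigma in sorted(network.edges.items()):
        lines.append(f'  "{s}" -> "{t}" [label="{sigma:.3f}"];')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run: rule parameters, type, seed."""

    merge_rule: str = "halfway"
    sigma0: float = 0.5
    alpha: dict = field(default_factory=dict)
    default_alpha: float = 0.3
    beta: float = 1.0
    lam: float = 1.0
    decay: float = 1.0
    network_type: str | None = None
    schema: str = "elemental"
    seed: int = 0
    budget: int = 10_000
    criterion: float = 1.0
    max_blocks: int = 25
    verbosity: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))
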