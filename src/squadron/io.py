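"""Reading and writing network models and scenario tables.

Three model dialects are supported:

signed-SIF
    UTF-8 text, tab-separated (node names may contain spaces, parentheses
    and asterisks, so lines are split on tabs, never on whitespace).
    Comment lines start with ``#``.  Node declarations::

        NODE<TAB>name<TAB>category[<TAB>gain<TAB>decay]

    Edge lines::

        source<TAB>+|-<TAB>target[<TAB>weight]

JSON
    Top-level keys ``nodes``, ``edges``, ``metadata``; the formal schema
    ships with the package (``data/model.schema.json``) and the loader
    enforces the same constraints structurally.

bnet (export only)
    BoolNet ``targets, factors`` text encoding each node's default logic
    as OR-of-activators AND NOT(OR-of-inhibitors), for interoperability
    with discrete-network tools.  Refused for models with non-unit edge
    weights, which the Boolean encoding cannot represent.

Scenario tables are TSV: rows are nodes, columns are scenario names, a
non-blank cell clamps the node at that value for the scenario, a blank
cell leaves it free.
"""

from __future__ import annotations

import json
import re
import warnings
from typing import Iterable

from .model import (
    ACTIVATION,
    DEFAULT_DECAY,
    DEFAULT_GAIN,
    INHIBITION,
    Edge,
    ModelValidationError,
    NetworkModel,
    Node,
    NodeCategory,
    ScenarioSpec,
)

__all__ = [
    "ParseError",
    "parse_model",
    "serialize_model",
    "parse_scenarios",
    "serialize_scenarios",
]


class ParseError(ValueError):
    """Malformed input text; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def parse_model(text: str, format: str = "signed_sif") -> NetworkModel:
    """Parse *text* in the given dialect into a validated model."""
    if format == "signed_sif":
        return _parse_sif(text)
    if format == "json":
        return _parse_json(text)
    raise ValueError(f"unknown model format {format!r}")


def serialize_model(model: NetworkModel, format: str = "signed_sif") -> str:
    """Serialize deterministically (nodes and edges sorted lexicographically)."""
    if format == "signed_sif":
        return _to_sif(model)
    if format == "json":
        return _to_json(model)
    if format == "bnet":
        return _to_bnet(model)
    raise ValueError(f"unknown model format {format!r}")


# -- signed-SIF -------------------------------------------------------------


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"bad {what} {token!r}", lineno) from None


def _parse_sif(text: str) -> NetworkModel:
    nodes: dict[str, Node] = {}
    edge_specs: list[tuple[str, str, str, float, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "NODE":
            if len(fields) not in (3, 5):
                raise ParseError(
                    "node declaration needs 'NODE<TAB>name<TAB>category"
                    "[<TAB>gain<TAB>decay]'",
                    lineno,
                )
            name = fields[1]
            try:
                category = NodeCategory(fields[2])
            except ValueError:
                raise ParseError(f"unknown category {fields[2]!r}", lineno) from None
            gain, decay = DEFAULT_GAIN, DEFAULT_DECAY
            if len(fields) == 5:
                gain = _parse_float(fields[3], "gain", lineno)
                decay = _parse_float(fields[4], "decay", lineno)
            if name in nodes:
                raise ParseError(f"duplicate node declaration {name!r}", lineno)
            try:
                nodes[name] = Node(name, category, gain, decay)
            except ModelValidationError as exc:
                raise ParseError(str(exc), lineno) from None
        else:
            if len(fields) not in (3, 4):
                raise ParseError(
                    "edge line needs 'source<TAB>+|-<TAB>target[<TAB>weight]'",
                    lineno,
                )
            source, sign_token, target = fields[0], fields[1], fields[2]
            if not source or not target:
                raise ParseError("empty node name on edge line", lineno)
            if sign_token not in ("+", "-"):
                raise ParseError(f"edge sign must be '+' or '-', got {sign_token!r}", lineno)
            weight = 1.0
            if len(fields) == 4:
                weight = _parse_float(fields[3], "weight", lineno)
            sign = ACTIVATION if sign_token == "+" else INHIBITION
            edge_specs.append((source, target, sign, weight, lineno))
    # implicitly declare endpoint nodes that carry no NODE line
    for source, target, _, _, _ in edge_specs:
        for name in (source, target):
            if name not in nodes:
                nodes[name] = Node(name)
    edges = []
    for source, target, sign, weight, lineno in edge_specs:
        try:
            edges.append(Edge(source, target, sign, weight))
        except ModelValidationError as exc:
            raise ParseError(str(exc), lineno) from None
    return NetworkModel(nodes.values(), edges)


def _to_sif(model: NetworkModel) -> str:
    lines = ["# signed interaction network"]
    for name in sorted(model.nodes):
        node = model.nodes[name]
        lines.append(
            f"NODE\t{node.name}\t{node.category.value}\t{node.gain!r}\t{node.decay!r}"
        )
    for edge in sorted(model.edges, key=lambda e: (e.source, e.target)):
        sign = "+" if edge.is_activation else "-"
        lines.append(f"{edge.source}\t{sign}\t{edge.target}\t{edge.weight!r}")
    return "\n".join(lines) + "\n"


# -- JSON -------------------------------------------------------------------


def _parse_json(text: str) -> NetworkModel:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}") from None
    if not isinstance(doc, dict):
        raise ParseError("top level must be an object")
    for key in ("nodes", "edges"):
        if key not in doc or not isinstance(doc[key], list):
            raise ParseError(f"missing or non-array top-level key {key!r}")
    nodes = []
    for i, entry in enumerate(doc["nodes"]):
        if not isinstance(entry, dict) or "name" not in entry:
            raise ParseError(f"nodes[{i}] must be an object with a 'name'")
        try:
            nodes.append(
                Node(
                    name=entry["name"],
                    category=NodeCategory(entry.get("category", "signaling")),
                    gain=float(entry.get("gain", DEFAULT_GAIN)),
                    decay=float(entry.get("decay", DEFAULT_DECAY)),
                )
            )
        except (ValueError, ModelValidationError) as exc:
            raise ParseError(f"nodes[{i}]: {exc}") from None
    edges = []
    for i, entry in enumerate(doc["edges"]):
        if not isinstance(entry, dict):
            raise ParseError(f"edges[{i}] must be an object")
        try:
            edges.append(
                Edge(
                    source=entry["source"],
                    target=entry["target"],
                    sign=entry.get("sign", ACTIVATION),
                    weight=float(entry.get("weight", 1.0)),
                )
            )
        except KeyError as exc:
            raise ParseError(f"edges[{i}]: missing key {exc}") from None
        except (ValueError, ModelValidationError) as exc:
            raise ParseError(f"edges[{i}]: {exc}") from None
    metadata = doc.get("metadata", {})
    if not isinstance(metadata, dict):
        raise ParseError("'metadata' must be an object")
    return NetworkModel(nodes, edges, metadata)


def _to_json(model: NetworkModel) -> str:
    doc = {
        "nodes": [
            {
                "name": n.name,
                "category": n.category.value,
                "gain": n.gain,
                "decay": n.decay,
            }
            for n in sorted(model.nodes.values(), key=lambda n: n.name)
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "weight": e.weight,
            }
            for e in sorted(model.edges, key=lambda e: (e.source, e.target))
        ],
        "metadata": model.metadata,
    }
    return json.dumps(doc, indent=2, sort_keys=False) + "\n"


# -- bnet export ------------------------------------------------------------

_BNET_SAFE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


def _bnet_name(name: str) -> str:
    """BoolNet identifiers allow only word characters; mangle the rest."""
    if _BNET_SAFE.match(name):
        return name
    mangled = re.sub(r"[^A-Za-z0-9_]", "_", name).strip("_")
    if not mangled or not mangled[0].isalpha():
        mangled = "n_" + mangled
    return mangled


def _to_bnet(model: NetworkModel) -> str:
    if any(e.weight != 1.0 for e in model.edges):
        raise ModelValidationError(
            "bnet export refused: model has non-unit edge weights, which the "
            "Boolean encoding would silently discard"
        )
    rename: dict[str, str] = {}
    used: set[str] = set()
    for name in sorted(model.nodes):
        candidate = _bnet_name(name)
        while candidate in used:
            candidate += "_"
        used.add(candidate)
        rename[name] = candidate
    lines = ["targets, factors"]
    for name in sorted(model.nodes):
        activators = [rename[e.source] for e in model.activators_of(name)]
        inhibitors = [rename[e.source] for e in model.inhibitors_of(name)]
        activators.sort()
        inhibitors.sort()
        if not activators and not inhibitors:
            rule = "0"
        else:
            act = " | ".join(activators) if activators else "1"
            if len(activators) > 1:
                act = f"({act})"
            if inhibitors:
                inh = " | ".join(inhibitors)
                if len(inhibitors) > 1:
                    inh = f"({inh})"
                rule = f"{act} & !{inh}"
            else:
                rule = act
        lines.append(f"{rename[name]}, {rule}")
    return "\n".join(lines) + "\n"


# -- scenario tables --------------------------------------------------------


def parse_scenarios(
    text: str,
    model: NetworkModel | None = None,
) -> list[ScenarioSpec]:
    """Parse a TSV scenario table into one :class:`ScenarioSpec` per column.

    Non-blank cells become clamps; blank cells leave the node free.  When a
    *model* is given, referenced names absent from it produce a warning
    (scenario tables may legitimately mention nodes a reduced model lacks).
    """
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError("empty scenario table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ParseError("header must name at least one scenario", 1)
    scenario_names = [h.strip() for h in header[1:]]
    clamps: list[dict[str, float]] = [{} for _ in scenario_names]
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        node = cells[0].strip()
        if not node:
            raise ParseError("row with empty node name", lineno)
        values = cells[1:]
        for j, cell in enumerate(values):
            cell = cell.strip()
            if not cell or j >= len(scenario_names):
                continue
            value = _parse_float(cell, "activity", lineno)
            if not 0.0 <= value <= 1.0:
                raise ParseError(
                    f"activity {value} for node {node!r} outside [0, 1]", lineno
                )
            clamps[j][node] = value
    scenarios = [
        ScenarioSpec(name=name, clamps=cl)
        for name, cl in zip(scenario_names, clamps)
    ]
    if model is not None:
        unknown = sorted(
            {n for sc in scenarios for n in sc.clamps} - set(model.nodes)
        )
        if unknown:
            warnings.warn(
                f"scenario table references nodes absent from the model: {unknown}",
                stacklevel=2,
            )
    return scenarios


def serialize_scenarios(scenarios: Iterable[ScenarioSpec]) -> str:
    """Write scenarios back to the TSV dialect (deterministic row order)."""
    scenarios = list(scenarios)
    nodes = sorted({n for sc in scenarios for n in sc.clamps})
    lines = ["node\t" + "\t".join(sc.name for sc in scenarios)]
    for node in nodes:
        cells = [
            ("" if node not in sc.clamps else repr(sc.clamps[node]))
            for sc in scenarios
        ]
        lines.append(node + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
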