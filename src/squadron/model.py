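"""Core domain types: nodes, signed edges, network models and scenarios.

A :class:`NetworkModel` is a signed directed graph over named signaling
nodes.  Each node carries the two dynamical parameters of the continuous
transform (sigmoid gain ``h`` and first-order decay rate ``gamma``); each
edge carries a sign (activation / inhibition) and a positive weight.

A :class:`ScenarioSpec` encodes one simulated condition: a set of *clamps*
(activities held constant for the whole run, the "perturbation" notion of
semi-quantitative network simulators) plus optional free initial values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "ACTIVATION",
    "INHIBITION",
    "DEFAULT_GAIN",
    "DEFAULT_DECAY",
    "NodeCategory",
    "Node",
    "Edge",
    "NetworkModel",
    "ScenarioSpec",
    "ModelValidationError",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"

#: Default sigmoid steepness of the normalized response curve.
DEFAULT_GAIN = 10.0
#: Default first-order decay rate.
DEFAULT_DECAY = 1.0


class ModelValidationError(ValueError):
    """Raised when a model, edge, node or scenario violates an invariant."""


class NodeCategory(str, Enum):
    RECEPTOR_TOTAL = "receptor_total"
    RECEPTOR_ACTIVE = "receptor_active"
    SIGNALING = "signaling"
    PHENOTYPE = "phenotype"
    DRUG = "drug"
    MUTATION = "mutation"
    AUXILIARY = "auxiliary"


@dataclass(frozen=True)
class Node:
    """A network species with its dynamical parameters.

    Parameters
    ----------
    name
        Unique, case-sensitive identifier.  May contain parentheses and
        asterisks (activated receptor forms are conventionally starred).
    category
        Functional role of the node; phenotype nodes are readouts.
    gain
        Sigmoid steepness ``h`` of the response curve (``> 0``).
    decay
        First-order decay rate ``gamma`` (``> 0``).
    """

    name: str
    category: NodeCategory = NodeCategory.SIGNALING
    gain: float = DEFAULT_GAIN
    decay: float = DEFAULT_DECAY

    def __post_init__(self) -> None:
        if not self.name:
            raise ModelValidationError("node name must be non-empty")
        if not isinstance(self.category, NodeCategory):
            object.__setattr__(self, "category", NodeCategory(self.category))
        if not self.gain > 0:
            raise ModelValidationError(
                f"node {self.name!r}: gain must be positive, got {self.gain}"
            )
        if not self.decay > 0:
            raise ModelValidationError(
                f"node {self.name!r}: decay must be positive, got {self.decay}"
            )


@dataclass(frozen=True)
class Edge:
    """A signed, weighted regulatory interaction ``source -> target``."""

    source: str
    target: str
    sign: str = ACTIVATION
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATION, INHIBITION):
            raise ModelValidationError(
                f"edge {self.source}->{self.target}: sign must be "
                f"{ACTIVATION!r} or {INHIBITION!r}, got {self.sign!r}"
            )
        if not self.weight > 0:
            raise ModelValidationError(
                f"edge {self.source}->{self.target}: weight must be positive, "
                f"got {self.weight}"
            )

    @property
    def is_activation(self) -> bool:
        return self.sign == ACTIVATION


class NetworkModel:
    """Signed directed graph of signaling nodes.

    Nodes and edges are stored in insertion order but compared as sets:
    two models are equal when they hold the same nodes (with identical
    parameters) and the same signed weighted edges.
    """

    def __init__(
        self,
        nodes: Iterable[Node],
        edges: Iterable[Edge] = (),
        metadata: Mapping[str, object] | None = None,
    ) -> None:
        self.nodes: dict[str, Node] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise ModelValidationError(f"duplicate node name {node.name!r}")
            self.nodes[node.name] = node
        self.edges: list[Edge] = []
        seen: set[tuple[str, str]] = set()
        for edge in edges:
            if edge.source not in self.nodes:
                raise ModelValidationError(
                    f"edge references unknown source node {edge.source!r}"
                )
            if edge.target not in self.nodes:
                raise ModelValidationError(
                    f"edge references unknown target node {edge.target!r}"
                )
            key = (edge.source, edge.target)
            if key in seen:
                raise ModelValidationError(
                    f"duplicate edge {edge.source!r} -> {edge.target!r}"
                )
            seen.add(key)
            self.edges.append(edge)
        self.metadata: dict[str, object] = dict(metadata or {})
        # incoming-edge index, split by sign, used by both engines
        self._activators: dict[str, list[Edge]] = {n: [] for n in self.nodes}
        self._inhibitors: dict[str, list[Edge]] = {n: [] for n in self.nodes}
        for edge in self.edges:
            if edge.is_activation:
                self._activators[edge.target].append(edge)
            else:
                self._inhibitors[edge.target].append(edge)

    # -- accessors ---------------------------------------------------------

    @property
    def node_names(self) -> list[str]:
        return list(self.nodes)

    def activators_of(self, name: str) -> list[Edge]:
        return self._activators[name]

    def inhibitors_of(self, name: str) -> list[Edge]:
        return self._inhibitors[name]

    def in_degree(self, name: str) -> int:
        return len(self._activators[name]) + len(self._inhibitors[name])

    def phenotype_nodes(self) -> list[str]:
        return [
            n.name
            for n in self.nodes.values()
            if n.category is NodeCategory.PHENOTYPE
        ]

    def to_networkx(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for node in self.nodes.values():
            graph.add_node(
                node.name,
                category=node.category.value,
                gain=node.gain,
                decay=node.decay,
            )
        for edge in self.edges:
            graph.add_edge(edge.source, edge.target, sign=edge.sign, weight=edge.weight)
        return graph

    # -- comparison --------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NetworkModel):
            return NotImplemented
        return (
            set(self.nodes.values()) == set(other.nodes.values())
            and set(self.edges) == set(other.edges)
        )

    def __repr__(self) -> str:
        return (
            f"NetworkModel({len(self.nodes)} nodes, {len(self.edges)} edges, "
            f"name={self.metadata.get('name')!r})"
        )

    def validate(self) -> None:
        """Re-check the structural invariants (cheap; raises on violation)."""
        for node in self.nodes.values():
            if not node.gain > 0 or not node.decay > 0:
                raise ModelValidationError(f"node {node.name!r} has bad parameters")
        for edge in self.edges:
            if edge.source not in self.nodes or edge.target not in self.nodes:
                raise ModelValidationError("dangling edge endpoint")


@dataclass
class ScenarioSpec:
    """One simulated condition: clamps plus free initial activities.

    ``clamps`` are held at their value for the entire simulation;
    ``initials`` only set the starting activity of free nodes.  A node may
    not appear in both.  Unlisted nodes start at activity 0.
    """

    name: str
    clamps: dict[str, float] = field(default_factory=dict)
    initials: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, mapping in (("clamp", self.clamps), ("initial", self.initials)):
            for node, value in mapping.items():
                if not 0.0 <= value <= 1.0:
                    raise ModelValidationError(
                        f"scenario {self.name!r}: {label} for {node!r} is "
                        f"{value}, outside [0, 1]"
                    )
        overlap = set(self.clamps) & set(self.initials)
        if overlap:
            raise ModelValidationError(
                f"scenario {self.name!r}: nodes {sorted(overlap)} appear in "
                "both clamps and initials"
            )

    def check_against(self, model: NetworkModel) -> list[str]:
        """Return names referenced by the scenario but absent from *model*."""
        return sorted(
            (set(self.clamps) | set(self.initials)) - set(model.nodes)
        )
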