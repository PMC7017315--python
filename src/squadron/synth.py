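"""Random signed networks and scenarios for property testing.

The generator draws a simple directed Erdős–Rényi topology with a
configurable inhibition fraction, weight range and per-node gain/decay
ranges.  It exists so every engine property (boundedness, clamp fidelity,
high-gain correspondence with the Boolean oracle) can be exercised on
ensembles of models without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ACTIVATION,
    INHIBITION,
    Edge,
    ModelValidationError,
    NetworkModel,
    Node,
    NodeCategory,
    ScenarioSpec,
)

__all__ = ["GeneratorConfig", "random_signed_network", "random_scenario"]


@dataclass
class GeneratorConfig:
    """Knobs of the random-network generator.

    Identical config + seed always produces an identical model.
    """

    n_nodes: int = 10
    edge_probability: float = 0.25
    inhibition_fraction: float = 0.3
    weight_range: tuple[float, float] = (1.0, 1.0)
    gain_range: tuple[float, float] = (10.0, 10.0)
    decay_range: tuple[float, float] = (1.0, 1.0)
    allow_self_loops: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ModelValidationError("n_nodes must be positive")
        if not 0.0 <= self.edge_probability <= 1.0:
            raise ModelValidationError("edge_probability must be in [0, 1]")
        if not 0.0 <= self.inhibition_fraction <= 1.0:
            raise ModelValidationError("inhibition_fraction must be in [0, 1]")
        for label, (lo, hi) in (
            ("weight_range", self.weight_range),
            ("gain_range", self.gain_range),
            ("decay_range", self.decay_range),
        ):
            if not (0 < lo <= hi):
                raise ModelValidationError(f"{label} must satisfy 0 < lo <= hi")


def random_signed_network(config: GeneratorConfig) -> NetworkModel:
    """Draw a validated random model under *config*."""
    rng = np.random.default_rng(config.seed)
    names = [f"N{i}" for i in range(config.n_nodes)]
    nodes = [
        Node(
            name,
            NodeCategory.SIGNALING,
            gain=float(rng.uniform(*config.gain_range)),
            decay=float(rng.uniform(*config.decay_range)),
        )
        for name in names
    ]
    edges = []
    for source in names:
        for target in names:
            if source == target and not config.allow_self_loops:
                continue
            if rng.random() >= config.edge_probability:
                continue
            sign = (
                INHIBITION
                if rng.random() < config.inhibition_fraction
                else ACTIVATION
            )
            weight = float(rng.uniform(*config.weight_range))
            edges.append(Edge(source, target, sign, weight))
    model = NetworkModel(nodes, edges, {"name": f"random-{config.seed}"})
    model.validate()
    return model


def random_scenario(
    model: NetworkModel,
    n_clamps: int,
    seed: int = 0,
    name: str | None = None,
) -> ScenarioSpec:
    """Clamp ``n_clamps`` distinct random nodes at uniform levels in [0, 1]."""
    names = model.node_names
    if n_clamps > len(names):
        raise ModelValidationError(
            f"n_clamps={n_clamps} exceeds the {len(names)} model nodes"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(names), size=n_clamps, replace=False)
    clamps = {names[i]: float(rng.uniform()) for i in sorted(chosen)}
    return ScenarioSpec(name=name or f"random-scenario-{seed}", clamps=clamps)
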