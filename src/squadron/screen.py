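"""In silico mode-of-action screen.

Systematically clamps single nodes (or unordered pairs) on top of a base
scenario and ranks the perturbations by apoptosis induction (descending)
and proliferation suppression (ascending), with a lexicographic node-name
tiebreak.  Clamping a node to 0 models a complete pharmacological block of
that species; clamping to 1 models constitutive activation.

A perturbation on a node that the base scenario already clamps *replaces*
the base clamp — a perturbation supersedes the pre-stimulation, the way a
dedicated inhibitor node at full activation overrides a calibrated level.
Non-convergent perturbations are ranked last and flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .dynamics import SimulationConfig, simulate
from .model import ModelValidationError, NetworkModel, NodeCategory, ScenarioSpec

__all__ = ["PerturbationRecord", "single_node_screen", "pair_screen"]


@dataclass(frozen=True)
class PerturbationRecord:
    """Outcome of one perturbed steady-state run."""

    nodes: tuple[str, ...]
    clamp_level: float
    apoptosis: float
    proliferation: float
    d_apoptosis: float
    d_proliferation: float
    converged: bool


def _base_phenotypes(
    model: NetworkModel,
    base: ScenarioSpec,
    config: SimulationConfig | None,
    apoptosis_node: str,
    proliferation_node: str,
) -> tuple[float, float]:
    result = simulate(model, base, config)
    end = result.trajectory[-1].activities
    return end[apoptosis_node], end[proliferation_node]


def _candidate_nodes(
    model: NetworkModel,
    base: ScenarioSpec,
    node_subset: Iterable[str] | None,
) -> list[str]:
    if node_subset is None:
        candidates = [
            n.name
            for n in model.nodes.values()
            if n.category is not NodeCategory.PHENOTYPE
        ]
    else:
        candidates = list(node_subset)
        for name in candidates:
            if name not in model.nodes:
                raise ModelValidationError(f"unknown candidate node {name!r}")
            if model.nodes[name].category is NodeCategory.PHENOTYPE:
                raise ModelValidationError(
                    f"phenotype node {name!r} may not be perturbed"
                )
            if name in base.clamps:
                raise ModelValidationError(
                    f"candidate node {name!r} is already clamped in the base "
                    f"scenario {base.name!r}"
                )
    if not candidates:
        raise ModelValidationError("empty candidate set")
    return candidates


def _run_perturbation(
    model: NetworkModel,
    base: ScenarioSpec,
    nodes: tuple[str, ...],
    clamp_level: float,
    config: SimulationConfig | None,
    base_apop: float,
    base_prol: float,
    apoptosis_node: str,
    proliferation_node: str,
) -> PerturbationRecord:
    clamps = dict(base.clamps)
    for name in nodes:
        clamps[name] = clamp_level  # perturbation supersedes any base clamp
    initials = {k: v for k, v in base.initials.items() if k not in clamps}
    scenario = ScenarioSpec(
        name=f"{base.name}+clamp({','.join(nodes)}={clamp_level})",
        clamps=clamps,
        initials=initials,
    )
    result = simulate(model, scenario, config)
    end = result.trajectory[-1].activities
    return PerturbationRecord(
        nodes=nodes,
        clamp_level=clamp_level,
        apoptosis=end[apoptosis_node],
        proliferation=end[proliferation_node],
        d_apoptosis=end[apoptosis_node] - base_apop,
        d_proliferation=end[proliferation_node] - base_prol,
        converged=result.converged,
    )


def _ranked(records: list[PerturbationRecord]) -> list[PerturbationRecord]:
    return sorted(
        records,
        key=lambda r: (
            not r.converged,          # non-convergent runs rank last
            -r.d_apoptosis,
            r.d_proliferation,
            r.nodes,
        ),
    )


def single_node_screen(
    model: NetworkModel,
    base: ScenarioSpec,
    clamp_level: float = 0.0,
    node_subset: Iterable[str] | None = None,
    config: SimulationConfig | None = None,
    apoptosis_node: str = "apoptosis",
    proliferation_node: str = "proliferation",
) -> list[PerturbationRecord]:
    """Clamp each candidate node at *clamp_level* and rank the outcomes."""
    if not 0.0 <= clamp_level <= 1.0:
        raise ModelValidationError(f"clamp_level {clamp_level} outside [0, 1]")
    candidates = _candidate_nodes(model, base, node_subset)
    base_apop, base_prol = _base_phenotypes(
        model, base, config, apoptosis_node, proliferation_node
    )
    records = [
        _run_perturbation(
            model, base, (name,), clamp_level, config,
            base_apop, base_prol, apoptosis_node, proliferation_node,
        )
        for name in candidates
    ]
    return _ranked(records)


def pair_screen(
    model: NetworkModel,
    base: ScenarioSpec,
    clamp_level: float = 0.0,
    node_subset: Iterable[str] | None = None,
    config: SimulationConfig | None = None,
    apoptosis_node: str = "apoptosis",
    proliferation_node: str = "proliferation",
) -> list[PerturbationRecord]:
    """Screen over unordered pairs of candidate nodes."""
    if not 0.0 <= clamp_level <= 1.0:
        raise ModelValidationError(f"clamp_level {clamp_level} outside [0, 1]")
    candidates = _candidate_nodes(model, base, node_subset)
    if len(candidates) < 2:
        raise ModelValidationError("pair screen needs at least two candidates")
    base_apop, base_prol = _base_phenotypes(
        model, base, config, apoptosis_node, proliferation_node
    )
    records = [
        _run_perturbation(
            model, base, tuple(sorted(pair)), clamp_level, config,
            base_apop, base_prol, apoptosis_node, proliferation_node,
        )
        for pair in combinations(sorted(candidates), 2)
    ]
    return _ranked(records)


def records_to_frame(records: Sequence[PerturbationRecord]) -> pd.DataFrame:
    """Tabulate screen records (CSV-ready)."""
    return pd.DataFrame(
        {
            "nodes": ["+".join(r.nodes) for r in records],
            "clamp_level": [r.clamp_level for r in records],
            "apoptosis": [r.apoptosis for r in records],
            "proliferation": [r.proliferation for r in records],
            "d_apoptosis": [r.d_apoptosis for r in records],
            "d_proliferation": [r.d_proliferation for r in records],
            "converged": [r.converged for r in records],
        }
    )
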