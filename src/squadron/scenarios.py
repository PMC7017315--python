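"""Treatment scenarios, readout tables and reference comparison.

`run_readouts` drives the continuous engine once per scenario and projects
the steady states onto the phenotype/readout rows, producing the machine
twin of the printed simulation-outcome table.  `compare_to_reference`
reports per-cell deviations plus a qualitative direction call (increased /
decreased / unchanged versus the untreated column).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .crc import READOUT_NODES, load_crc_hroc87, load_treatment_scenarios
from .dynamics import SimulationConfig, simulate
from .model import ModelValidationError, NetworkModel, ScenarioSpec

__all__ = [
    "ReadoutTable",
    "ComparisonReport",
    "build_treatment_scenarios",
    "run_readouts",
    "compare_to_reference",
    "UNCHANGED_BAND",
]

#: |delta| vs untreated below which a readout counts as "unchanged".
UNCHANGED_BAND = 0.05


@dataclass
class ReadoutTable:
    """Scenarios x readout-nodes matrix of steady-state activities."""

    rows: list[str]
    columns: list[str]
    values: dict[str, dict[str, float]]        # column -> row -> activity
    converged: dict[str, dict[str, bool]]      # column -> row -> flag

    def value(self, row: str, column: str) -> float:
        return self.values[column][row]

    def is_converged(self, row: str, column: str) -> bool:
        return self.converged[column][row]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {col: [self.values[col][row] for row in self.rows] for col in self.columns},
            index=self.rows,
        )

    def __repr__(self) -> str:
        return f"ReadoutTable({len(self.rows)} readouts x {len(self.columns)} scenarios)"


@dataclass
class ComparisonReport:
    """Cellwise deviations from a reference table plus direction calls."""

    deviations: pd.DataFrame
    passed: pd.DataFrame
    tolerance: float
    directions: pd.DataFrame = field(repr=False, default=None)

    @property
    def all_passed(self) -> bool:
        return bool(self.passed.to_numpy().all())

    def failures(self) -> list[tuple[str, str, float]]:
        out = []
        for row in self.deviations.index:
            for col in self.deviations.columns:
                if not self.passed.loc[row, col]:
                    out.append((row, col, float(self.deviations.loc[row, col])))
        return out


def build_treatment_scenarios() -> list[ScenarioSpec]:
    """The six packaged treatment scenarios (pre-stimulation clamps)."""
    return load_treatment_scenarios()


def run_readouts(
    model: NetworkModel | None = None,
    scenarios: Sequence[ScenarioSpec] | None = None,
    readout_nodes: Sequence[str] | None = None,
    config: SimulationConfig | None = None,
) -> ReadoutTable:
    """One steady-state run per scenario, projected onto the readout rows.

    Non-convergent cells keep the trajectory endpoint but are flagged, never
    silently treated as steady states.
    """
    model = model if model is not None else load_crc_hroc87()
    scenarios = list(scenarios) if scenarios is not None else build_treatment_scenarios()
    rows = list(readout_nodes) if readout_nodes is not None else list(READOUT_NODES)
    missing = [r for r in rows if r not in model.nodes]
    if missing:
        raise ModelValidationError(f"model lacks readout nodes: {missing}")
    values: dict[str, dict[str, float]] = {}
    flags: dict[str, dict[str, bool]] = {}
    for scenario in scenarios:
        result = simulate(model, scenario, config)
        endpoint = result.trajectory[-1]
        values[scenario.name] = {r: endpoint.activities[r] for r in rows}
        flags[scenario.name] = {r: result.converged for r in rows}
    return ReadoutTable(
        rows=rows,
        columns=[sc.name for sc in scenarios],
        values=values,
        converged=flags,
    )


def classify_direction(delta: float, band: float = UNCHANGED_BAND) -> str:
    if delta > band:
        return "increased"
    if delta < -band:
        return "decreased"
    return "unchanged"


def compare_to_reference(
    table: ReadoutTable,
    reference: ReadoutTable,
    tolerance: float = 0.05,
    untreated: str = "untr.",
    band: float = UNCHANGED_BAND,
) -> ComparisonReport:
    """Cellwise |deviation| <= tolerance check plus direction classification.

    Directions compare each scenario column against the *untreated* column
    of the same table, calling a readout unchanged when the shift stays
    within *band*.
    """
    if set(table.rows) != set(reference.rows) or set(table.columns) != set(
        reference.columns
    ):
        raise ModelValidationError(
            "table and reference must cover identical rows and columns"
        )
    got = table.to_frame().loc[table.rows, table.columns]
    ref = reference.to_frame().loc[table.rows, table.columns]
    deviations = (got - ref).abs()
    passed = deviations <= tolerance
    directions = None
    if untreated in table.columns:
        base = got[untreated]
        directions = got.apply(
            lambda col: (col - base).map(lambda d: classify_direction(d, band))
        )
    return ComparisonReport(
        deviations=deviations,
        passed=passed,
        tolerance=tolerance,
        directions=directions,
    )
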