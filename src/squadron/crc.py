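"""The packaged colorectal-cancer model calibrated to HROC87 cells.

HROC87 is a low-passage, microsatellite-instable colorectal cancer cell
line carrying a BRAF(V600E) mutation and a p53 mutation.  The model wires
the two receptor arms (EGFR and HGFR/MET) into the RAS–RAF–MEK–ERK cascade
and the PI3K–AKT axis, and connects both to the intrinsic apoptosis
machinery (p53, PTEN, BAD, Bcl2, BAX, Casp3/7) and to the two phenotype
readouts ``apoptosis`` and ``proliferation``.

Four drug nodes act as inhibitory inputs: gefitinib on the active EGFR,
vemurafenib on the mutant-BRAF activity (the wild-type RAF arm stays
drug-insensitive, which is why BRAF blockade alone barely dents MEK–ERK
output in this background), a generic MEK inhibitor, and a Bcl2 inhibitor.
Mutations enter as clamped inputs: ``BRAF(V600)-Act`` drives the mutant
BRAF node constitutively, ``p53-Mut`` suppresses functional p53 so that
PTEN and BAX lose their upstream activator.  The auxiliary nodes
``ERK-Inh``, ``c-Myc-Inh`` and ``c-Myc-Act`` carry the scenario-specific
calibration levels of the pre-stimulation table.

All non-default gains, decays and edge weights are calibration constants
(recorded in the model metadata); they were tuned once so that the six
treatment scenarios reproduce the reference steady-state readouts.
"""

from __future__ import annotations

from importlib import resources

from .io import parse_model, parse_scenarios
from .model import NetworkModel, ScenarioSpec

__all__ = [
    "load_crc_hroc87",
    "load_treatment_scenarios",
    "load_reference_readouts",
    "READOUT_NODES",
    "SCENARIO_NAMES",
]

#: Readout rows of the reference table, in its printed order.
READOUT_NODES = ["apoptosis", "proliferation", "(HGFR)*", "ERK", "(EGFR)*", "AKT"]

#: The six treatment scenarios, in pre-stimulation-table order.
SCENARIO_NAMES = ["untr.", "+gef", "+vem", "+combi", "+MEK-Inh", "+BCL2-Inh"]


def _read_data(filename: str) -> str:
    return resources.files("squadron.data").joinpath(filename).read_text("utf-8")


def load_crc_hroc87() -> NetworkModel:
    """Load the packaged, calibrated HROC87 CRC model."""
    model = parse_model(_read_data("hroc87.json"), format="json")
    model.validate()
    return model


def load_treatment_scenarios() -> list[ScenarioSpec]:
    """The six treatment scenarios (pre-stimulation clamps)."""
    return parse_scenarios(_read_data("treatment_scenarios.tsv"))


def load_reference_readouts():
    """Reference steady-state readout table as a :class:`ReadoutTable`."""
    from .scenarios import ReadoutTable

    scenarios = parse_scenarios(_read_data("reference_readouts.tsv"))
    values = {
        sc.name: {node: sc.clamps[node] for node in READOUT_NODES}
        for sc in scenarios
    }
    return ReadoutTable(
        rows=list(READOUT_NODES),
        columns=[sc.name for sc in scenarios],
        values=values,
        converged={sc.name: {node: True for node in READOUT_NODES} for sc in scenarios},
    )
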