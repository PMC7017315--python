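"""Continuous semi-quantitative dynamics of a signed network.

Each node activity :math:`x_i \\in [0, 1]` follows

.. math::

    \\frac{dx_i}{dt} = f_{h_i}(\\omega_i) - \\gamma_i x_i

where :math:`\\omega_i` is the normalized input weight aggregated from the
node's activators and inhibitors and :math:`f_h` is a normalized sigmoid
with :math:`f_h(0) = 0`, :math:`f_h(1/2) = 1/2`, :math:`f_h(1) = 1`.  This
is the standard continuous relaxation of a Boolean regulatory network used
by semi-quantitative network simulators: steady states of the high-gain
system sit near the fixed points of the underlying Boolean model, while at
moderate gain intermediate activation levels become meaningful.

Input weight.  With activator activities :math:`x_a` (weights
:math:`\\alpha_a`) and inhibitor activities :math:`x_b` (weights
:math:`\\beta_b`),

.. math::

    \\omega = \\underbrace{\\frac{1+\\sum\\alpha}{\\sum\\alpha}
        \\cdot \\frac{\\sum\\alpha x}{1 + \\sum\\alpha x}}_{A}
        \\cdot \\Bigl(1 - \\underbrace{\\frac{1+\\sum\\beta}{\\sum\\beta}
        \\cdot \\frac{\\sum\\beta x}{1 + \\sum\\beta x}}_{I}\\Bigr)

with the conventions: no activators => :math:`A = 1` (constitutive), no
inhibitors => :math:`I = 0`, and no inputs at all => :math:`\\omega = 0`
(an isolated node simply decays).

Clamped nodes are removed from the integrated state vector and substituted
algebraically, so clamp fidelity is exact rather than enforced stiffly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import ModelValidationError, NetworkModel, ScenarioSpec

__all__ = [
    "ContinuousState",
    "SimulationResult",
    "IntegrationError",
    "input_weight",
    "response",
    "derivative",
    "simulate",
    "find_steady_state",
    "SimulationConfig",
]

#: Convergence criterion: max |dx/dt| over free nodes.
DEFAULT_TOLERANCE = 1e-6
#: Default simulation horizon (dimensionless time units).
DEFAULT_T_END = 100.0
#: Default number of equally spaced output points.
DEFAULT_N_OUTPUT = 400


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the last valid state."""

    def __init__(self, message: str, last_state: "ContinuousState | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ContinuousState:
    """Activities of every node at one time point."""

    activities: dict[str, float]
    time: float = 0.0

    def __getitem__(self, name: str) -> float:
        return self.activities[name]


@dataclass
class SimulationResult:
    """Trajectory plus (when reached) the steady state of one scenario."""

    trajectory: list[ContinuousState]
    steady_state: ContinuousState | None
    converged: bool
    convergence_norm: float
    scenario: str = ""

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.trajectory])

    def activity_of(self, name: str) -> np.ndarray:
        return np.array([s.activities[name] for s in self.trajectory])


@dataclass
class SimulationConfig:
    """Integrator and convergence settings (all config-exposed)."""

    t_end: float = DEFAULT_T_END
    n_output: int = DEFAULT_N_OUTPUT
    tolerance: float = DEFAULT_TOLERANCE
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"


def input_weight(
    activator_levels: Sequence[tuple[float, float]],
    inhibitor_levels: Sequence[tuple[float, float]],
) -> float:
    """Aggregate activator/inhibitor activities into a single drive in [0, 1].

    Parameters are sequences of ``(activity, weight)`` pairs.  The activator
    and inhibitor sums are each normalized so that a full set of saturated
    activators (and no inhibition) yields exactly 1, and any single
    inhibitor at activity 1 fully silences the node.
    """
    for level, weight in list(activator_levels) + list(inhibitor_levels):
        if weight < 0:
            raise ModelValidationError(f"negative input weight {weight}")
        if not 0.0 <= level <= 1.0:
            raise ModelValidationError(f"input activity {level} outside [0, 1]")
    if not activator_levels and not inhibitor_levels:
        return 0.0
    if activator_levels:
        total_w = sum(w for _, w in activator_levels)
        wx = sum(w * x for x, w in activator_levels)
        act = ((1.0 + total_w) / total_w) * (wx / (1.0 + wx))
    else:
        act = 1.0
    if inhibitor_levels:
        total_w = sum(w for _, w in inhibitor_levels)
        wx = sum(w * x for x, w in inhibitor_levels)
        inh = ((1.0 + total_w) / total_w) * (wx / (1.0 + wx))
    else:
        inh = 0.0
    omega = act * (1.0 - inh)
    # guard against roundoff just outside the unit interval
    return min(1.0, max(0.0, omega))


def response(omega: float, gain: float) -> float:
    """Normalized sigmoid response ``f_h(omega)``.

    .. math::

        f_h(\\omega) = \\frac{-e^{h/2} + e^{-h(\\omega - 1/2)}}
                            {(1 - e^{h/2})(1 + e^{-h(\\omega - 1/2)})}

    Strictly increasing on [0, 1] with fixed points 0, 1/2 and 1 at the
    corresponding arguments, for every gain ``h > 0``.
    """
    if not 0.0 <= omega <= 1.0:
        raise ModelValidationError(f"omega {omega} outside [0, 1]")
    if not gain > 0:
        raise ModelValidationError(f"gain must be positive, got {gain}")
    half = math.exp(0.5 * gain)
    ez = math.exp(-gain * (omega - 0.5))
    return (-half + ez) / ((1.0 - half) * (1.0 + ez))


def _omega_of(model: NetworkModel, name: str, activities: Mapping[str, float]) -> float:
    acts = [(activities[e.source], e.weight) for e in model.activators_of(name)]
    inhs = [(activities[e.source], e.weight) for e in model.inhibitors_of(name)]
    return input_weight(acts, inhs)


def derivative(
    model: NetworkModel,
    state: ContinuousState | Mapping[str, float],
    clamps: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-node time derivative; clamped nodes get exactly 0."""
    activities = state.activities if isinstance(state, ContinuousState) else dict(state)
    clamps = clamps or {}
    for node in clamps:
        if node not in model.nodes:
            raise ModelValidationError(f"clamp on unknown node {node!r}")
    out: dict[str, float] = {}
    for name, node in model.nodes.items():
        if name in clamps:
            out[name] = 0.0
            continue
        omega = _omega_of(model, name, activities)
        out[name] = response(omega, node.gain) - node.decay * activities[name]
    return out


def _initial_activities(model: NetworkModel, scenario: ScenarioSpec) -> dict[str, float]:
    x0 = {name: 0.0 for name in model.nodes}
    x0.update(scenario.initials)
    x0.update(scenario.clamps)
    return x0


def simulate(
    model: NetworkModel,
    scenario: ScenarioSpec,
    config: SimulationConfig | None = None,
) -> SimulationResult:
    """Integrate the coupled system for one scenario.

    Clamped nodes are held algebraically at their clamp value; all other
    nodes start from their declared initial (default 0) and evolve freely.
    Output activities are hard-projected onto [0, 1] to absorb integrator
    roundoff.  Convergence is declared when ``max |dx/dt| < tolerance`` at
    the final time.
    """
    config = config or SimulationConfig()
    missing = scenario.check_against(model)
    if missing:
        raise ModelValidationError(
            f"scenario {scenario.name!r} references unknown nodes: {missing}"
        )
    free = [n for n in model.nodes if n not in scenario.clamps]
    clamps = dict(scenario.clamps)
    x0_map = _initial_activities(model, scenario)

    gains = np.array([model.nodes[n].gain for n in free])
    decays = np.array([model.nodes[n].decay for n in free])
    free_index = {n: i for i, n in enumerate(free)}

    # Pre-compile the input structure of each free node: lists of
    # (free-index or None, clamped-value, weight) for activators/inhibitors.
    def compile_inputs(edges):
        entries = []
        for e in edges:
            if e.source in free_index:
                entries.append((free_index[e.source], 0.0, e.weight))
            else:
                entries.append((None, clamps[e.source], e.weight))
        return entries

    act_in = [compile_inputs(model.activators_of(n)) for n in free]
    inh_in = [compile_inputs(model.inhibitors_of(n)) for n in free]

    exp_half = np.exp(0.5 * gains)

    def omegas(x: np.ndarray) -> np.ndarray:
        xc = np.clip(x, 0.0, 1.0)
        out = np.empty(len(free))
        for i in range(len(free)):
            acts = act_in[i]
            inhs = inh_in[i]
            if not acts and not inhs:
                out[i] = 0.0
                continue
            if acts:
                tw = sum(w for _, _, w in acts)
                wx = sum(w * (xc[j] if j is not None else v) for j, v, w in acts)
                a = ((1.0 + tw) / tw) * (wx / (1.0 + wx))
            else:
                a = 1.0
            if inhs:
                tw = sum(w for _, _, w in inhs)
                wx = sum(w * (xc[j] if j is not None else v) for j, v, w in inhs)
                b = ((1.0 + tw) / tw) * (wx / (1.0 + wx))
            else:
                b = 0.0
            out[i] = a * (1.0 - b)
        return np.clip(out, 0.0, 1.0)

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        om = omegas(x)
        ez = np.exp(-gains * (om - 0.5))
        resp = (-exp_half + ez) / ((1.0 - exp_half) * (1.0 + ez))
        return resp - decays * np.clip(x, 0.0, 1.0)

    t_eval = np.linspace(0.0, config.t_end, config.n_output)
    x0 = np.array([x0_map[n] for n in free])

    if free:
        sol = solve_ivp(
            rhs,
            (0.0, config.t_end),
            x0,
            method=config.method,
            t_eval=t_eval,
            rtol=config.rtol,
            atol=config.atol,
        )
        if not sol.success:
            last = None
            if sol.y.size:
                last = _assemble_state(free, sol.y[:, -1], clamps, sol.t[-1])
            raise IntegrationError(f"integrator failed: {sol.message}", last)
        ys = np.clip(sol.y, 0.0, 1.0)
        final = ys[:, -1]
        residual = float(np.max(np.abs(rhs(config.t_end, final)))) if free else 0.0
    else:
        ys = np.zeros((0, len(t_eval)))
        final = np.zeros(0)
        residual = 0.0

    trajectory = [
        _assemble_state(free, ys[:, k], clamps, float(t_eval[k]))
        for k in range(len(t_eval))
    ]
    converged = residual < config.tolerance
    steady = trajectory[-1] if converged else None
    if not converged:
        warnings.warn(
            f"scenario {scenario.name!r} did not converge within t_end="
            f"{config.t_end} (max |dx/dt| = {residual:.3g}); possible oscillation",
            stacklevel=2,
        )
    return SimulationResult(
        trajectory=trajectory,
        steady_state=steady,
        converged=converged,
        convergence_norm=residual,
        scenario=scenario.name,
    )


def _assemble_state(
    free: Sequence[str],
    x: np.ndarray,
    clamps: Mapping[str, float],
    t: float,
) -> ContinuousState:
    activities = dict(clamps)
    for name, value in zip(free, x):
        activities[name] = float(min(1.0, max(0.0, value)))
    return ContinuousState(activities=activities, time=t)


def find_steady_state(
    model: NetworkModel,
    scenario: ScenarioSpec,
    config: SimulationConfig | None = None,
) -> tuple[ContinuousState, bool]:
    """Run :func:`simulate` and return (final state, converged flag).

    The returned state is the trajectory endpoint; when the convergence
    criterion is met it is the steady state (clamped nodes at exactly their
    clamp value).
    """
    result = simulate(model, scenario, config)
    if result.steady_state is not None:
        return result.steady_state, True
    return result.trajectory[-1], False


def propagate_dag_steady_state(
    model: NetworkModel,
    clamps: Mapping[str, float],
) -> dict[str, float]:
    """Closed-form steady state for acyclic models.

    When the free part of the network is a DAG, the unique fixed point can
    be computed by propagating ``x* = f_h(omega)/gamma`` in topological
    order.  Used as an internal cross-check against the integrator and for
    fast calibration; raises if the free subgraph contains a cycle.
    """
    import networkx as nx

    graph = model.to_networkx()
    free = [n for n in model.nodes if n not in clamps]
    sub = graph.subgraph(free)
    order = list(nx.topological_sort(sub))
    activities: dict[str, float] = {n: 0.0 for n in model.nodes}
    activities.update(clamps)
    for name in order:
        omega = _omega_of(model, name, activities)
        node = model.nodes[name]
        activities[name] = min(1.0, max(0.0, response(omega, node.gain) / node.decay))
    return activities
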