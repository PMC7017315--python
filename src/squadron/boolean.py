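"""Discrete Boolean dynamics — the exhaustive oracle for the continuous engine.

The default node logic is inhibitor-dominant:

    next(v) = OR(activators) AND NOT OR(inhibitors)

with two conventions matching the continuous input-weight rules: a node
with inhibitors but no activators uses a constitutive 1 in place of the
activator term, and a node with no inputs at all relaxes to 0.  Updates
are synchronous; clamped nodes never change.
"""

from __future__ import annotations

from typing import Mapping

from .model import ModelValidationError, NetworkModel

__all__ = [
    "BooleanState",
    "boolean_update",
    "enumerate_fixed_points",
    "reachable_attractor",
    "MAX_EXHAUSTIVE_NODES",
]

#: Exhaustive fixed-point enumeration sweeps 2^n states; refuse beyond this.
MAX_EXHAUSTIVE_NODES = 20

# A BooleanState is a hashable total assignment: frozenset of (name, value).
# We expose it as a plain dict in the public API and convert internally.
BooleanState = dict[str, int]


def _check_state(model: NetworkModel, state: Mapping[str, int]) -> None:
    if set(state) != set(model.nodes):
        missing = set(model.nodes) - set(state)
        extra = set(state) - set(model.nodes)
        raise ModelValidationError(
            f"state is not total: missing {sorted(missing)}, extra {sorted(extra)}"
        )
    for name, value in state.items():
        if value not in (0, 1):
            raise ModelValidationError(f"state[{name!r}] = {value!r} is not binary")


def _check_clamps(model: NetworkModel, clamps: Mapping[str, int]) -> None:
    for name, value in clamps.items():
        if name not in model.nodes:
            raise ModelValidationError(f"clamp on unknown node {name!r}")
        if value not in (0, 1):
            raise ModelValidationError(f"clamp[{name!r}] = {value!r} is not binary")


def boolean_update(
    model: NetworkModel,
    state: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
) -> BooleanState:
    """One synchronous step of the inhibitor-dominant default logic."""
    clamps = clamps or {}
    _check_state(model, state)
    _check_clamps(model, clamps)
    nxt: BooleanState = {}
    for name in model.nodes:
        if name in clamps:
            nxt[name] = clamps[name]
            continue
        activators = model.activators_of(name)
        inhibitors = model.inhibitors_of(name)
        if not activators and not inhibitors:
            nxt[name] = 0
            continue
        if activators:
            act = int(any(state[e.source] for e in activators))
        else:
            act = 1  # constitutive: only inhibitors regulate this node
        inh = int(any(state[e.source] for e in inhibitors))
        nxt[name] = act & (1 - inh)
    return nxt


def enumerate_fixed_points(
    model: NetworkModel,
    clamps: Mapping[str, int] | None = None,
) -> set[frozenset[tuple[str, int]]]:
    """All states with ``boolean_update(s) == s``, by exhaustive 2^n sweep.

    Returns a set of frozensets of ``(name, value)`` pairs so fixed points
    are hashable; convert with ``dict(fp)``.
    """
    clamps = clamps or {}
    _check_clamps(model, clamps)
    free = [n for n in model.nodes if n not in clamps]
    if len(free) > MAX_EXHAUSTIVE_NODES:
        raise ModelValidationError(
            f"{len(free)} unclamped nodes exceeds the exhaustive-sweep bound "
            f"of {MAX_EXHAUSTIVE_NODES}"
        )
    fixed: set[frozenset[tuple[str, int]]] = set()
    for bits in range(1 << len(free)):
        state: BooleanState = dict(clamps)
        for i, name in enumerate(free):
            state[name] = (bits >> i) & 1
        if boolean_update(model, state, clamps) == state:
            fixed.add(frozenset(state.items()))
    return fixed


def reachable_attractor(
    model: NetworkModel,
    start: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
) -> list[BooleanState]:
    """Iterate synchronous updates from *start* until a state repeats.

    Returns the attractor cycle in order of traversal (length 1 for a
    fixed point).  Termination is guaranteed in at most 2^n steps.
    """
    clamps = clamps or {}
    state = dict(start)
    state.update(clamps)
    _check_state(model, state)
    seen: dict[frozenset[tuple[str, int]], int] = {}
    history: list[BooleanState] = []
    while True:
        key = frozenset(state.items())
        if key in seen:
            return history[seen[key]:]
        seen[key] = len(history)
        history.append(dict(state))
        state = boolean_update(model, state, clamps)
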