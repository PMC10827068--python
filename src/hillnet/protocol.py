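"""Staged simulation protocols and the systematic knockout screen.

A protocol is an ordered list of steps; each step changes some reaction
weights and/or species parameters instantaneously and then integrates
for a duration, continuing from the exact end state of the previous
step.  This mirrors the interactive workflow of logic-based network
GUIs: change a weight, simulate, change another, simulate again.
Parameter changes persist across later steps; a fresh protocol run is
the equivalent of "reset parameters / reset simulation".

Protocol files are plain YAML or JSON::

    n_out_per_step: 101
    steps:
      - duration: 10
      - duration: 10
        weights: {r1: 1}
        species: {NKX25: {ymax: 0, tau: 2}}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dynamics import TimeCourse, simulate_segment, steady_state
from .model import (
    ModelError,
    NetworkModel,
    apply_knockout,
    set_reaction_weight,
    set_species_params,
)

__all__ = [
    "ProtocolStep",
    "SimulationProtocol",
    "KnockoutRow",
    "KnockoutScreenResult",
    "run_protocol",
    "run_knockout_protocol",
    "knockout_screen",
    "load_protocol",
    "protocol_from_dict",
]


@dataclass(frozen=True)
class ProtocolStep:
    """One segment: parameter changes applied at its start, then a run."""

    duration: float = 10.0
    weight_changes: Mapping[str, float] = field(default_factory=dict)
    species_changes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class SimulationProtocol:
    steps: tuple[ProtocolStep, ...]
    n_out_per_step: int = 101

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a protocol needs at least one step")


_SPECIES_KEYS = {"ymax": "y_max", "y_max": "y_max", "tau": "tau"}


def protocol_from_dict(d: Mapping) -> SimulationProtocol:
    """Build a protocol from the YAML/JSON schema (see module docstring)."""
    steps = []
    for i, raw in enumerate(d.get("steps", [])):
        try:
            duration = float(raw.get("duration", 10.0))
            weights = {str(k): float(v) for k, v in (raw.get("weights") or {}).items()}
            species = {}
            for sid, overrides in (raw.get("species") or {}).items():
                clean = {}
                for k, v in overrides.items():
                    if k not in _SPECIES_KEYS:
                        raise ValueError(f"unknown species override {k!r} (use ymax/tau)")
                    clean[_SPECIES_KEYS[k]] = float(v)
                species[str(sid)] = clean
        except (TypeError, ValueError, AttributeError) as e:
            raise ValueError(f"protocol step {i}: {e}") from e
        steps.append(ProtocolStep(duration, weights, species))
    if not steps:
        raise ValueError("protocol file defines no steps")
    return SimulationProtocol(tuple(steps), int(d.get("n_out_per_step", 101)))


def load_protocol(path) -> SimulationProtocol:
    """Read a protocol file (YAML; JSON is a YAML subset)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValueError(f"protocol file {path} must contain a mapping")
    return protocol_from_dict(data)


def _apply_step_changes(model: NetworkModel, step: ProtocolStep, index: int) -> NetworkModel:
    try:
        for rid, w in step.weight_changes.items():
            model = set_reaction_weight(model, rid, w)
        for sid, overrides in step.species_changes.items():
            model = set_species_params(
                model, sid, y_max=overrides.get("y_max"), tau=overrides.get("tau")
            )
    except ModelError as e:
        raise ModelError(f"protocol step {index}: {e}") from e
    return model


def run_protocol(model: NetworkModel, protocol: SimulationProtocol) -> TimeCourse:
    """Run the staged protocol; returns one continuous time course.

    Each step's parameter changes are step functions applied at the
    segment boundary; the state continues from the exact final
    integrator state of the previous segment (never a re-interpolated
    value).  All changes are validated up front so an invalid step
    aborts before any integration.
    """
    staged = model
    for i, step in enumerate(protocol.steps):
        staged = _apply_step_changes(staged, step, i)  # validation pass

    times: list[np.ndarray] = []
    acts: list[np.ndarray] = []
    boundaries: list[float] = []
    y = None
    t = 0.0
    current = model
    for i, step in enumerate(protocol.steps):
        current = _apply_step_changes(current, step, i)
        tc = simulate_segment(current, y, step.duration, protocol.n_out_per_step, t0=t)
        y = tc.final_state
        t = float(tc.times[-1])
        if times:
            # the boundary row duplicates the previous segment's end state
            times.append(tc.times[1:])
            acts.append(tc.activities[1:])
        else:
            times.append(tc.times)
            acts.append(tc.activities)
        boundaries.append(t)
    return TimeCourse(
        times=np.concatenate(times),
        activities=np.vstack(acts),
        species_ids=model.species_ids,
        segment_boundaries=tuple(boundaries[:-1]),
    )


def run_knockout_protocol(
    model: NetworkModel, species_id: str, protocol: SimulationProtocol
) -> TimeCourse:
    """Knock out one species (y_max = 0), then run the protocol."""
    return run_protocol(apply_knockout(model, species_id), protocol)


# ---------------------------------------------------------------------
# systematic knockout screen
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class KnockoutRow:
    species_id: str
    steady_state: np.ndarray
    delta: np.ndarray  # knockout steady state minus baseline
    converged: bool


@dataclass(frozen=True)
class KnockoutScreenResult:
    species_ids: tuple[str, ...]
    baseline_ss: np.ndarray
    baseline_converged: bool
    rows: tuple[KnockoutRow, ...]

    def to_dataframe(self):
        """Delta table: one row per knockout, one column per species."""
        import pandas as pd

        df = pd.DataFrame(
            [r.delta for r in self.rows],
            index=[r.species_id for r in self.rows],
            columns=list(self.species_ids),
        )
        df.index.name = "knockout"
        df["converged"] = [r.converged for r in self.rows]
        return df


def knockout_screen(
    model: NetworkModel,
    targets: Sequence[str] | str = "all",
    input_weights: Mapping[str, float] | None = None,
    tol: float = 1e-6,
    t_cap: float | None = None,
) -> KnockoutScreenResult:
    """Single-knockout screen against a stimulated baseline steady state.

    Every input reaction's weight defaults to 1 ("all stimuli on")
    unless overridden via ``input_weights`` (which may also set weights
    of non-input reactions).  For each target species, y_max is set to 0
    and the steady state re-computed by integration to convergence;
    deltas are knockout minus baseline.  Non-convergence (oscillatory
    networks) is flagged per row, never fatal.
    """
    stimulated = model
    overrides = dict(input_weights or {})
    for r in model.input_reactions:
        if r.id not in overrides:
            stimulated = set_reaction_weight(stimulated, r.id, 1.0)
    for rid, w in overrides.items():
        stimulated = set_reaction_weight(stimulated, rid, w)

    if isinstance(targets, str):
        if targets != "all":
            raise ModelError(f"targets must be 'all' or a list of species ids, got {targets!r}")
        target_ids = list(stimulated.species_ids)
    else:
        target_ids = [str(t) for t in targets]
        for t in target_ids:
            stimulated.species_index(t)  # raises on unknown id
        # deterministic ordering by species index regardless of input order
        target_ids.sort(key=stimulated.species_index)

    baseline_ss, base_conv = steady_state(stimulated, tol=tol, t_cap=t_cap)
    rows = []
    for sid in target_ids:
        ko = apply_knockout(stimulated, sid)
        ss, conv = steady_state(ko, tol=tol, t_cap=t_cap)
        rows.append(KnockoutRow(sid, ss, ss - baseline_ss, conv))
    return KnockoutScreenResult(
        species_ids=stimulated.species_ids,
        baseline_ss=baseline_ss,
        baseline_converged=base_conv,
        rows=tuple(rows),
    )
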