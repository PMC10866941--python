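"""Per-agent kinetics: aging, division with space search, quiescence, death.

One agent step advances a cell by ``dt`` hours.  A cycling cell whose age
reaches its doubling time attempts mitosis: spontaneous death is evaluated
once per completed cycle, a drug-fate hook (if any) runs next, and only a
cell that comes through unaffected searches for space.  With no vacancy in
rings 1..max_search_ring the cell parks in reversible quiescence and retries
every subsequent step, claiming freed space promptly.

Dying cells sit through a lysis period before their site turns to debris
(reusable space).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .lattice_core import (
    Cell,
    CellState,
    Lattice,
    SimulationConfig,
    draw_doubling_time,
    find_empty_site,
)

__all__ = ["EventLog", "step_cell", "attempt_division", "apply_spontaneous_death"]

#: fate_hook(cell) -> one of "proliferate", "G0", "die", or None (no drugs)
FateHook = Optional[Callable[[Cell], str]]


@dataclass
class EventLog:
    """Running event counters for one simulation (reset per replicate)."""

    divisions: int = 0
    quiescence_entries: int = 0
    spontaneous_deaths: int = 0
    drug_deaths: int = 0
    drug_arrests: int = 0
    g0_deaths: int = 0
    lysis_completions: int = 0
    #: state transitions seen, as (from, to) -> count; used for audits
    transitions: dict = field(default_factory=dict)

    def note_transition(self, old: CellState, new: CellState) -> None:
        key = (old, new)
        self.transitions[key] = self.transitions.get(key, 0) + 1


def apply_spontaneous_death(
    cell: Cell, config: SimulationConfig, rng: np.random.Generator
) -> bool:
    """Intrinsic death check at a cycle boundary.

    Returns True (and moves the cell to DYING) with probability
    ``spontaneous_death_prob``; evaluated at most once per cell cycle.
    """
    p = config.spontaneous_death_prob
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"spontaneous_death_prob outside [0, 1]: {p}")
    if p > 0.0 and rng.random() < p:
        cell.transition(CellState.DYING)
        cell.lysis_clock = config.lysis_period_h
        return True
    return False


def attempt_division(
    pos: tuple[int, int],
    cell: Cell,
    lattice: Lattice,
    config: SimulationConfig,
    rng: np.random.Generator,
    events: Optional[EventLog] = None,
) -> str:
    """Space-limited division: place a daughter or enter reversible quiescence.

    On success both mother and daughter reset age to zero and draw fresh
    doubling times; the mother's cycle index advances.  Returns "divided" or
    "quiescent".
    """
    target = find_empty_site(lattice, pos, config.max_search_ring, rng)
    if target is None:
        if cell.state == CellState.PROLIFERATIVE:
            cell.transition(CellState.QUIESCENT)
            if events:
                events.note_transition(CellState.PROLIFERATIVE, CellState.QUIESCENT)
                events.quiescence_entries += 1
        cell.age = cell.doubling_time  # held at threshold; re-attempts next step
        return "quiescent"
    if cell.state == CellState.QUIESCENT:
        cell.transition(CellState.PROLIFERATIVE)
        if events:
            events.note_transition(CellState.QUIESCENT, CellState.PROLIFERATIVE)
    cell.age = 0.0
    cell.doubling_time = draw_doubling_time(config, rng)
    cell.cycle_index += 1
    daughter = Cell(
        state=CellState.PROLIFERATIVE,
        age=0.0,
        doubling_time=draw_doubling_time(config, rng),
        cell_id=lattice.new_cell_id(),
        lineage=cell.lineage,
    )
    lattice.place(target, daughter)
    if events:
        events.divisions += 1
    return "divided"


def step_cell(
    pos: tuple[int, int],
    cell: Cell,
    lattice: Lattice,
    config: SimulationConfig,
    rng: np.random.Generator,
    dt: float,
    fate_hook: FateHook = None,
    spont_rng=None,
    events: Optional[EventLog] = None,
) -> None:
    """Advance one cell by ``dt`` hours, mutating cell and lattice in place.

    ``spont_rng`` supplies the spontaneous-death uniform (a per-cycle keyed
    stream in full simulations); it may be a Generator or a zero-argument
    factory returning one (built lazily, as most steps never need the draw),
    and defaults to ``rng``.  ``fate_hook`` is the drug decision applied at
    mitosis, before the space search.
    """

    def _spont_source() -> np.random.Generator:
        if spont_rng is None:
            return rng
        return spont_rng() if callable(spont_rng) else spont_rng

    if dt <= 0:
        raise ValueError("dt must be positive")
    if cell.state == CellState.DEBRIS:
        raise ValueError("cannot step a DEBRIS site")

    if cell.state == CellState.DYING:
        cell.lysis_clock -= dt
        if cell.lysis_clock <= 0.0:
            cell.transition(CellState.DEBRIS)
            lattice.remove(pos, to_debris=True)
            if events:
                events.note_transition(CellState.DYING, CellState.DEBRIS)
                events.lysis_completions += 1
        return

    cell.age += dt

    if cell.state == CellState.G0_ARRESTED:
        # Arrested cells no longer divide; an optional necrosis hazard is
        # evaluated on the same cycle cadence.
        if config.g0_death_prob > 0.0 and cell.age >= cell.doubling_time:
            cell.age -= cell.doubling_time
            cell.cycle_index += 1
            if _spont_source().random() < config.g0_death_prob:
                cell.transition(CellState.DYING)
                cell.lysis_clock = config.lysis_period_h
                if events:
                    events.note_transition(CellState.G0_ARRESTED, CellState.DYING)
                    events.g0_deaths += 1
        return

    if cell.age < cell.doubling_time:
        return

    # --- mitosis attempt ---------------------------------------------------
    old_state = cell.state

    if cell.spont_checked_cycle < cell.cycle_index:
        cell.spont_checked_cycle = cell.cycle_index
        if apply_spontaneous_death(cell, config, _spont_source()):
            if events:
                events.note_transition(old_state, CellState.DYING)
                events.spontaneous_deaths += 1
            return

    if fate_hook is not None:
        outcome = fate_hook(cell)
        if outcome == "G0":
            cell.transition(CellState.G0_ARRESTED)
            if events:
                events.note_transition(old_state, CellState.G0_ARRESTED)
                events.drug_arrests += 1
            return
        if outcome == "die":
            cell.transition(CellState.DYING)
            cell.lysis_clock = config.lysis_period_h
            if events:
                events.note_transition(old_state, CellState.DYING)
                events.drug_deaths += 1
            return
        if outcome != "proliferate":
            raise ValueError(f"unknown fate outcome {outcome!r}")

    attempt_division(pos, cell, lattice, config, rng, events)
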