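"""Simulation driver: couples cell agents, drug fields, and fate decisions.

Time zero is the moment of treatment.  Each agent step (default 1 h)
advances every drug field across the step (implicit PDE substeps, default
60 s), folds the fields into each cell's exposure record, then steps the
agents in a freshly shuffled order.  Fate draws at mitosis come from
counter-based streams keyed by (cell id, cycle index, drug) -- see
:mod:`spheroidsim.streams` -- which makes replicates reproducible and a
zero-dose combination arm bitwise identical to the monotherapy run.

Replicate seeds derive from ``SeedSequence(base_seed, spawn_key=(rep,))``
so they do not depend on which drugs are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import streams
from .analysis_metrics import GrowthRecord
from .cell_kinetics import EventLog, step_cell
from .combination_model import decide_fate_combination
from .drug_transport import DosingSchedule, DrugField, DrugParams, record_max_concentration
from .lattice_core import (
    CellState,
    Lattice,
    SimulationConfig,
    census,
    init_monolayer,
    init_spheroid_slice,
)
from .pharmacodynamics import FateModel

__all__ = ["DrugSpec", "SimulationResult", "run_simulation", "run_replicates"]


@dataclass(frozen=True)
class DrugSpec:
    """Everything the engine needs for one drug: transport + calibrated fate."""

    params: DrugParams
    schedule: DosingSchedule
    fate_model: FateModel

    def with_transport_mode(self, mode: str) -> "DrugSpec":
        return DrugSpec(
            params=replace(self.params, transport_mode=mode),
            schedule=self.schedule,
            fate_model=self.fate_model,
        )

    def with_dose(self, dose_M: float) -> "DrugSpec":
        return DrugSpec(
            params=replace(self.params, boundary_dose_M=dose_M),
            schedule=self.schedule,
            fate_model=self.fate_model,
        )


@dataclass
class SimulationResult:
    """Census time series, death kinetics, and event totals for one run."""

    days: np.ndarray
    census_frame: pd.DataFrame
    viable_area_um2: np.ndarray
    death_events_per_day: pd.DataFrame
    events: EventLog
    final_snapshot: np.ndarray
    snapshots: dict = field(default_factory=dict)

    @property
    def viable_counts(self) -> np.ndarray:
        return self.census_frame["viable"].to_numpy()


def _initial_lattice(config: SimulationConfig, rng: np.random.Generator) -> Lattice:
    if config.initial_configuration == "monolayer":
        return init_monolayer(config, config.n_initial_cells, rng)
    return init_spheroid_slice(config, config.initial_radius_sites, rng)


def run_simulation(
    config: SimulationConfig,
    drugs: Sequence[DrugSpec],
    seed: int,
    policy: str = "toxic_dominates",
    snapshot_days: Sequence[float] = (),
) -> SimulationResult:
    """Run one replicate from treatment time to ``config.total_days``.

    ``drugs`` may be empty (untreated control).  ``seed`` should come from a
    replicate-independent derivation (see :func:`run_replicates`).
    """
    ss = np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.Philox(ss))
    # fate-draw root: derived from the same seed, independent of drug list
    seed_root = int(np.random.SeedSequence(seed, spawn_key=(0xFA7E,)).generate_state(1)[0])

    lattice = _initial_lattice(config, rng)
    fields = [
        DrugField(
            spec.params,
            spec.schedule,
            config.n_rows,
            config.n_cols,
            config.spacing_um,
        )
        for spec in drugs
    ]
    fate_models = {spec.fate_model.name: spec.fate_model for spec in drugs}
    events = EventLog()

    if fate_models:
        def fate_hook(cell):
            outcome = decide_fate_combination(
                cell, fate_models, policy, rng, seed_root=seed_root
            )
            return {"proliferate": "proliferate", "G0": "G0", "die": "die"}[outcome]
    else:
        fate_hook = None

    dt = config.agent_dt_h
    n_steps = int(round(config.total_hours / dt))
    record_every = max(1, int(round(config.record_interval_days * 24.0 / dt)))
    snapshot_steps = {int(round(d * 24.0 / dt)) for d in snapshot_days}

    census_rows = []
    days = []
    areas = []
    snapshots = {}
    death_day_bins: dict[int, int] = {}
    area_factor = config.spacing_um**2

    def record(step: int) -> None:
        c = census(lattice)
        row = c.as_dict()
        row["day"] = step * dt / 24.0
        census_rows.append(row)
        days.append(row["day"])
        areas.append(c.viable * area_factor)

    # initial exposure so that fate lookups at the first mitoses see the field
    for f in fields:
        record_max_concentration(f, lattice)
    record(0)

    deaths_before = 0
    for step in range(1, n_steps + 1):
        t0 = (step - 1) * dt
        for f in fields:
            f.advance(lattice, t0, dt, config.pde_dt_s)
            record_max_concentration(f, lattice)

        items = list(lattice.cells.items())
        order = rng.permutation(len(items))
        for idx in order:
            pos, cell = items[idx]
            if cell.state == CellState.DEBRIS:
                continue

            def spont_stream(cell=cell):
                return streams.keyed_generator(
                    seed_root, cell.cell_id, cell.cycle_index, streams.SPONTANEOUS_CHANNEL
                )

            step_cell(
                pos,
                cell,
                lattice,
                config,
                rng,
                dt,
                fate_hook=fate_hook,
                spont_rng=spont_stream,
                events=events,
            )

        deaths_now = (
            events.spontaneous_deaths + events.drug_deaths + events.g0_deaths
        )
        day_bin = int(np.ceil(step * dt / 24.0))
        death_day_bins[day_bin] = death_day_bins.get(day_bin, 0) + (
            deaths_now - deaths_before
        )
        deaths_before = deaths_now

        if step % record_every == 0 or step == n_steps:
            record(step)
        if step in snapshot_steps:
            snapshots[step * dt / 24.0] = lattice.snapshot()

    census_frame = pd.DataFrame(census_rows).drop_duplicates(subset="day")
    death_frame = pd.DataFrame(
        {
            "day": sorted(death_day_bins),
            "deaths": [death_day_bins[d] for d in sorted(death_day_bins)],
        }
    )
    return SimulationResult(
        days=np.array(sorted(set(days))),
        census_frame=census_frame.reset_index(drop=True),
        viable_area_um2=census_frame["viable"].to_numpy() * area_factor,
        death_events_per_day=death_frame,
        events=events,
        final_snapshot=lattice.snapshot(),
    )


def run_replicates(
    config: SimulationConfig,
    drugs: Sequence[DrugSpec],
    base_seed: int,
    n_replicates: Optional[int] = None,
    policy: str = "toxic_dominates",
    condition: Optional[str] = None,
) -> GrowthRecord:
    """Run replicates and collect viable-area trajectories.

    Replicate ``rep`` uses ``SeedSequence(base_seed, spawn_key=(rep,))``, so
    a given replicate is reproducible irrespective of how many replicates
    are requested or which drugs are in play.  The individual
    ``SimulationResult`` objects are attached as ``record.results``.
    """
    reps = config.n_replicates if n_replicates is None else n_replicates
    results = []
    for rep in range(reps):
        seed = int(
            np.random.SeedSequence(base_seed, spawn_key=(rep,)).generate_state(1)[0]
        )
        results.append(run_simulation(config, drugs, seed, policy=policy))
    days = results[0].days
    areas = np.vstack([r.viable_area_um2 for r in results])
    if condition is None:
        if drugs:
            condition = "+".join(
                f"{s.fate_model.name}:{s.params.boundary_dose_M * 1e6:g}uM" for s in drugs
            )
        else:
            condition = "untreated"
    record = GrowthRecord(condition=condition, days=days, areas=areas)
    record.results = results  # type: ignore[attr-defined]
    return record
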