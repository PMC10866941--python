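"""Lattice, cell agents, and simulation configuration.

The tumor is represented on a square lattice whose sites each fit a single
cell of fixed size (site spacing h = 15 um). A site is empty, holds one live
or dying cell, or holds debris left behind after lysis. Debris sites are
reoccupiable by dividing neighbors; a site occupied by a dying cell is not.

Cell states:

* ``PROLIFERATIVE`` -- cycling, will attempt division when its age reaches
  its doubling time.
* ``QUIESCENT`` -- space-limited, reversible; re-checks for free space every
  step and resumes cycling when a neighboring site frees up.
* ``G0_ARRESTED`` -- drug-induced irreversible arrest (senescence-like).
  Counts as viable but never divides again.
* ``DYING`` -- in lysis; after the lysis period the site becomes debris.
* ``DEBRIS`` -- degraded remains, treated as reoccupiable space.
"""

from __future__ import annotations

import dataclasses
import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import yaml

__all__ = [
    "CellState",
    "Cell",
    "Lattice",
    "SimulationConfig",
    "Census",
    "init_monolayer",
    "init_spheroid_slice",
    "find_empty_site",
    "census",
]


class CellState(enum.IntEnum):
    """Discrete cell states; integer codes are used in grid snapshots (0 = empty)."""

    PROLIFERATIVE = 1
    QUIESCENT = 2
    G0_ARRESTED = 3
    DYING = 4
    DEBRIS = 5


#: Allowed state transitions.  G0 arrest and death are irreversible: a cell
#: may leave G0 only toward death, and a dying cell only toward debris.
ALLOWED_TRANSITIONS = {
    (CellState.PROLIFERATIVE, CellState.QUIESCENT),
    (CellState.QUIESCENT, CellState.PROLIFERATIVE),
    (CellState.PROLIFERATIVE, CellState.G0_ARRESTED),
    (CellState.QUIESCENT, CellState.G0_ARRESTED),
    (CellState.PROLIFERATIVE, CellState.DYING),
    (CellState.QUIESCENT, CellState.DYING),
    (CellState.G0_ARRESTED, CellState.DYING),
    (CellState.DYING, CellState.DEBRIS),
}

LIVE_STATES = (CellState.PROLIFERATIVE, CellState.QUIESCENT, CellState.G0_ARRESTED)


def _ring_offsets(radius: int) -> tuple[tuple[int, int], ...]:
    """(dr, dc) offsets of the Chebyshev ring at ``radius`` (cached)."""
    try:
        return _RING_OFFSET_CACHE[radius]
    except KeyError:
        offs = tuple(
            (dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if max(abs(dr), abs(dc)) == radius
        )
        _RING_OFFSET_CACHE[radius] = offs
        return offs


_RING_OFFSET_CACHE: dict[int, tuple[tuple[int, int], ...]] = {}


@dataclass
class Cell:
    """A single lattice agent.

    ``age`` is hours since the last division; a cell attempts mitosis once
    ``age >= doubling_time``.  ``max_conc`` records, per drug, the maximum
    extracellular concentration (molar) the cell has ever experienced; fate
    probabilities key on this exposure peak.  ``current_conc`` mirrors the
    instantaneous local concentration for diagnostics.
    """

    state: CellState = CellState.PROLIFERATIVE
    age: float = 0.0
    doubling_time: float = 22.0
    lysis_clock: float = 0.0
    max_conc: dict = field(default_factory=dict)
    current_conc: dict = field(default_factory=dict)
    cell_id: Optional[int] = None
    cycle_index: int = 0
    lineage: Optional[int] = None
    #: last cycle index at which the intrinsic-death check ran (at most once
    #: per cycle, even when a space-blocked cell re-attempts mitosis)
    spont_checked_cycle: int = -1

    def transition(self, new_state: CellState) -> None:
        """Change state, enforcing irreversibility of G0 arrest and death."""
        if new_state == self.state:
            return
        if (self.state, new_state) not in ALLOWED_TRANSITIONS:
            raise ValueError(
                f"forbidden state transition {self.state.name} -> {new_state.name}"
            )
        self.state = new_state

    def record_exposure(self, drug: str, conc: float) -> None:
        """Update the per-drug exposure peak (non-decreasing) and current value."""
        self.current_conc[drug] = conc
        prev = self.max_conc.get(drug, 0.0)
        if conc > prev:
            self.max_conc[drug] = conc
        elif drug not in self.max_conc:
            self.max_conc[drug] = prev

    @property
    def is_live(self) -> bool:
        return self.state in LIVE_STATES


class Lattice:
    """Square grid of sites; at most one cell per site.

    Live and dying cells are stored in ``cells`` (position -> Cell, insertion
    ordered); post-lysis debris positions in ``debris``.  Debris sites count
    as available space for division targets; sites held by dying cells do not.
    """

    def __init__(self, n_rows: int, n_cols: int, spacing_um: float = 15.0):
        if n_rows < 1 or n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        self.n_rows = int(n_rows)
        self.n_cols = int(n_cols)
        self.spacing_um = float(spacing_um)
        self.cells: dict[tuple[int, int], Cell] = {}
        self.debris: set[tuple[int, int]] = set()
        self._next_cell_id = 0
        self._boundary_warned = False

    # -- geometry -----------------------------------------------------------

    @property
    def capacity(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def center(self) -> tuple[int, int]:
        return (self.n_rows // 2, self.n_cols // 2)

    def in_bounds(self, pos: tuple[int, int]) -> bool:
        r, c = pos
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def is_vacant(self, pos: tuple[int, int]) -> bool:
        """True if a daughter cell may be placed here (empty or debris)."""
        return self.in_bounds(pos) and pos not in self.cells

    def ring_sites(self, pos: tuple[int, int], radius: int) -> list[tuple[int, int]]:
        """In-bounds sites at exactly Chebyshev distance ``radius`` from ``pos``."""
        r0, c0 = pos
        nr, nc = self.n_rows, self.n_cols
        out = []
        for dr, dc in _ring_offsets(radius):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < nr and 0 <= c < nc:
                out.append((r, c))
        return out

    # -- occupancy ----------------------------------------------------------

    def new_cell_id(self) -> int:
        cid = self._next_cell_id
        self._next_cell_id += 1
        return cid

    def place(self, pos: tuple[int, int], cell: Cell) -> None:
        if not self.in_bounds(pos):
            raise ValueError(f"position {pos} outside lattice")
        if pos in self.cells:
            raise ValueError(f"site {pos} already occupied")
        if cell.cell_id is None:
            cell.cell_id = self.new_cell_id()
        if cell.lineage is None:
            cell.lineage = cell.cell_id
        self.debris.discard(pos)
        self.cells[pos] = cell
        r, c = pos
        if (
            not self._boundary_warned
            and (r in (0, self.n_rows - 1) or c in (0, self.n_cols - 1))
        ):
            self._boundary_warned = True
            warnings.warn(
                "cell placed on the lattice boundary ring; the domain is too "
                "small for this run",
                RuntimeWarning,
                stacklevel=2,
            )

    def remove(self, pos: tuple[int, int], *, to_debris: bool = False) -> Cell:
        cell = self.cells.pop(pos)
        if to_debris:
            self.debris.add(pos)
        return cell

    def occupancy_mask(self, states: Iterable[CellState] = LIVE_STATES) -> np.ndarray:
        """Boolean grid marking sites holding a cell in one of ``states``."""
        wanted = set(states)
        mask = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for (r, c), cell in self.cells.items():
            if cell.state in wanted:
                mask[r, c] = True
        return mask

    def snapshot(self) -> np.ndarray:
        """Integer-coded grid: 0 empty, otherwise the ``CellState`` code."""
        grid = np.zeros((self.n_rows, self.n_cols), dtype=np.int8)
        for (r, c), cell in self.cells.items():
            grid[r, c] = int(cell.state)
        for r, c in self.debris:
            grid[r, c] = int(CellState.DEBRIS)
        return grid


@dataclass(frozen=True)
class Census:
    """Per-state population counts at one instant."""

    proliferative: int
    quiescent: int
    g0_arrested: int
    dying: int
    debris: int
    empty: int

    @property
    def viable(self) -> int:
        """Viable = cycling + space-quiescent + drug-arrested cells."""
        return self.proliferative + self.quiescent + self.g0_arrested

    @property
    def occupied(self) -> int:
        return self.proliferative + self.quiescent + self.g0_arrested + self.dying

    @property
    def total_sites(self) -> int:
        return self.occupied + self.debris + self.empty

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["viable"] = self.viable
        return d


def census(lattice: Lattice) -> Census:
    """Count cells per state; counts partition the lattice sites exactly."""
    n = {s: 0 for s in CellState}
    for cell in lattice.cells.values():
        n[cell.state] += 1
    n_debris = len(lattice.debris)
    occupied = sum(n.values()) + n_debris
    return Census(
        proliferative=n[CellState.PROLIFERATIVE],
        quiescent=n[CellState.QUIESCENT],
        g0_arrested=n[CellState.G0_ARRESTED],
        dying=n[CellState.DYING],
        debris=n_debris,
        empty=lattice.capacity - occupied,
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_INITIAL_CONFIGURATIONS = ("monolayer", "spheroid_slice")


@dataclass
class SimulationConfig:
    """All tunable simulation parameters (flat key-value surface).

    Durations are hours unless the field name says otherwise.  Defaults
    describe the patient-derived glioblastoma line the model was built
    around: mean cell-cycle time 22 h (SD 1 h), intrinsic spontaneous death
    of ~5% per cycle, and a 300x300 lattice (4.5 mm span at 15 um spacing)
    large enough that a three-week spheroid run never reaches the boundary.
    """

    n_rows: int = 300
    n_cols: int = 300
    spacing_um: float = 15.0
    mean_doubling_time_h: float = 22.0
    doubling_time_sd_h: float = 1.0
    spontaneous_death_prob: float = 0.05
    g0_death_prob: float = 0.0
    lysis_period_h: float = 48.0
    n_replicates: int = 10
    rng_seed: int = 0
    max_search_ring: int = 3
    agent_dt_h: float = 1.0
    pde_dt_s: float = 60.0
    total_days: float = 21.0
    record_interval_days: float = 1.0
    initial_configuration: str = "spheroid_slice"
    initial_radius_sites: int = 14
    n_initial_cells: int = 10000
    treatment_start_day: float = 4.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in (
            "mean_doubling_time_h",
            "lysis_period_h",
            "agent_dt_h",
            "pde_dt_s",
            "total_days",
            "record_interval_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.doubling_time_sd_h < 0:
            raise ValueError("doubling_time_sd_h must be non-negative")
        for name in ("spontaneous_death_prob", "g0_death_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.max_search_ring not in (1, 2, 3):
            raise ValueError("max_search_ring must be 1, 2 or 3")
        if self.initial_configuration not in _INITIAL_CONFIGURATIONS:
            raise ValueError(
                f"initial_configuration must be one of {_INITIAL_CONFIGURATIONS}"
            )
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")

    @property
    def total_hours(self) -> float:
        return self.total_days * 24.0

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("configuration file must be a flat key-value mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# initial configurations
# ---------------------------------------------------------------------------


def draw_doubling_time(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Doubling time ~ Normal(mean, sd) truncated at +/- 4 SD (keeps it positive)."""
    mu, sd = config.mean_doubling_time_h, config.doubling_time_sd_h
    if sd == 0:
        return mu
    lo, hi = mu - 4.0 * sd, mu + 4.0 * sd
    while True:
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return x


def _new_cell(config: SimulationConfig, rng: np.random.Generator, lattice: Lattice) -> Cell:
    dt = draw_doubling_time(config, rng)
    cid = lattice.new_cell_id()
    return Cell(
        state=CellState.PROLIFERATIVE,
        age=rng.uniform(0.0, dt),
        doubling_time=dt,
        cell_id=cid,
        lineage=cid,
    )


def init_monolayer(
    config: SimulationConfig, n_cells: int, rng: np.random.Generator
) -> Lattice:
    """Sparse monolayer: cells scattered uniformly at random without collision.

    Mirrors the 2D well assay where the drug bath is spatially homogeneous.
    Ages are drawn Uniform[0, doubling_time) per cell so that divisions are
    desynchronized from the start.
    """
    lattice = Lattice(config.n_rows, config.n_cols, config.spacing_um)
    # scattered monolayers legitimately touch the edge; the boundary warning
    # is aimed at diffusion-limited spheroid geometries outgrowing the domain
    lattice._boundary_warned = True
    if n_cells > lattice.capacity:
        raise ValueError(
            f"cannot place {n_cells} cells on a lattice with capacity "
            f"{lattice.capacity}"
        )
    if n_cells == 0:
        return lattice
    flat = rng.choice(lattice.capacity, size=n_cells, replace=False)
    for idx in flat:
        pos = (int(idx) // config.n_cols, int(idx) % config.n_cols)
        lattice.place(pos, _new_cell(config, rng, lattice))
    return lattice


def init_spheroid_slice(
    config: SimulationConfig, initial_radius_sites: int, rng: np.random.Generator
) -> Lattice:
    """Dense disc representing the planar central slice of a spheroid.

    Every site within Euclidean distance ``initial_radius_sites`` of the
    lattice center starts occupied by a cycling cell with randomized age and
    doubling time.  The disc must fit with a margin of at least two rings.
    """
    if initial_radius_sites < 0:
        raise ValueError("initial_radius_sites must be non-negative")
    lattice = Lattice(config.n_rows, config.n_cols, config.spacing_um)
    r0, c0 = lattice.center
    margin = 2
    if (
        r0 - initial_radius_sites < margin
        or c0 - initial_radius_sites < margin
        or r0 + initial_radius_sites >= config.n_rows - margin
        or c0 + initial_radius_sites >= config.n_cols - margin
    ):
        raise ValueError(
            f"disc of radius {initial_radius_sites} does not fit a "
            f"{config.n_rows}x{config.n_cols} lattice with a {margin}-ring margin"
        )
    rad2 = initial_radius_sites * initial_radius_sites
    for dr in range(-initial_radius_sites, initial_radius_sites + 1):
        for dc in range(-initial_radius_sites, initial_radius_sites + 1):
            if dr * dr + dc * dc <= rad2:
                lattice.place((r0 + dr, c0 + dc), _new_cell(config, rng, lattice))
    return lattice


def find_empty_site(
    lattice: Lattice,
    position: tuple[int, int],
    max_ring: int,
    rng: np.random.Generator,
) -> Optional[tuple[int, int]]:
    """Nearest-ring-first search for a reoccupiable site around ``position``.

    Ring r+1 is inspected only when ring r holds no vacancy (Moore
    neighborhoods, i.e. Chebyshev rings).  The return value is a uniformly
    random vacancy of the first non-full ring, or None if rings 1..max_ring
    are all full.
    """
    if position not in lattice.cells:
        raise ValueError(f"no cell at {position}")
    r0, c0 = position
    nr, nc = lattice.n_rows, lattice.n_cols
    cells = lattice.cells
    for radius in range(1, max_ring + 1):
        vacancies = [
            (r, c)
            for dr, dc in _ring_offsets(radius)
            if 0 <= (r := r0 + dr) < nr
            and 0 <= (c := c0 + dc) < nc
            and (r, c) not in cells
        ]
        if vacancies:
            return vacancies[int(rng.integers(len(vacancies)))]
    return None


def viable_area_um2(lattice: Lattice) -> float:
    """Viable-area proxy: viable-site count x spacing^2 (debris excluded)."""
    c = census(lattice)
    return c.viable * lattice.spacing_um**2
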