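"""Agent-based simulation of stochastic, positionally triggered commitment.

Cells are points in 3D around a static tip attractor at the origin. Each
step applies, in fixed order: (1) migration of cap cells (random walk plus
tip attraction/repulsion, summed and applied once; committed cells do not
move), (2) induction bookkeeping (in-zone increment, threshold commitment,
out-of-zone reversion), (3) division of cap cells (Bernoulli per cell).

The population is held as a struct-of-arrays (:class:`Population`) so that
runs with up to ~1e5 agents stay vectorised; the per-cell operations the
model is defined by (:func:`sample_random_displacement`,
:func:`tip_interaction`, :func:`update_state`) are also exposed in scalar
form and the vectorised step is tested against them.

All randomness flows through one seeded ``numpy.random.Generator`` per
simulation, consumed in a fixed documented order (per step: movement
directions, movement magnitudes, division coin flips, daughter jitter
directions, daughter jitter magnitudes), so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolationError, DegenerateGeometryError, ParameterError
from .params import SimParams

CAP = "cap"
COMMITTED = "committed"


@dataclass
class AgentCell:
    """One simulated progenitor cell."""

    cell_id: int
    parent_id: int | None
    position: np.ndarray  # 3-vector, niche units
    cell_type: str = CAP
    state_count: int = 0
    labelled: bool = False
    birth_step: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ParameterError("position must be a 3-vector")
        if self.state_count < 0:
            raise ParameterError("state_count must be >= 0")
        if self.cell_type not in (CAP, COMMITTED):
            raise ParameterError(f"unknown cell_type {self.cell_type!r}")


class Population:
    """Struct-of-arrays container for the whole population.

    Cell ids are dense indices ``0..n-1`` in birth order; cells are never
    removed, so ids are stable for the lifetime of a simulation.
    """

    def __init__(
        self,
        pos: np.ndarray,
        state: np.ndarray,
        committed: np.ndarray,
        parent: np.ndarray,
        birth_step: np.ndarray,
        labelled: np.ndarray,
    ) -> None:
        self.pos = np.asarray(pos, dtype=float).reshape(-1, 3)
        self.state = np.asarray(state, dtype=np.int64)
        self.committed = np.asarray(committed, dtype=bool)
        self.parent = np.asarray(parent, dtype=np.int64)  # -1 for founders
        self.birth_step = np.asarray(birth_step, dtype=np.int64)
        self.labelled = np.asarray(labelled, dtype=bool)

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    def copy(self) -> "Population":
        return Population(
            self.pos.copy(), self.state.copy(), self.committed.copy(),
            self.parent.copy(), self.birth_step.copy(), self.labelled.copy(),
        )

    @classmethod
    def from_cells(cls, cells: Sequence[AgentCell]) -> "Population":
        return cls(
            pos=np.array([c.position for c in cells], dtype=float).reshape(-1, 3),
            state=np.array([c.state_count for c in cells], dtype=np.int64),
            committed=np.array([c.cell_type == COMMITTED for c in cells], dtype=bool),
            parent=np.array(
                [-1 if c.parent_id is None else c.parent_id for c in cells],
                dtype=np.int64,
            ),
            birth_step=np.array([c.birth_step for c in cells], dtype=np.int64),
            labelled=np.array([c.labelled for c in cells], dtype=bool),
        )

    def to_cells(self) -> list[AgentCell]:
        return [
            AgentCell(
                cell_id=i,
                parent_id=None if self.parent[i] < 0 else int(self.parent[i]),
                position=self.pos[i].copy(),
                cell_type=COMMITTED if self.committed[i] else CAP,
                state_count=int(self.state[i]),
                labelled=bool(self.labelled[i]),
                birth_step=int(self.birth_step[i]),
            )
            for i in range(self.n)
        ]


@dataclass
class Snapshot:
    """Per-step state of the population (positions, states, types)."""

    n_cells: int
    pos: np.ndarray
    state: np.ndarray
    committed: np.ndarray


@dataclass
class Trajectory:
    """Record of one simulation: per-step snapshots plus event logs.

    ``snapshots[t]`` is the population state after step ``t``
    (``snapshots[0]`` is the initial state). ``division_events`` holds
    ``(step, parent_id, child_id)``; ``commitment_events`` holds
    ``(step, cell_id)``. Static per-cell attributes (parent, birth step,
    lineage label) live on the final population.
    """

    params: SimParams
    snapshots: list[Snapshot]
    division_events: list[tuple[int, int, int]]
    commitment_events: list[tuple[int, int]]
    population: Population  # final state, carries the static registry

    @property
    def n_steps(self) -> int:
        return len(self.snapshots) - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (step, cell)."""
        rows = []
        for t, snap in enumerate(self.snapshots):
            n = snap.n_cells
            rows.append(
                pd.DataFrame(
                    {
                        "step": t,
                        "cell_id": np.arange(n),
                        "parent_id": self.population.parent[:n],
                        "x": snap.pos[:, 0],
                        "y": snap.pos[:, 1],
                        "z": snap.pos[:, 2],
                        "cell_type": np.where(snap.committed, COMMITTED, CAP),
                        "state_count": snap.state,
                        "labelled": self.population.labelled[:n],
                        "birth_step": self.population.birth_step[:n],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def events_frame(self) -> pd.DataFrame:
        rows = [
            {"step": s, "event_type": "division", "cell_id": p, "child_id": c}
            for (s, p, c) in self.division_events
        ] + [
            {"step": s, "event_type": "commitment", "cell_id": i, "child_id": pd.NA}
            for (s, i) in self.commitment_events
        ]
        frame = pd.DataFrame(
            rows, columns=["step", "event_type", "cell_id", "child_id"]
        )
        frame["child_id"] = frame["child_id"].astype("Int64")
        return frame.sort_values(["step", "event_type", "cell_id"]).reset_index(
            drop=True
        )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def _random_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit vectors with components drawn Uniform(-1, 1), zero draws resampled."""
    comps = rng.uniform(-1.0, 1.0, size=(n, 3))
    norms = np.linalg.norm(comps, axis=1)
    while np.any(norms == 0.0):  # probability-zero; keeps the contract total
        bad = norms == 0.0
        comps[bad] = rng.uniform(-1.0, 1.0, size=(int(bad.sum()), 3))
        norms = np.linalg.norm(comps, axis=1)
    return comps / norms[:, None]


def sample_random_displacement(
    rng: np.random.Generator, sigma: float, size: int | None = None
) -> np.ndarray:
    """Random migration displacement(s): signed Normal(0, sigma) magnitude
    along a direction whose components are each Uniform(-1, 1), normalised.

    With ``size=None`` returns a single 3-vector; otherwise a ``(size, 3)``
    array. Draw order: all direction components first, then all magnitudes.
    """
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    n = 1 if size is None else int(size)
    units = _random_directions(rng, n)
    mags = rng.normal(0.0, sigma, size=n) if sigma > 0 else np.zeros(n)
    out = units * mags[:, None]
    return out[0] if size is None else out


def tip_interaction(position: np.ndarray, params: SimParams) -> np.ndarray:
    """Tip attraction/repulsion displacement for one position or an (n, 3) array.

    At distance ``d`` from the tip centre (origin), with scaled tip size
    ``R = tip_size * niche_scale`` and attraction constant ``a``:

    * ``d >= R``: inward vector of magnitude ``a * R**2 / d**2``
    * ``d <  R``: outward vector of magnitude ``a``
    """
    pos = np.asarray(position, dtype=float)
    single = pos.ndim == 1
    pos2 = pos.reshape(-1, 3)
    d = np.linalg.norm(pos2, axis=1)
    if np.any(d == 0.0):
        raise DegenerateGeometryError(
            "cell exactly at the tip centre has no defined interaction direction"
        )
    r = params.scaled_tip_size
    unit_out = pos2 / d[:, None]
    mag = np.where(d >= r, params.tip_attraction * r**2 / d**2, params.tip_attraction)
    sign = np.where(d >= r, -1.0, 1.0)  # inward for attraction, outward inside
    disp = unit_out * (sign * mag)[:, None]
    return disp[0] if single else disp


def update_state(cell: AgentCell, params: SimParams) -> AgentCell:
    """Apply one step of induction bookkeeping to a cap cell (in place).

    Inside the zone (``y < induction_cutoff * niche_scale``) the state count
    increments; if it reaches the threshold the cell commits. Outside the
    zone the count decays by ``reentry_value``, floored at zero.
    """
    if cell.cell_type == COMMITTED:
        raise ContractViolationError("update_state must not receive committed cells")
    if cell.position[1] < params.scaled_induction_cutoff:
        cell.state_count += 1
        if cell.state_count >= params.state_threshold:
            cell.cell_type = COMMITTED
    else:
        cell.state_count = max(0, cell.state_count - params.reentry_value)
    return cell


def divide_population(
    population: Population,
    params: SimParams,
    rng: np.random.Generator,
    step_index: int = 0,
) -> tuple[Population, list[tuple[int, int, int]]]:
    """Bernoulli(mitotic_index) division of cap cells.

    Daughters get a fresh id, the parent's state count and label, and the
    parent's position offset by an independent random-migration displacement.
    Committed cells never divide. Draw order: one uniform per cap cell, then
    daughter jitter (directions, then magnitudes).
    """
    cap_idx = np.nonzero(~population.committed)[0]
    if cap_idx.size == 0 or params.mitotic_index == 0.0:
        if cap_idx.size:
            rng.uniform(size=cap_idx.size)  # keep the stream schedule fixed
        return population, []
    coins = rng.uniform(size=cap_idx.size)
    parents = cap_idx[coins < params.mitotic_index]
    if parents.size == 0:
        return population, []
    jitter = sample_random_displacement(rng, params.random_migration, size=parents.size)
    first_child = population.n
    child_ids = np.arange(first_child, first_child + parents.size)
    population.pos = np.vstack([population.pos, population.pos[parents] + jitter])
    population.state = np.concatenate([population.state, population.state[parents]])
    population.committed = np.concatenate(
        [population.committed, np.zeros(parents.size, dtype=bool)]
    )
    population.parent = np.concatenate([population.parent, parents])
    population.birth_step = np.concatenate(
        [population.birth_step, np.full(parents.size, step_index, dtype=np.int64)]
    )
    population.labelled = np.concatenate(
        [population.labelled, population.labelled[parents]]
    )
    events = [
        (step_index, int(p), int(c)) for p, c in zip(parents, child_ids)
    ]
    return population, events


def step(
    population: Population,
    params: SimParams,
    rng: np.random.Generator,
    step_index: int = 0,
) -> tuple[Population, dict[str, list]]:
    """Advance the population by one step (move -> induct/commit -> divide)."""
    cap = ~population.committed
    n_cap = int(cap.sum())

    # (1) movement: random walk + tip interaction, applied once, cap only
    if n_cap:
        rand = sample_random_displacement(rng, params.random_migration, size=n_cap)
        tip = tip_interaction(population.pos[cap], params)
        population.pos[cap] += rand + tip.reshape(-1, 3)

    # (2) induction / commitment / reversion (vectorised update_state)
    in_zone = cap & (population.pos[:, 1] < params.scaled_induction_cutoff)
    population.state[in_zone] += 1
    newly = in_zone & (population.state >= params.state_threshold)
    population.committed |= newly
    outside = cap & ~in_zone
    if params.reentry_value > 0 and np.any(outside):
        population.state[outside] = np.maximum(
            0, population.state[outside] - params.reentry_value
        )
    commitments = [(step_index, int(i)) for i in np.nonzero(newly)[0]]

    # (3) division among cells still cap after commitment
    population, divisions = divide_population(population, params, rng, step_index)
    return population, {"divisions": divisions, "commitments": commitments}


def init_population(
    params: SimParams,
    rng: np.random.Generator,
    initial_positions: np.ndarray | None = None,
) -> Population:
    """Initial population: all cap, state 0, unlabelled.

    By default cells are placed isotropically at radii uniform in
    ``[R, 1.5 R]`` (``R`` the scaled tip size) around the origin; explicit
    ``initial_positions`` override the placement (e.g. to pin probe cells).
    """
    if initial_positions is not None:
        pos = np.asarray(initial_positions, dtype=float).reshape(-1, 3).copy()
        n = pos.shape[0]
        if n < 1:
            raise ParameterError("initial_positions must contain at least one cell")
    else:
        n = params.n_init
        units = _random_directions(rng, n)
        radii = rng.uniform(params.scaled_tip_size, 1.5 * params.scaled_tip_size, size=n)
        pos = units * radii[:, None]
    return Population(
        pos=pos,
        state=np.zeros(n, dtype=np.int64),
        committed=np.zeros(n, dtype=bool),
        parent=np.full(n, -1, dtype=np.int64),
        birth_step=np.zeros(n, dtype=np.int64),
        labelled=np.zeros(n, dtype=bool),
    )


def simulate(
    params: SimParams, initial_positions: np.ndarray | None = None
) -> Trajectory:
    """Run a full simulation; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    population = init_population(params, rng, initial_positions=initial_positions)
    snapshots = [
        Snapshot(
            population.n, population.pos.copy(), population.state.copy(),
            population.committed.copy(),
        )
    ]
    divisions: list[tuple[int, int, int]] = []
    commitments: list[tuple[int, int]] = []
    for t in range(1, params.n_steps + 1):
        population, events = step(population, params, rng, step_index=t)
        divisions.extend(events["divisions"])
        commitments.extend(events["commitments"])
        snapshots.append(
            Snapshot(
                population.n, population.pos.copy(), population.state.copy(),
                population.committed.copy(),
            )
        )
    return Trajectory(
        params=params,
        snapshots=snapshots,
        division_events=divisions,
        commitment_events=commitments,
        population=population,
    )
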