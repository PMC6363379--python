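"""In-silico experiments over the niche simulation.

Mirrors the wet lineage-tracing design: mark the cells receiving inductive
signal at a chosen step (the in-silico analogue of a tamoxifen pulse on
cells switching on the commitment marker), then ask, at a later step, how
the marked lineage distributed between committed cells, induced cap cells
and cap cells that returned to the uninduced ground state. Also provides
the population-level uninduced-fraction time series and seeded parameter
sweeps over niche scale and random-migration rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .params import SimParams, VARIANTS
from .simulation import Trajectory, simulate


@dataclass
class CohortFate:
    """Fate of a labelled induction cohort (descendants included)."""

    label_step: int
    observe_step: int
    n_labelled: int
    n_committed: int
    n_cap_induced: int
    n_cap_uninduced: int

    @property
    def lineage_size(self) -> int:
        return self.n_committed + self.n_cap_induced + self.n_cap_uninduced


@dataclass
class SweepResult:
    """Mean/sd of the final uninduced fraction at one sweep grid point."""

    niche_scale: float
    random_migration: float
    variant: str
    n_reps: int
    mean_uninduced_fraction: float
    sd_uninduced_fraction: float


def label_induction_cohort(trajectory: Trajectory, label_step: int) -> set[int]:
    """Ids of cap cells whose state count incremented at ``label_step``.

    These are exactly the cells inside the induction zone during that step
    (cells committing at that step are included: the increment precedes the
    threshold check). ``label_step == 0`` is the initial snapshot, before
    any induction, and yields an empty cohort.
    """
    if not 0 <= label_step < len(trajectory.snapshots):
        raise ParameterError(
            f"label_step {label_step} outside 0..{len(trajectory.snapshots) - 1}"
        )
    if label_step == 0:
        return set()
    prev = trajectory.snapshots[label_step - 1]
    cur = trajectory.snapshots[label_step]
    n_prev = prev.n_cells
    incremented = cur.state[:n_prev] > prev.state[:n_prev]
    return {int(i) for i in np.nonzero(incremented)[0]}


def _lineage_members(
    trajectory: Trajectory, cohort: set[int], label_step: int, observe_step: int
) -> np.ndarray:
    """Cohort plus descendants born after ``label_step`` up to ``observe_step``."""
    parent = trajectory.population.parent
    birth = trajectory.population.birth_step
    n_obs = trajectory.snapshots[observe_step].n_cells
    member = np.zeros(n_obs, dtype=bool)
    for i in cohort:
        member[i] = True
    # ids are in birth order, so one forward pass propagates the label
    for i in range(n_obs):
        p = parent[i]
        if p >= 0 and member[p] and label_step < birth[i] <= observe_step:
            member[i] = True
    return np.nonzero(member)[0]


def cohort_fate_summary(
    trajectory: Trajectory, cohort: set[int], observe_step: int, label_step: int
) -> CohortFate:
    """Classify cohort members and their descendants at ``observe_step``.

    Descendants born after ``label_step`` inherit the label (the in-silico
    analogue of heritable Cre-reporter labelling).
    """
    if observe_step < label_step:
        raise ParameterError("observe_step must be >= label_step")
    if not 0 <= observe_step < len(trajectory.snapshots):
        raise ParameterError("observe_step outside trajectory range")
    if not cohort:
        return CohortFate(label_step, observe_step, 0, 0, 0, 0)
    members = _lineage_members(trajectory, cohort, label_step, observe_step)
    snap = trajectory.snapshots[observe_step]
    committed = snap.committed[members]
    state = snap.state[members]
    n_committed = int(committed.sum())
    n_cap_induced = int((~committed & (state > 0)).sum())
    n_cap_uninduced = int((~committed & (state == 0)).sum())
    return CohortFate(
        label_step=label_step,
        observe_step=observe_step,
        n_labelled=len(cohort),
        n_committed=n_committed,
        n_cap_induced=n_cap_induced,
        n_cap_uninduced=n_cap_uninduced,
    )


def class_fractions(trajectory: Trajectory, step: int) -> tuple[float, float, float]:
    """(uninduced, induced, committed) fractions of all cells at ``step``."""
    snap = trajectory.snapshots[step]
    n = snap.n_cells
    if n == 0:
        raise ParameterError("empty population")
    committed = snap.committed
    uninduced = (~committed) & (snap.state == 0)
    induced = (~committed) & (snap.state > 0)
    return (
        float(uninduced.sum()) / n,
        float(induced.sum()) / n,
        float(committed.sum()) / n,
    )


def uninduced_fraction(
    trajectory: Trajectory, step: int, denominator: str = "all"
) -> float:
    """Fraction of cells that are cap with zero accumulated state.

    ``denominator="all"`` counts committed cells in the denominator (the
    default population-level convention); ``"cap"`` restricts to cap cells.
    """
    if not 0 <= step < len(trajectory.snapshots):
        raise ParameterError("step outside trajectory range")
    snap = trajectory.snapshots[step]
    if snap.n_cells == 0:
        raise ParameterError("empty population")
    committed = snap.committed
    uninduced = int(((~committed) & (snap.state == 0)).sum())
    if denominator == "all":
        return uninduced / snap.n_cells
    if denominator == "cap":
        n_cap = int((~committed).sum())
        if n_cap == 0:
            raise ParameterError("no cap cells at this step")
        return uninduced / n_cap
    raise ParameterError("denominator must be 'all' or 'cap'")


def fraction_time_series(trajectory: Trajectory) -> pd.DataFrame:
    """Per-step uninduced/induced/committed fractions as a table."""
    rows = []
    for t in range(len(trajectory.snapshots)):
        u, i, c = class_fractions(trajectory, t)
        rows.append(
            {
                "step": t,
                "variant": trajectory.params.variant,
                "seed": trajectory.params.seed,
                "fraction_uninduced": u,
                "fraction_induced": i,
                "fraction_committed": c,
            }
        )
    return pd.DataFrame(rows)


def rep_seed(master_seed: int, *indices: int) -> int:
    """Per-replicate seed derived from the master seed and counter indices."""
    ss = np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_sweep(
    base: SimParams,
    scales: list[float],
    migrations: list[float],
    n_reps: int = 10,
    seed: int = 0,
    variants: tuple[str, ...] = VARIANTS,
) -> list[SweepResult]:
    """Grid sweep over niche scale and random-migration rate.

    Each grid point runs ``n_reps`` independent simulations with seeds
    derived deterministically from ``seed`` and the grid/replicate indices;
    reports mean and sample sd of the final-step uninduced fraction.
    """
    if n_reps < 2:
        raise ParameterError("n_reps must be >= 2")
    if not scales or not migrations or not variants:
        raise ParameterError("scales, migrations and variants must be nonempty")
    results = []
    for vi, variant in enumerate(variants):
        for si, scale in enumerate(scales):
            for mi, migration in enumerate(migrations):
                fracs = []
                for rep in range(n_reps):
                    params = base.replace(
                        variant=variant,
                        reentry_value=None,  # re-resolve from variant
                        niche_scale=scale,
                        random_migration=migration,
                        seed=rep_seed(seed, vi, si, mi, rep),
                    )
                    traj = simulate(params)
                    fracs.append(uninduced_fraction(traj, traj.n_steps))
                results.append(
                    SweepResult(
                        niche_scale=scale,
                        random_migration=migration,
                        variant=variant,
                        n_reps=n_reps,
                        mean_uninduced_fraction=float(np.mean(fracs)),
                        sd_uninduced_fraction=float(np.std(fracs, ddof=1)),
                    )
                )
    return results


def sweep_frame(results: list[SweepResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "niche_scale": [r.niche_scale for r in results],
            "random_migration": [r.random_migration for r in results],
            "variant": [r.variant for r in results],
            "n_reps": [r.n_reps for r in results],
            "mean_uninduced_fraction": [r.mean_uninduced_fraction for r in results],
            "sd_uninduced_fraction": [r.sd_uninduced_fraction for r in results],
        }
    )
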