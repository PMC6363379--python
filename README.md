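# nichesim

Agent-based modelling of nephron-progenitor commitment in a motile niche,
with the accompanying 3D spot-classification and cell-track analysis
utilities.

## The problem

Nephron progenitors (cap mesenchyme) swarm around each ureteric tip while
commitment to nephron formation happens only in a spatially restricted
region at the tip–stalk junction. Lineage tracing shows that some cells
that switch on the early commitment marker *Wnt4* nevertheless migrate
back into the progenitor domain ("escapers"). `nichesim` implements a
minimal model that reconciles these observations: cells migrate randomly
under tip attraction/repulsion, accumulate inductive signal only while
inside an induction zone (`y < induction_cutoff`), and commit irreversibly
once the accumulated signal reaches a threshold. Whether an induced cell
escapes is then purely a consequence of its migration history. Two
variants bracket the fate of escaped cells: **primed** (accumulated state
is retained outside the zone, re-entry value 0) and **return-to-ground**
(state decays by a fixed decrement per step outside, re-entry value ≥ 1).

The package also implements the bespoke computations used on the wet data:
3D nearest-neighbour classification of lineage-labelled spots
(cap ⇔ nearest SIX2 spot within 8 µm and Wnt4-GFP < 10000), per-sample
intensity-cutoff inference for dense constitutive labelling (nuclear and
SIX2 minima, YFP mean − 1 sd over manually matched reference cells), and
tip-relative drift correction of cell tracks with a dataset-stratified
permutation test on migration speeds. Synthetic generators with exact
ground truth drive all of it; see `docs/methods.md` for the full model
description.

## Worked example

```python
from nichesim import (SimParams, simulate, uninduced_fraction,
                      label_induction_cohort, cohort_fate_summary)

params = SimParams(variant="return_to_ground", seed=0)  # defaults: 200 cells, 400 steps
traj = simulate(params)
print(f"final population {traj.population.n}, "
      f"{len(traj.commitment_events)} commitments")
print(f"uninduced fraction at step 400: {uninduced_fraction(traj, 400):.3f}")

cohort = label_induction_cohort(traj, 100)   # cells being induced at step 100
fate = cohort_fate_summary(traj, cohort, 200, label_step=100)
print(f"labelled {fate.n_labelled}; by step 200: {fate.n_committed} committed, "
      f"{fate.n_cap_induced} induced cap, {fate.n_cap_uninduced} uninduced cap")
```

prints

```
final population 6263, 865 commitments
uninduced fraction at step 400: 0.797
labelled 28; by step 200: 30 committed, 3 induced cap, 16 uninduced cap
```

So of the 28-cell cohort receiving inductive signal at step 100 (49 cells
counting daughters born since labelling), 30 committed while 19 re-entered
the cap — and in the return-to-ground variant 16 of those have already
relaxed back to the uninduced progenitor state, transcriptionally
indistinguishable from cells that were never induced. Roughly 80 % of the
population remains
uninduced at step 400: the reversion variant holds a steady progenitor
pool instead of exhausting it.

The numbered scripts under `analysis/` run the full in-silico experiments
(variant comparison, lineage labelling, niche-scale × migration sweeps,
classification and track pipelines on synthetic ground truth) and write
tables and figures to `results/`. The same functionality is available from
the CLI:

```sh
nichesim simulate --out out/run1            # trajectory, events, fractions + manifest
nichesim sweep --reps 10 --out out/sweep
nichesim synth spots --seed 2 --out out/synth
nichesim classify-spots --td out/synth/tdtomato.csv --six2 out/synth/six2.csv --out out/cls
nichesim tracks --in tracks.csv --permutations 10000 --seed 1 --out out/tracks
```

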