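# Methods

## The model

`nichesim` simulates nephron-progenitor (cap mesenchyme) cells as points in
3D around a static spherical attractor at the origin representing a
ureteric tip. Each cell is either `cap` (motile progenitor) or `committed`
(immotile, nephron-forming). Time advances in discrete steps; each step
applies three phases in a fixed order:

1. **Migration** (cap cells only). The displacement is the sum of a random
   component and a tip-interaction component, applied once:
   - *Random migration*: a signed magnitude `m ~ Normal(0, random_migration)`
     along a direction `u` obtained by normalising a vector whose three
     components are drawn independently from Uniform(−1, 1) (zero-norm draws
     are resampled). This direction rule has a mild corner bias relative to
     an isotropic sphere draw; it is retained deliberately as the model's
     definition.
   - *Tip interaction*: with `R = tip_size × niche_scale` and distance to
     origin `d`, cells at `d ≥ R` move toward the origin with magnitude
     `tip_attraction · R²/d²`; cells at `d < R` move away with constant
     magnitude `tip_attraction`. A cell exactly at the origin has no defined
     direction and raises a degenerate-geometry error (a probability-zero
     configuration under continuous dynamics).
2. **Induction.** Cells with `y < induction_cutoff × niche_scale` (the
   induction zone, a half-space below the tip) increment an integer state
   counter by 1; a cell reaching `state_threshold` immediately becomes
   `committed` and never moves or divides again — the threshold check
   follows the increment, so committed positions always lie inside the
   zone. Cells outside the zone decrement their counter by `reentry_value`
   per step, floored at 0.
3. **Division.** Each cap cell independently divides with probability
   `mitotic_index`. Daughters inherit the parent's state counter and
   lineage label (clonal memory, mirroring heritable Cre-reporter
   labelling) and start at the parent's position plus one independent
   random-migration displacement.

Two variants differ only in `reentry_value`: **primed** (0 — induction
history is retained indefinitely) and **return-to-ground** (≥ 1 — escaping
cells relax back to the uninduced progenitor state). The constructor
enforces this pairing; `allow_variant_mismatch` relaxes it for exploration.

### Default parameters

| parameter | default | units / meaning |
|---|---|---|
| `tip_size` | 5 | niche units; tip radius and attraction/repulsion boundary |
| `induction_cutoff` | −2 | niche units; zone is `y` below this (× scale) |
| `tip_attraction` | 0.5 | displacement magnitude scale per step |
| `random_migration` | 0.5 | sd of the per-step random magnitude |
| `state_threshold` | 30 | in-zone steps needed to commit |
| `mitotic_index` | 0.01 | division probability per cap cell per step |
| `reentry_value` | 0 / 1 | per-step decay outside the zone (primed / return) |
| `n_steps` | 400 | steps per run |
| `niche_scale` | 1.0 | multiplies `tip_size` and `induction_cutoff` only |
| `n_init` | 200 | initial population (model leaves this open; 200 gives a realistically dense cap and sub-second runs) |

Initial cells are all cap with state 0, placed isotropically at radii
uniform in `[R, 1.5R]` — a shell hugging the tip, like the cap in vivo.
Explicit initial positions can be supplied to pin probe cells.

### Randomness and reproducibility

One `numpy.random.Generator` per simulation, seeded from `SimParams.seed`,
consumed in a fixed order per step (movement directions, movement
magnitudes, division coin flips, daughter jitter). Identical parameters
including the seed give bit-identical trajectories. Sweeps derive
per-replicate seeds with `numpy.random.SeedSequence([master, variant_index,
scale_index, migration_index, rep])`, so grid points are independent and
reproducible in any execution order.

The engine is vectorised (struct-of-arrays over the population); the
scalar per-cell operations that define the model are exposed alongside and
the vectorised step is tested against them.

## Readouts

- **Uninduced fraction**: cap cells with state 0 over all cells
  (`denominator="all"`, the default) or over cap cells only
  (`denominator="cap"`). The population convention is not uniquely
  determined by the model description, so both are provided. The long-run
  decline of the primed variant is monotone under the cap convention; under
  the all-cells convention the curve dips early (the initial in-zone cohort
  commits quickly), rebounds through division, and then declines — trend
  tests therefore use the cap convention.
- **Lineage labelling**: `label_induction_cohort` marks every cap cell
  whose counter incremented at the chosen step (cells committing at that
  step included, since the increment precedes the threshold check);
  descendants born after the label step inherit the mark.
  `cohort_fate_summary` partitions the lineage at a later step into
  committed / induced cap / uninduced cap.
- **Sweeps**: mean ± sample sd of the final-step uninduced fraction over
  `n_reps` replicates per (niche scale, migration, variant) grid point.

## Spot classification

Operates on spot tables (CSV: `spot_id, x_um, y_um, z_um` + one column per
channel). Sparse-labelling pipeline: SIX2 spots are z-scored within the
dataset and spots below the mean dropped ("scaled value < 0"); each
tdTomato spot is classed as a SIX2+ cap cell iff its 3D nearest filtered
SIX2 neighbour lies within 8 µm (inclusive; nearest-neighbour ties break
to the smallest spot id) and its Wnt4-GFP intensity is strictly below
10000. The labelled fraction is cap-classed tdTomato spots over filtered
SIX2 spots.

Constitutive pipeline: manual reference positions are matched one-to-one
to automated spots (greedy by ascending distance, ≤ 3 µm, unmatched
references are an error listing the offenders). Cutoffs over the matched
set: nuclear and SIX2 minima, and YFP mean − 1 sample sd (ddof = 1). Spots
with natural-log SIX2 above 10 are dropped as spurious bright detections
(log base configurable), spots strictly below the nuclear or SIX2 cutoffs
are dropped (a spot exactly at a cutoff is retained), and the rest are
labelled iff YFP ≥ the YFP cutoff. `normalize_q99` (divide by the 99th
percentile, linear-interpolation quantile) is the display normalisation.

Boundary conventions (≤ 8 µm inclusive, < 10000 strict, strict below-cutoff
removal) follow the literal wording of the rules and are asserted in tests.

## Track analysis

Tracks are integer-indexed 3D positions (µm) with one tip-landmark
reference track per imaging field (default frame interval 15 min).
`drift_correct` subtracts the reference's displacement over each interval,
anchoring the corrected track at the raw start; the reference is linearly
interpolated at missing frames and must cover the track's range.
`mean_track_speed` is total path length over total elapsed time — the
per-interval speeds weighted by their true durations, so intervals spanning
imaging pauses count by their actual elapsed minutes; for uniform sampling
this equals the plain mean of per-interval speeds.

Group comparison uses a dataset-stratified permutation test on the
difference of group means: labels are permuted within each imaging field,
so field-level speed offsets cannot create a spurious group effect. The
p-value is `(1 + #{|T*| ≥ |T|})/(n_perm + 1)`, two-sided, deterministic
given the seed; exactly two groups are supported (a mixed-effects model is
the natural tool for richer designs and is intentionally not reimplemented
here).

## Synthetic data

The generators emulate the statistical structure of the real inputs, with
truth tables sufficient to score every downstream decision exactly:

- **Niche spot tables**: cap spots on an upper-hemisphere shell
  (40–60 µm) around a virtual tip, a GFP-high committing cluster ~35 µm
  below the tip, dim stromal background in a bounding box. A configured
  fraction of cap spots is "labelled"; their tdTomato-channel detections
  carry ~1 µm registration jitter relative to the SIX2 detections.
- **Constitutive dataset**: a dense SIX2+ population with a known labelled
  fraction, dim background spots, a configurable fraction of spurious
  ultra-bright SIX2 artefacts (above the e¹⁰ bound by construction), and
  manual reference positions jittered uniformly within a 1 µm ball of truly
  labelled spots (strictly inside the 3 µm match radius).
- **Track sets**: per-field drift (constant-velocity or random-walk) shared
  by all tracks and recorded as the reference, plus per-cell isotropic
  Gaussian walks whose per-axis scale is `speed · Δt / E‖N(0, I₃)‖`
  (chi-3 mean, `2√(2/π)`), making the configured intrinsic speed exact in
  expectation.

Intensities are lognormal — microscopy intensities are positive and
right-skewed — and the default high/low parameters are separable by
construction. The labelled-YFP scale (σ = 0.7 on the log scale) is chosen
strongly right-skewed: a mean-minus-one-sd cutoff cuts ~16 % of any
near-symmetric distribution's lower tail, whereas for a right-skewed
intensity distribution the cutoff falls below the bulk of the labelled
population, which is the regime in which that cutoff rule is a sensible
classifier at all. The genuine high-SIX2 scale (σ = 0.15 around 10⁴) keeps
real spots below the e¹⁰ spurious bound by construction.

What the generators do **not** emulate: depth-dependent attenuation,
optical crowding and segmentation errors, spatially varying background,
cell death, tip growth/branching, and non-stationary drift within a field.
Passing the recovery tests therefore shows the *rules* are implemented
faithfully and behave as intended on well-posed inputs, not that the
thresholds are optimal for any particular microscope.

## Numerical choices

- Sample statistics use ddof = 1 throughout (z-scores, YFP cutoff, sweep sd).
- Boundary cases are fixed and tested: attraction branch at `d = tip_size`;
  induction strictly `y < cutoff`; NN rule inclusive at 8 µm; GFP rule
  strict at 10000; cutoff filtering strictly below.
- CSV floats are written at full round-trip precision and read back with
  pandas' round-trip parser.
- Population sizes: a default run (200 cells, 400 steps) finishes in well
  under a second; the replicate counts used in tests and the analysis
  scripts (10 seeds / 10 replicates per grid point) match the convention of
  reporting mean ± sd over 10 simulations per condition.

## Known limitations

- The tip is static; niche remodelling enters only through the global
  scale factor.
- Induction is an abstract counter; no ligand field or signalling kinetics.
- The direction-sampling corner bias (cube-normalised directions) is part
  of the model definition, not corrected.
- The permutation test conditions on the observed group sizes within each
  field; fields containing a single group contribute no label exchanges.
- With the all-cells denominator the early uninduced-fraction transient is
  non-monotone (see Readouts); comparisons pinned to single early steps are
  sensitive to this.
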