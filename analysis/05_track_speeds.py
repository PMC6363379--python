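#!/usr/bin/env python
"""Drift-correct synthetic cell tracks and compare group migration speeds.

Two lineage groups with configured intrinsic speeds (0.3 vs 0.2 um/min,
the faster group standing for the lineage that must make larger movements
to re-enter the cap) share a bulk tissue drift per imaging field. The tip-
landmark reference removes the drift, per-track mean speeds recover the
configured values, and a dataset-stratified permutation test separates the
groups. Writes per-track speeds and a group summary to results/.
"""

from pathlib import Path

import pandas as pd

from nichesim import (
    TrackConfig,
    make_track_set,
    mean_track_speed,
    permutation_group_test,
    speed_table,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    config = TrackConfig(seed=0)  # 0.3 vs 0.2 um/min, 2 fields, 96 frames
    track_set, truth = make_track_set(config)
    speeds = speed_table(track_set)
    speeds.to_csv(RESULTS / "track_speeds.csv", index=False)

    raw = pd.Series(
        [mean_track_speed(t, config.frame_interval) for t in track_set.tracks]
    )
    p = permutation_group_test(
        speeds["speed_um_per_min"].to_numpy(),
        speeds["group"].to_numpy(),
        speeds["dataset_id"].to_numpy(),
        n_perm=10000,
        seed=0,
    )
    summary = (
        speeds.groupby("group")["speed_um_per_min"]
        .agg(["count", "mean", "std"]).reset_index()
    )
    summary["permutation_p"] = p
    summary.to_csv(RESULTS / "track_speed_summary.csv", index=False)

    configured = dict(config.group_speeds)
    for _, row in summary.iterrows():
        print(f"{row['group']}: corrected mean speed "
              f"{row['mean']:.3f} um/min (configured "
              f"{configured[row['group']]:.2f}, n={int(row['count'])})")
    print(f"Uncorrected speeds average {raw.mean():.3f} um/min - bulk drift "
          f"inflates every track until the tip-landmark motion is removed.")
    print(f"Dataset-stratified permutation test: p = {p:.4g} "
          f"({10000} permutations).")


if __name__ == "__main__":
    main()
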