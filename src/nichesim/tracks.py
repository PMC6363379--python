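"""Cell-track drift correction and migration-speed statistics.

Time-lapse fields drift as the explant and its epithelial tips move, so raw
track displacements mix intrinsic cell motility with bulk tissue motion.
Each imaging field carries one manually tracked tip-landmark reference
track; subtracting the reference's frame-to-frame displacement from each
cell's displacement yields niche-relative motion. Speeds are path length
over elapsed time; group comparisons use a dataset-stratified permutation
test on group mean speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError

DEFAULT_FRAME_INTERVAL_MIN = 15.0


@dataclass
class Track:
    """One cell (or landmark) track: strictly increasing integer time
    indices with 3D positions in micrometres."""

    track_id: int
    times: np.ndarray  # (T,) integer time indices
    positions: np.ndarray  # (T, 3) um
    group: str = ""
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.times.shape[0] != self.positions.shape[0]:
            raise ParameterError("times and positions length mismatch")
        if self.times.shape[0] >= 2 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("time indices must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.times.shape[0]


@dataclass
class TrackSet:
    """Tracks plus one reference (tip landmark) track per imaging field."""

    tracks: list[Track]
    references: dict[str, Track]
    frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN  # minutes per time index

    def __post_init__(self) -> None:
        for tr in self.tracks:
            if tr.dataset_id not in self.references:
                raise ParameterError(
                    f"track {tr.track_id}: no reference for dataset {tr.dataset_id!r}"
                )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for is_ref, iterable in ((False, self.tracks), (True, self.references.values())):
            for tr in iterable:
                rows.append(
                    pd.DataFrame(
                        {
                            "dataset_id": tr.dataset_id,
                            "track_id": tr.track_id,
                            "t": tr.times,
                            "x_um": tr.positions[:, 0],
                            "y_um": tr.positions[:, 1],
                            "z_um": tr.positions[:, 2],
                            "group": tr.group,
                            "is_reference": is_ref,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN
    ) -> "TrackSet":
        required = {"dataset_id", "track_id", "t", "x_um", "y_um", "z_um",
                    "group", "is_reference"}
        missing = required - set(frame.columns)
        if missing:
            raise ParameterError(f"track table missing column(s): {sorted(missing)}")
        tracks, references = [], {}
        for (ds, tid, is_ref), sub in frame.groupby(
            ["dataset_id", "track_id", "is_reference"], sort=True
        ):
            sub = sub.sort_values("t")
            tr = Track(
                track_id=int(tid),
                times=sub["t"].to_numpy(),
                positions=sub[["x_um", "y_um", "z_um"]].to_numpy(float),
                group=str(sub["group"].iloc[0]),
                dataset_id=str(ds),
            )
            if bool(is_ref):
                references[str(ds)] = tr
            else:
                tracks.append(tr)
        return cls(tracks=tracks, references=references, frame_interval=frame_interval)


def drift_correct(track: Track, reference: Track) -> Track:
    """Subtract the reference landmark's motion from a cell track.

    The corrected track keeps the raw starting position; each subsequent
    displacement is the raw displacement minus the reference displacement
    over the same interval. The reference is linearly interpolated at the
    track's time indices, and must span the track's time range.
    """
    if track.n_samples < 1:
        raise ParameterError("empty track")
    t = np.asarray(track.times, dtype=float)
    rt = np.asarray(reference.times, dtype=float)
    if t.min() < rt.min() or t.max() > rt.max():
        raise CoverageError(
            f"reference track (t in [{rt.min():g}, {rt.max():g}]) does not cover "
            f"cell track {track.track_id} (t in [{t.min():g}, {t.max():g}])"
        )
    ref_at = np.column_stack(
        [np.interp(t, rt, reference.positions[:, k]) for k in range(3)]
    )
    # anchored at the raw start: ref_at - ref_at[0] vanishes at the first sample
    corrected = track.positions - (ref_at - ref_at[0])
    return Track(
        track_id=track.track_id,
        times=track.times.copy(),
        positions=corrected,
        group=track.group,
        dataset_id=track.dataset_id,
    )


def mean_track_speed(
    track: Track, frame_interval: float = DEFAULT_FRAME_INTERVAL_MIN
) -> float:
    """Mean migration speed in um/min.

    Per-interval speeds (step length over elapsed minutes) are averaged
    weighted by the actual elapsed minutes of each interval, i.e. total
    path length over total elapsed time; for uniformly sampled tracks this
    equals the plain mean of per-interval speeds. Intervals longer than one
    frame (imaging pauses) therefore count by their true duration.
    """
    if track.n_samples < 2:
        raise ParameterError("speed requires at least two samples")
    if frame_interval <= 0:
        raise ParameterError("frame_interval must be > 0")
    steps = np.diff(track.positions, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    elapsed = np.diff(np.asarray(track.times, dtype=float)) * frame_interval
    return float(lengths.sum() / elapsed.sum())


def speed_table(track_set: TrackSet) -> pd.DataFrame:
    """Drift-corrected mean speed per track."""
    rows = []
    for tr in track_set.tracks:
        corrected = drift_correct(tr, track_set.references[tr.dataset_id])
        rows.append(
            {
                "dataset_id": tr.dataset_id,
                "track_id": tr.track_id,
                "group": tr.group,
                "n_samples": tr.n_samples,
                "speed_um_per_min": mean_track_speed(
                    corrected, track_set.frame_interval
                ),
            }
        )
    return pd.DataFrame(rows)


def permutation_group_test(
    speeds,
    groups,
    dataset_ids,
    n_perm: int = 10000,
    seed: int = 0,
) -> float:
    """Two-sided stratified permutation test on the difference of group means.

    Group labels are permuted independently within each imaging field
    (dataset), so field-to-field speed differences cannot masquerade as a
    group effect. Exactly two groups are supported; a dataset containing a
    single group is left unpermuted and contributes no label exchanges.
    Returns ``(1 + #{|T*| >= |T|}) / (n_perm + 1)``.
    """
    speeds = np.asarray(speeds, dtype=float)
    groups = np.asarray(groups)
    dataset_ids = np.asarray(dataset_ids)
    if not (speeds.shape == groups.shape == dataset_ids.shape):
        raise ParameterError("speeds, groups and dataset_ids must align")
    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100")
    levels = np.unique(groups)
    if levels.size != 2:
        raise ParameterError(f"exactly two groups required, got {levels.size}")
    if np.all(speeds == speeds[0]):
        raise ParameterError("degenerate input: all speeds identical")

    def statistic(g: np.ndarray) -> float:
        return float(speeds[g == levels[0]].mean() - speeds[g == levels[1]].mean())

    observed = abs(statistic(groups))
    rng = np.random.default_rng(seed)
    strata = [np.nonzero(dataset_ids == ds)[0] for ds in np.unique(dataset_ids)]
    # strata with one group only never change under within-stratum permutation
    exceed = 0
    perm = groups.copy()
    for _ in range(n_perm):
        for idx in strata:
            perm[idx] = rng.permutation(perm[idx])
        if abs(statistic(perm)) >= observed - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)
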