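"""Synthetic ground-truth inputs for the spot and track pipelines.

The generators emulate the *statistical* structure of whole-mount niche
imaging and tip-relative time-lapse data, not the images themselves:

* a hemispherical shell of SIX2-high cap cells over a virtual tip, a
  Wnt4-GFP-high committing (PTA) cluster below the tip, and dim stromal
  background spots, with a known labelled (tdTomato) subset of the cap;
* a dense SIX2+ population with a known YFP-labelled fraction plus manual
  reference positions, for the constitutive-labelling cutoff workflow;
* track sets sharing a known bulk drift with known per-group intrinsic
  speeds.

Channel intensities are lognormal (microscopy intensities are positive and
right-skewed); the default high/low parameters are chosen separable so the
generators' truth tables can score every downstream classification exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .tracks import Track, TrackSet

# E[||N(0, s^2 I_3)||] = s * 2 * sqrt(2/pi) ... the chi-3 mean coefficient
CHI3_MEAN = np.sqrt(2.0) * 2.0 / np.sqrt(np.pi)


@dataclass
class LogNormalChannel:
    """Lognormal intensity model: location/scale on the log scale."""

    mu_log: float
    sigma_log: float

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.lognormal(self.mu_log, self.sigma_log, size=n)


@dataclass
class NicheSpotConfig:
    """Geometry and intensity model of one synthetic niche.

    Distances in micrometres around a virtual tip centre at the origin;
    the cap occupies the upper hemisphere shell, the committing (PTA)
    cluster sits ``pta_offset`` below the tip centre.
    """

    n_cap: int = 300
    n_pta: int = 60
    n_stroma: int = 300
    cap_shell: tuple[float, float] = (40.0, 60.0)
    pta_offset: float = 35.0
    pta_spread: float = 8.0
    labelled_fraction_cap: float = 0.15
    channel_jitter_um: float = 1.0  # registration jitter between channel detections
    box_halfwidth: float = 120.0
    six2_high: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(30000.0), 0.2)
    )
    six2_low: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(1000.0), 0.4)
    )
    gfp_high: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(40000.0), 0.4)
    )
    gfp_low: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(800.0), 0.6)
    )
    td_intensity: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(15000.0), 0.4)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cap, self.n_pta, self.n_stroma) < 0:
            raise ParameterError("spot counts must be >= 0")
        if not 0.0 <= self.labelled_fraction_cap <= 1.0:
            raise ParameterError("labelled_fraction_cap must lie in [0, 1]")
        if not 0 < self.cap_shell[0] <= self.cap_shell[1]:
            raise ParameterError("cap_shell radii must satisfy 0 < inner <= outer")


def _hemisphere_shell(
    rng: np.random.Generator, n: int, inner: float, outer: float
) -> np.ndarray:
    """Uniform-direction points on the upper (y >= 0) hemisphere shell."""
    z = rng.normal(size=(n, 3))
    z /= np.linalg.norm(z, axis=1)[:, None]
    z[:, 1] = np.abs(z[:, 1])
    radii = rng.uniform(inner, outer, size=n)
    return z * radii[:, None]


def make_niche_spot_tables(
    config: NicheSpotConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthetic (six2 table, tdtomato table, truth table) for one niche.

    The SIX2 table holds cap spots (SIX2-high) plus stromal background
    (SIX2-low). The tdTomato table holds the labelled cap subset (cells
    detected independently in the red channel, so their positions carry a
    small registration jitter) plus every PTA spot (Wnt4-GFP-high). The
    truth table gives each tdTomato spot's true class (``cap`` or ``pta``).
    """
    rng = np.random.default_rng(config.seed)
    cap_pos = _hemisphere_shell(rng, config.n_cap, *config.cap_shell)
    pta_pos = rng.normal(
        loc=(0.0, -config.pta_offset, 0.0),
        scale=config.pta_spread,
        size=(config.n_pta, 3),
    )
    stroma_pos = rng.uniform(
        -config.box_halfwidth, config.box_halfwidth, size=(config.n_stroma, 3)
    )

    six2_pos = np.vstack([cap_pos, stroma_pos])
    six2_int = np.concatenate(
        [
            config.six2_high.sample(rng, config.n_cap),
            config.six2_low.sample(rng, config.n_stroma),
        ]
    )
    six2_table = pd.DataFrame(
        {
            "spot_id": np.arange(six2_pos.shape[0]),
            "x_um": six2_pos[:, 0],
            "y_um": six2_pos[:, 1],
            "z_um": six2_pos[:, 2],
            "six2": six2_int,
        }
    )

    n_labelled = int(round(config.labelled_fraction_cap * config.n_cap))
    labelled_cap = rng.choice(config.n_cap, size=n_labelled, replace=False)
    labelled_cap.sort()
    jitter = rng.normal(
        scale=config.channel_jitter_um / np.sqrt(3.0), size=(n_labelled, 3)
    )
    td_pos = np.vstack([cap_pos[labelled_cap] + jitter, pta_pos])
    n_td = td_pos.shape[0]
    td_table = pd.DataFrame(
        {
            "spot_id": np.arange(n_td),
            "x_um": td_pos[:, 0],
            "y_um": td_pos[:, 1],
            "z_um": td_pos[:, 2],
            "tdtomato": config.td_intensity.sample(rng, n_td),
            "wnt4gfp": np.concatenate(
                [
                    config.gfp_low.sample(rng, n_labelled),
                    config.gfp_high.sample(rng, config.n_pta),
                ]
            ),
        }
    )
    truth = pd.DataFrame(
        {
            "spot_id": np.arange(n_td),
            "true_class": ["cap"] * n_labelled + ["pta"] * config.n_pta,
            "source_six2_id": np.concatenate(
                [labelled_cap, np.full(config.n_pta, -1)]
            ).astype(np.int64),
        }
    )
    return six2_table, td_table, truth


@dataclass
class ConstitutiveConfig:
    """Synthetic dense-labelling dataset for the cutoff-inference workflow."""

    n_cap: int = 1000
    labelled_fraction: float = 0.25
    n_manual: int = 150
    n_background: int = 200  # dim non-cap detections below the cutoffs
    spurious_fraction: float = 0.02  # bright artefacts with log SIX2 > 10
    manual_jitter_um: float = 1.0  # < match radius, keeps matching unambiguous
    box_halfwidth: float = 150.0
    nuclear_high: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(12000.0), 0.25)
    )
    nuclear_low: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(1500.0), 0.4)
    )
    # high-SIX2 scale kept tight so genuine cap spots stay below the e^10
    # spurious-brightness bound by construction
    six2_high: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(10000.0), 0.15)
    )
    six2_low: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(1200.0), 0.4)
    )
    # labelled YFP is strongly right-skewed so the mean-minus-one-sd cutoff
    # falls well below the bulk of the labelled population
    yfp_labelled: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(20000.0), 0.7)
    )
    yfp_unlabelled: LogNormalChannel = field(
        default_factory=lambda: LogNormalChannel(np.log(300.0), 0.6)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.labelled_fraction <= 1.0:
            raise ParameterError("labelled_fraction must lie in [0, 1]")
        if not 0.0 <= self.spurious_fraction < 1.0:
            raise ParameterError("spurious_fraction must lie in [0, 1)")
        n_labelled = int(round(self.labelled_fraction * self.n_cap))
        if self.n_manual > n_labelled:
            raise ParameterError(
                f"n_manual ({self.n_manual}) exceeds labelled spots ({n_labelled})"
            )


def make_constitutive_dataset(
    config: ConstitutiveConfig,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Synthetic (spot table, manual reference positions, truth table).

    Cap spots carry high nuclear and SIX2 signal; a known fraction carries
    high YFP (labelled). Background spots are dim in all channels and a
    small spurious fraction is implausibly SIX2-bright. Manual references
    are jittered positions of a random sample of truly labelled cap spots.
    """
    rng = np.random.default_rng(config.seed)
    n_cap = config.n_cap
    n_lab = int(round(config.labelled_fraction * n_cap))
    n_bg = config.n_background
    n_spur = int(round(config.spurious_fraction * n_cap))
    n_total = n_cap + n_bg + n_spur

    pos = rng.uniform(-config.box_halfwidth, config.box_halfwidth, size=(n_total, 3))
    labelled = np.zeros(n_total, dtype=bool)
    lab_idx = rng.choice(n_cap, size=n_lab, replace=False)
    lab_idx.sort()
    labelled[lab_idx] = True
    is_cap = np.zeros(n_total, dtype=bool)
    is_cap[:n_cap] = True
    is_spurious = np.zeros(n_total, dtype=bool)
    is_spurious[n_cap + n_bg:] = True

    nuclear = np.concatenate(
        [
            config.nuclear_high.sample(rng, n_cap),
            config.nuclear_low.sample(rng, n_bg),
            config.nuclear_high.sample(rng, n_spur),
        ]
    )
    six2 = np.concatenate(
        [
            config.six2_high.sample(rng, n_cap),
            config.six2_low.sample(rng, n_bg),
            # above the e^10 ~ 22026 spurious bound by construction
            np.exp(rng.uniform(10.5, 12.0, size=n_spur)),
        ]
    )
    yfp = np.where(
        labelled,
        config.yfp_labelled.sample(rng, n_total),
        config.yfp_unlabelled.sample(rng, n_total),
    )
    table = pd.DataFrame(
        {
            "spot_id": np.arange(n_total),
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "z_um": pos[:, 2],
            "six2": six2,
            "yfp": yfp,
            "nuclear": nuclear,
        }
    )
    manual_idx = rng.choice(lab_idx, size=config.n_manual, replace=False)
    # jitter uniform in a ball of radius manual_jitter_um, so every reference
    # stays strictly inside the 3 um matching radius by construction
    directions = rng.normal(size=(config.n_manual, 3))
    directions /= np.linalg.norm(directions, axis=1)[:, None]
    radii = config.manual_jitter_um * rng.uniform(size=config.n_manual) ** (1 / 3)
    manual_refs = pos[manual_idx] + directions * radii[:, None]
    truth = pd.DataFrame(
        {
            "spot_id": np.arange(n_total),
            "is_cap": is_cap,
            "is_labelled": labelled,
            "is_spurious": is_spurious,
        }
    )
    return table, manual_refs, truth


@dataclass
class TrackConfig:
    """Synthetic track sets with known drift and intrinsic speeds.

    ``group_speeds`` maps group label -> intrinsic speed (um/min); each
    dataset (imaging field) shares one drift trajectory, either constant
    velocity or a random walk, recorded as the reference track.
    """

    group_speeds: dict[str, float] = field(
        default_factory=lambda: {"wnt4_lineage": 0.3, "six2_lineage": 0.2}
    )
    n_tracks_per_group: int = 25
    n_frames: int = 96
    frame_interval: float = 15.0  # minutes
    n_datasets: int = 2
    drift_kind: str = "constant"  # or "random_walk"
    drift_speed: float = 0.15  # um/min magnitude of the bulk drift
    field_halfwidth: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if any(v < 0 for v in self.group_speeds.values()):
            raise ParameterError("intrinsic speeds must be >= 0")
        if self.drift_kind not in ("constant", "random_walk"):
            raise ParameterError("drift_kind must be 'constant' or 'random_walk'")


def make_track_set(config: TrackConfig) -> tuple[TrackSet, pd.DataFrame]:
    """Synthetic (TrackSet, truth table).

    Cell tracks are the dataset drift plus an isotropic Gaussian random
    walk whose per-axis step scale is calibrated so the *expected* step
    length equals ``speed * frame_interval`` exactly (chi-3 mean); the
    truth table records each track's configured intrinsic speed.
    """
    rng = np.random.default_rng(config.seed)
    step_minutes = config.frame_interval
    times = np.arange(config.n_frames)
    tracks: list[Track] = []
    references: dict[str, Track] = {}
    truth_rows = []
    next_id = 0
    for d in range(config.n_datasets):
        ds = f"field{d}"
        if config.drift_kind == "constant":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            drift_steps = np.tile(
                direction * config.drift_speed * step_minutes, (config.n_frames - 1, 1)
            )
        else:
            drift_steps = rng.normal(
                scale=config.drift_speed * step_minutes / CHI3_MEAN,
                size=(config.n_frames - 1, 3),
            )
        drift_path = np.vstack([np.zeros(3), np.cumsum(drift_steps, axis=0)])
        ref_start = rng.uniform(-config.field_halfwidth, config.field_halfwidth, 3)
        references[ds] = Track(
            track_id=next_id,
            times=times.copy(),
            positions=ref_start + drift_path,
            group="reference",
            dataset_id=ds,
        )
        next_id += 1
        for group, speed in config.group_speeds.items():
            for _ in range(config.n_tracks_per_group):
                start = rng.uniform(
                    -config.field_halfwidth, config.field_halfwidth, 3
                )
                axis_scale = speed * step_minutes / CHI3_MEAN
                intrinsic = (
                    rng.normal(scale=axis_scale, size=(config.n_frames - 1, 3))
                    if speed > 0
                    else np.zeros((config.n_frames - 1, 3))
                )
                path = start + np.vstack(
                    [np.zeros(3), np.cumsum(intrinsic + drift_steps, axis=0)]
                )
                tracks.append(
                    Track(
                        track_id=next_id,
                        times=times.copy(),
                        positions=path,
                        group=group,
                        dataset_id=ds,
                    )
                )
                truth_rows.append(
                    {
                        "dataset_id": ds,
                        "track_id": next_id,
                        "group": group,
                        "intrinsic_speed_um_per_min": speed,
                    }
                )
                next_id += 1
    truth = pd.DataFrame(truth_rows)
    return (
        TrackSet(
            tracks=tracks, references=references, frame_interval=config.frame_interval
        ),
        truth,
    )
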