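"""Whole-mount spot-table analysis: filtering and 3D classification.

Works on tables of detected cell centres ("spots") with 3D positions in
micrometres and per-channel fluorescence intensities, as produced by any
Laplacian-of-Gaussian style spot detector. Two pipelines are covered:

* sparse lineage labelling: tdTomato spots are classed as SIX2+ cap cells
  when their nearest SIX2 spot (after mean-filtering the SIX2 channel)
  lies within 8 um and their Wnt4-GFP intensity is below 10000; the
  labelled fraction is cap-classed tdTomato spots over filtered SIX2 spots.
* dense constitutive labelling: intensity cutoffs (nuclear and SIX2 minima,
  YFP mean minus one sd) are derived from manually marked reference cells
  matched to automated spots within 3 um, then applied to classify the
  whole SIX2+ population as labelled vs unlabelled.

Spot tables are pandas DataFrames with columns ``spot_id, x_um, y_um, z_um``
plus one lowercase column per channel (``six2, tdtomato, wnt4gfp, yfp,
nuclear``; absent channels omitted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (
    DegenerateScaleError,
    ParameterError,
    SchemaError,
    UnmatchedReferenceError,
)

POSITION_COLUMNS = ["x_um", "y_um", "z_um"]
CHANNELS = ("six2", "tdtomato", "wnt4gfp", "yfp", "nuclear")


@dataclass
class ClassifierParams:
    """Thresholds of the spot classification rules.

    nn_max_distance: max nearest-neighbour distance (um, inclusive) for a
        tdTomato spot to count as sitting on a SIX2 spot.
    gfp_max_intensity: strict upper bound on Wnt4-GFP intensity for cap
        classification (at or above it the spot is called PTA/committed).
    manual_match_radius: max distance (um) for matching a manually marked
        position to an automated spot.
    log_six2_max: spots with log(SIX2) above this are dropped as spurious
        bright detections; ``log_base`` selects the logarithm (natural by
        default).
    """

    nn_max_distance: float = 8.0
    gfp_max_intensity: float = 10000.0
    manual_match_radius: float = 3.0
    log_six2_max: float = 10.0
    log_base: float = np.e

    def __post_init__(self) -> None:
        for name in ("nn_max_distance", "gfp_max_intensity", "manual_match_radius",
                     "log_six2_max", "log_base"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")


@dataclass
class CutoffSet:
    """Per-sample intensity cutoffs inferred from manual reference cells."""

    nuclear_cutoff: float
    six2_cutoff: float
    yfp_cutoff: float
    n_matched: int = 0


def validate_spot_table(table: pd.DataFrame, channels: tuple[str, ...] = ()) -> None:
    missing = [c for c in ["spot_id", *POSITION_COLUMNS, *channels]
               if c not in table.columns]
    if missing:
        raise SchemaError(f"spot table missing column(s): {', '.join(missing)}")
    if len(table):
        pos = table[POSITION_COLUMNS].to_numpy(float)
        if not np.all(np.isfinite(pos)):
            raise SchemaError("spot positions must be finite")
        for ch in channels:
            vals = table[ch].to_numpy(float)
            if np.any(vals < 0) or not np.all(np.isfinite(vals)):
                raise SchemaError(f"channel {ch!r} must be finite and >= 0")


def zscore_scale(values) -> np.ndarray:
    """Centre and scale to unit sample standard deviation (ddof=1)."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ParameterError("need at least two values to scale")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise DegenerateScaleError("cannot z-score values with zero spread")
    return (vals - vals.mean()) / sd


def normalize_q99(values) -> np.ndarray:
    """Divide by the population's 99th percentile (display normalisation)."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ParameterError("cannot normalise an empty population")
    q = float(np.quantile(vals, 0.99))
    if q <= 0:
        raise DegenerateScaleError("99th quantile must be > 0")
    return vals / q


def filter_six2_spots(table: pd.DataFrame) -> pd.DataFrame:
    """Keep spots whose z-scored SIX2 intensity is >= 0 (at/above the mean)."""
    validate_spot_table(table, channels=("six2",))
    if len(table) == 0:
        return table.copy()
    scaled = zscore_scale(table["six2"].to_numpy(float))
    return table.loc[scaled >= 0].reset_index(drop=True)


def _nn_with_tiebreak(
    query_xyz: np.ndarray, ref_xyz: np.ndarray, ref_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest neighbour per query point; exact-distance ties -> smallest id."""
    tree = cKDTree(ref_xyz)
    k = min(4, ref_xyz.shape[0])
    dist, idx = tree.query(query_xyz, k=k)
    if k == 1:
        return np.atleast_1d(dist), ref_ids[np.atleast_1d(idx)]
    dist = np.atleast_2d(dist)
    idx = np.atleast_2d(idx)
    best_d = dist[:, 0]
    # among the k nearest, any at (numerically) the minimal distance competes
    tied = dist <= best_d[:, None] + 1e-9
    cand_ids = np.where(tied, ref_ids[idx], np.iinfo(np.int64).max)
    return best_d, cand_ids.min(axis=1)


def nearest_six2_distance(
    td_spots: pd.DataFrame, six2_spots: pd.DataFrame
) -> pd.DataFrame:
    """Nearest SIX2 spot (3D Euclidean) for each tdTomato spot.

    Returns a table with ``spot_id, nn_distance_um, nn_six2_id``; distance
    ties are broken by the smallest SIX2 ``spot_id``.
    """
    validate_spot_table(td_spots)
    validate_spot_table(six2_spots)
    if len(six2_spots) == 0:
        raise ParameterError("SIX2 reference table is empty")
    if len(td_spots) == 0:
        return pd.DataFrame(columns=["spot_id", "nn_distance_um", "nn_six2_id"])
    d, ids = _nn_with_tiebreak(
        td_spots[POSITION_COLUMNS].to_numpy(float),
        six2_spots[POSITION_COLUMNS].to_numpy(float),
        six2_spots["spot_id"].to_numpy(np.int64),
    )
    return pd.DataFrame(
        {
            "spot_id": td_spots["spot_id"].to_numpy(),
            "nn_distance_um": d,
            "nn_six2_id": ids,
        }
    )


def classify_td_spots(
    td_spots: pd.DataFrame,
    six2_filtered: pd.DataFrame,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Class each tdTomato spot as SIX2+ cap cell or not.

    cap  <=>  nearest filtered SIX2 spot within ``nn_max_distance``
    (inclusive) AND Wnt4-GFP intensity strictly below ``gfp_max_intensity``.
    Returns the tdTomato table with ``nn_distance_um, nn_six2_id, is_cap``.
    """
    params = params or ClassifierParams()
    validate_spot_table(td_spots, channels=("wnt4gfp",))
    nn = nearest_six2_distance(td_spots, six2_filtered)
    out = td_spots.merge(nn, on="spot_id", how="left")
    out["is_cap"] = (out["nn_distance_um"] <= params.nn_max_distance) & (
        out["wnt4gfp"].to_numpy(float) < params.gfp_max_intensity
    )
    return out


def labelled_fraction(n_td_cap: int, six2_filtered: pd.DataFrame) -> float:
    """Cap-classed tdTomato spots as a proportion of filtered SIX2 spots."""
    if len(six2_filtered) == 0:
        raise ParameterError("filtered SIX2 table is empty")
    if n_td_cap < 0:
        raise ParameterError("n_td_cap must be >= 0")
    return n_td_cap / len(six2_filtered)


def derive_constitutive_cutoffs(
    auto_spots: pd.DataFrame,
    manual_refs: np.ndarray,
    params: ClassifierParams | None = None,
) -> CutoffSet:
    """Infer per-sample cutoffs from manually marked labelled cap cells.

    Each manual position is matched one-to-one to an automated spot within
    ``manual_match_radius`` (greedy, ascending distance; a spot can serve
    only one reference). Over the matched spots: nuclear cutoff = min
    nuclear, SIX2 cutoff = min SIX2, YFP cutoff = mean(YFP) - sd(YFP)
    (sample sd, ddof=1).
    """
    params = params or ClassifierParams()
    validate_spot_table(auto_spots, channels=("six2", "yfp", "nuclear"))
    refs = np.asarray(manual_refs, dtype=float).reshape(-1, 3)
    if refs.shape[0] == 0:
        raise ParameterError("manual reference set is empty")
    xyz = auto_spots[POSITION_COLUMNS].to_numpy(float)
    tree = cKDTree(xyz)
    # all candidate (reference, spot) pairs within the radius
    neighbour_lists = tree.query_ball_point(refs, params.manual_match_radius)
    pairs = []
    for ri, neighbours in enumerate(neighbour_lists):
        for si in neighbours:
            pairs.append((float(np.linalg.norm(refs[ri] - xyz[si])), ri, si))
    pairs.sort()
    matched_spot: dict[int, int] = {}
    used_spots: set[int] = set()
    for dist, ri, si in pairs:
        if ri in matched_spot or si in used_spots:
            continue
        matched_spot[ri] = si
        used_spots.add(si)
    unmatched = [ri for ri in range(refs.shape[0]) if ri not in matched_spot]
    if unmatched:
        raise UnmatchedReferenceError(unmatched, params.manual_match_radius)
    if len(matched_spot) < 2:
        raise DegenerateScaleError(
            "need at least two matched references to estimate the YFP sd"
        )
    rows = auto_spots.iloc[sorted(matched_spot.values())]
    yfp = rows["yfp"].to_numpy(float)
    return CutoffSet(
        nuclear_cutoff=float(rows["nuclear"].min()),
        six2_cutoff=float(rows["six2"].min()),
        yfp_cutoff=float(yfp.mean() - yfp.std(ddof=1)),
        n_matched=len(rows),
    )


def classify_constitutive(
    auto_spots: pd.DataFrame,
    cutoffs: CutoffSet,
    params: ClassifierParams | None = None,
) -> tuple[pd.DataFrame, float]:
    """Filter the SIX2+ population and split it into labelled vs unlabelled.

    Steps: drop spurious bright spots (log SIX2 above ``log_six2_max``,
    strict); drop spots strictly below the nuclear or SIX2 cutoff (spots at
    a cutoff are retained); flag the rest labelled iff YFP >= YFP cutoff.
    Returns the filtered table with a boolean ``labelled`` column, plus the
    labelled proportion.
    """
    params = params or ClassifierParams()
    validate_spot_table(auto_spots, channels=("six2", "yfp", "nuclear"))
    six2 = auto_spots["six2"].to_numpy(float)
    with np.errstate(divide="ignore"):
        log_six2 = np.log(six2) / np.log(params.log_base)
    keep = log_six2 <= params.log_six2_max
    keep &= auto_spots["nuclear"].to_numpy(float) >= cutoffs.nuclear_cutoff
    keep &= six2 >= cutoffs.six2_cutoff
    kept = auto_spots.loc[keep].reset_index(drop=True)
    if len(kept) == 0:
        raise ParameterError("no spots survive the cutoffs")
    kept = kept.copy()
    kept["labelled"] = kept["yfp"].to_numpy(float) >= cutoffs.yfp_cutoff
    proportion = float(kept["labelled"].mean())
    return kept, proportion
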