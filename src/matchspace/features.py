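"""Per-possession spatiotemporal variables.

Fifteen variables summarize each included ball possession:

* ball path — distance covered (m), mean speed (km/h), speed CV%, speed
  regularity (normalized ApEn, a.u.) and the cumulative length/width ratio
  of the ball displacement;
* team space — effective playing space (EPS), the convex-hull area (m²) of
  the in-possession team's ten outfield players, as a mean and CV% over the
  possession;
* game space — length (x-extent) and width (y-extent) of the region
  covering all twenty outfield players, mean and CV%;
* end of possession — deepest location (x of the most advanced attacking
  outfield player at the final frame), the offensive available space left
  between that player and the goal line (full-width rectangle), and the
  number of opposing outfield players inside that space.

All x/y semantics assume the possession slice has been attack-normalized so
the possessing team attacks toward increasing x.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .entropy import ApEnParams, normalized_apen
from .io import PitchSpec, UsageError, normalize_attack_direction
from .segmentation import PossessionSequence, end_frame_of

logger = logging.getLogger("matchspace")

#: Column order of the features table (matches the descriptive-table layout).
FEATURE_COLUMNS = [
    "duration_s",
    "ball_distance_m",
    "ball_speed_mean_kmh",
    "ball_speed_cv_pct",
    "ball_speed_apen_au",
    "ball_lw_ratio_au",
    "eps_mean_m2",
    "eps_cv_pct",
    "game_length_mean_m",
    "game_length_cv_pct",
    "game_width_mean_m",
    "game_width_cv_pct",
    "deepest_location_m",
    "offensive_space_m2",
    "n_opponents_in_space",
]


@dataclass
class PossessionFeatures:
    duration_s: float
    ball_distance_m: float
    ball_speed_mean_kmh: float
    ball_speed_cv_pct: float
    ball_speed_apen_au: float
    ball_lw_ratio_au: float
    eps_mean_m2: float
    eps_cv_pct: float
    game_length_mean_m: float
    game_length_cv_pct: float
    game_width_mean_m: float
    game_width_cv_pct: float
    deepest_location_m: float
    offensive_space_m2: float
    n_opponents_in_space: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class SpeedSeries:
    """Per-frame-transition ball speeds in km/h."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class FeatureConfig:
    smoothing_window: int = 1  # odd; 1 = no smoothing (raw frame differences)
    apen: ApEnParams | None = None


# ---------------------------------------------------------------------------
# ball-path metrics
# ---------------------------------------------------------------------------


def ball_distance(seq: PossessionSequence) -> float:
    """Total path length (m) of the ball: sum of frame-to-frame displacements."""
    xy = seq.tracking.ball_xy
    if len(xy) < 2:
        raise UsageError("need at least two frames")
    return float(np.sum(np.linalg.norm(np.diff(xy, axis=0), axis=1)))


def ball_speed_series(seq: PossessionSequence, smoothing_window: int = 1) -> SpeedSeries:
    """Per-transition ball speed in km/h, optionally moving-averaged.

    speed = displacement × sampling_rate × 3.6; the mean of the series is
    the possession's reported ball speed.
    """
    xy = seq.tracking.ball_xy
    if len(xy) < 2:
        raise UsageError("need at least two frames")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise UsageError("smoothing_window must be odd and ≥ 1")
    disp = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    speed = disp * seq.tracking.sampling_rate_hz * 3.6
    if smoothing_window > 1:
        if smoothing_window > len(speed):
            raise UsageError("smoothing window larger than the speed series")
        kernel = np.ones(smoothing_window) / smoothing_window
        # centred moving average; edges keep the raw values
        sm = np.convolve(speed, kernel, mode="same")
        h = smoothing_window // 2
        sm[:h], sm[-h:] = speed[:h], speed[-h:]
        speed = sm
    return SpeedSeries(values=speed)


def cv_percent(series) -> float:
    """Coefficient of variation, 100 × sample SD / mean; NaN when mean is 0."""
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 2:
        raise UsageError("CV% needs at least two values")
    mean = float(np.mean(x))
    if mean == 0.0:
        logger.info("CV%% undefined (zero mean); reporting NaN")
        return math.nan
    return 100.0 * float(np.std(x, ddof=1)) / mean


def lw_ratio(seq: PossessionSequence) -> float:
    """Cumulative lengthwise over widthwise ball displacement, Σ|Δx| / Σ|Δy|.

    > 1 means predominantly goal-to-goal circulation. NaN (flagged, logged)
    when the ball never moves across the width.
    """
    xy = seq.tracking.ball_xy
    if len(xy) < 2:
        raise UsageError("need at least two frames")
    dx = float(np.sum(np.abs(np.diff(xy[:, 0]))))
    dy = float(np.sum(np.abs(np.diff(xy[:, 1]))))
    if dy == 0.0:
        logger.info("length/width ratio undefined (no widthwise movement); NaN")
        return math.nan
    return dx / dy


# ---------------------------------------------------------------------------
# space metrics
# ---------------------------------------------------------------------------


def hull_area(points: np.ndarray) -> float:
    """Convex-hull area (m²) of a point set; 0 for < 3 non-collinear points."""
    return float(MultiPoint([tuple(p) for p in points]).convex_hull.area)


def eps_series(seq: PossessionSequence) -> np.ndarray:
    """Effective playing space per frame: convex-hull area (m²) of the
    in-possession team's outfield players. Degenerate (collinear) frames
    yield 0.0."""
    pos = seq.tracking.team_positions(seq.team, "outfield")  # (n, k, 2)
    areas = np.array([hull_area(frame) for frame in pos])
    if np.any(areas == 0.0):
        logger.info("degenerate (collinear) team shape in %d frames", int((areas == 0).sum()))
    return areas


def game_bounds_series(seq: PossessionSequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (length, width): x- and y-extent over all 20 outfield players."""
    both = np.concatenate(
        [seq.tracking.team_positions(t, "outfield") for t in seq.tracking.teams], axis=1
    )
    length = both[:, :, 0].max(axis=1) - both[:, :, 0].min(axis=1)
    width = both[:, :, 1].max(axis=1) - both[:, :, 1].min(axis=1)
    return length, width


# ---------------------------------------------------------------------------
# end-of-possession metrics
# ---------------------------------------------------------------------------


def deepest_location(seq: PossessionSequence) -> float:
    """x (m) of the most advanced attacking outfield player at the end frame."""
    pos = seq.tracking.team_positions(seq.team, "outfield")
    return float(pos[-1, :, 0].max())


def offensive_available_space(seq: PossessionSequence, pitch: PitchSpec | None = None) -> float:
    """Area (m²) between the deepest attacker and the opponents' goal line,
    as a full-pitch-width rectangle at the end frame."""
    pitch = pitch or seq.tracking.pitch
    deep = deepest_location(seq)
    return (pitch.length_m - deep) * pitch.width_m


def opponents_in_space(seq: PossessionSequence) -> int:
    """Opposing outfield players strictly beyond the deepest attacker at the
    end frame (the opposing goalkeeper never counts)."""
    deep = deepest_location(seq)
    opp = seq.tracking.team_positions(seq.opponent, "outfield")
    return int(np.sum(opp[-1, :, 0] > deep))


# ---------------------------------------------------------------------------
# possession summary
# ---------------------------------------------------------------------------


def summarize_possession(
    seq: PossessionSequence,
    config: FeatureConfig | None = None,
    allow_short: bool = False,
) -> PossessionFeatures:
    """All fifteen variables for one (attack-normalized) possession.

    The slice is attack-normalized here if needed, so deepest location and
    offensive space are measured toward the opponents' goal regardless of
    the half or venue. Undefined ratios (zero denominators) propagate as
    NaN and are excluded listwise downstream.
    """
    config = config or FeatureConfig()
    apen_params = config.apen or ApEnParams()
    if not allow_short and seq.n_frames < apen_params.min_length:
        raise UsageError(
            f"possession of {seq.n_frames} frames below the "
            f"{apen_params.min_length}-frame inclusion floor"
        )
    oriented = PossessionSequence(
        team=seq.team,
        start_frame=seq.start_frame,
        end_frame=seq.end_frame,
        tracking=normalize_attack_direction(seq.tracking, seq.team),
        end_reason=seq.end_reason,
        contains_set_piece=seq.contains_set_piece,
        possession_id=seq.possession_id,
    )
    speed = ball_speed_series(oriented, config.smoothing_window)
    eps = eps_series(oriented)
    length, width = game_bounds_series(oriented)
    return PossessionFeatures(
        duration_s=oriented.duration_s,
        ball_distance_m=ball_distance(oriented),
        ball_speed_mean_kmh=float(np.mean(speed.values)),
        ball_speed_cv_pct=cv_percent(speed.values),
        ball_speed_apen_au=normalized_apen(speed.values, apen_params, allow_short=allow_short),
        ball_lw_ratio_au=lw_ratio(oriented),
        eps_mean_m2=float(np.mean(eps)),
        eps_cv_pct=cv_percent(eps),
        game_length_mean_m=float(np.mean(length)),
        game_length_cv_pct=cv_percent(length),
        game_width_mean_m=float(np.mean(width)),
        game_width_cv_pct=cv_percent(width),
        deepest_location_m=deepest_location(oriented),
        offensive_space_m2=offensive_available_space(oriented),
        n_opponents_in_space=float(opponents_in_space(oriented)),
    )


def features_table(
    possessions,
    context: str = "",
    config: FeatureConfig | None = None,
    allow_short: bool = False,
) -> pd.DataFrame:
    """Features CSV frame: one row per possession plus id/team/context columns."""
    rows = []
    for seq in possessions:
        feats = summarize_possession(seq, config, allow_short=allow_short)
        row = {"possession_id": seq.possession_id, "team": seq.team,
               "opponent_quality": context}
        row.update(feats.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["possession_id", "team", "opponent_quality"]
                        + FEATURE_COLUMNS)
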