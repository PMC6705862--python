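"""Reading, writing and normalizing tracking / event data.

The package defines two plain-text dialects for 2-D player-tracking data
sampled at a fixed rate (25 Hz by default) on a pitch with a corner origin
(x along the pitch length, y along the width):

* long-form CSV with header ``frame,time_s,entity_id,team,role,x,y`` — the
  ball uses ``entity_id`` ``ball``, empty team and role ``ball``;
* a single JSON document mirroring the same fields.

Event streams (touches, possession boundaries, set pieces, shots, ball-out)
travel in a companion CSV with header ``frame,kind,team,player_id``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("matchspace")

#: Sampling rate of the optical tracking this pipeline targets.
DEFAULT_SAMPLING_RATE_HZ = 25.0
#: Coordinates may stray this far (m) outside the pitch (ball out of play).
DEFAULT_MARGIN_M = 10.0
#: Decimal places kept on write: 3 ≙ millimetre resolution.
DEFAULT_PRECISION = 3
#: Longest per-player tracking gap (frames) bridged by linear interpolation.
MAX_INTERP_GAP_FRAMES = 5

EVENT_KINDS = frozenset(
    {"touch", "possession_start", "possession_end", "set_piece", "ball_out", "shot"}
)


class MalformedInputError(ValueError):
    """Raised when an input file violates the tracking/event contract."""


class UsageError(ValueError):
    """Raised when the caller asks for something the API does not support."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PitchSpec:
    """Pitch dimensions in metres; origin at a corner.

    ``length_m`` runs goal line to goal line (the x axis), ``width_m``
    touchline to touchline (the y axis).
    """

    length_m: float = 105.0
    width_m: float = 68.0

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.width_m <= 0:
            raise UsageError("pitch dimensions must be positive")

    @property
    def area_m2(self) -> float:
        return self.length_m * self.width_m


@dataclass(frozen=True)
class PlayerInfo:
    """Roster entry: identity, side and role of one tracked player."""

    player_id: str
    team: str
    role: str  # "outfield" | "goalkeeper"

    def __post_init__(self) -> None:
        if self.role not in ("outfield", "goalkeeper"):
            raise UsageError(f"unknown role {self.role!r} for {self.player_id!r}")


@dataclass(frozen=True)
class FrameRecord:
    """One frame: ball position plus a player-id → (x, y) map."""

    frame_index: int
    time_s: float
    ball_xy: np.ndarray
    player_xy: dict[str, np.ndarray]


@dataclass
class TrackingDataset:
    """In-memory tracking data: column arrays per entity.

    ``frame_index`` is strictly increasing and gapless within a playing
    period; ``positions[pid]`` is an ``(n_frames, 2)`` float array (NaN rows
    mark unbridged tracking gaps); ``ball_xy`` has the same shape and never
    contains NaN.
    """

    sampling_rate_hz: float
    pitch: PitchSpec
    roster: tuple[PlayerInfo, ...]
    frame_index: np.ndarray
    ball_xy: np.ndarray
    positions: dict[str, np.ndarray]
    margin_m: float = DEFAULT_MARGIN_M

    # -- derived ------------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def time_s(self) -> np.ndarray:
        return self.frame_index / self.sampling_rate_hz

    @property
    def teams(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in self.roster:
            if p.team not in seen:
                seen.append(p.team)
        return tuple(seen)

    def players_of(self, team: str, role: str | None = None) -> list[str]:
        return [
            p.player_id
            for p in self.roster
            if p.team == team and (role is None or p.role == role)
        ]

    def outfield_ids(self, team: str) -> list[str]:
        return self.players_of(team, "outfield")

    def goalkeeper_id(self, team: str) -> str | None:
        gks = self.players_of(team, "goalkeeper")
        return gks[0] if gks else None

    def frame(self, i: int) -> FrameRecord:
        return FrameRecord(
            frame_index=int(self.frame_index[i]),
            time_s=float(self.frame_index[i] / self.sampling_rate_hz),
            ball_xy=self.ball_xy[i].copy(),
            player_xy={pid: xy[i].copy() for pid, xy in self.positions.items()},
        )

    def slice(self, start_frame: int, end_frame: int) -> "TrackingDataset":
        """Inclusive frame-index slice as a new dataset (copies arrays)."""
        lo = int(np.searchsorted(self.frame_index, start_frame))
        hi = int(np.searchsorted(self.frame_index, end_frame, side="right"))
        if lo >= hi:
            raise UsageError(f"empty slice [{start_frame}, {end_frame}]")
        return TrackingDataset(
            sampling_rate_hz=self.sampling_rate_hz,
            pitch=self.pitch,
            roster=self.roster,
            frame_index=self.frame_index[lo:hi].copy(),
            ball_xy=self.ball_xy[lo:hi].copy(),
            positions={pid: xy[lo:hi].copy() for pid, xy in self.positions.items()},
            margin_m=self.margin_m,
        )

    def team_positions(self, team: str, role: str = "outfield") -> np.ndarray:
        """Stack of shape ``(n_frames, n_players, 2)`` for one team/role."""
        ids = self.players_of(team, role)
        return np.stack([self.positions[pid] for pid in ids], axis=1)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        n = self.n_frames
        if n == 0:
            raise MalformedInputError("dataset has no frames")
        diffs = np.diff(self.frame_index)
        if np.any(diffs <= 0):
            bad = int(self.frame_index[np.argmax(diffs <= 0) + 1])
            raise MalformedInputError(f"frame indices not strictly increasing at frame {bad}")
        if np.any(diffs != 1):
            bad = int(self.frame_index[int(np.argmax(diffs != 1))])
            raise MalformedInputError(f"gap in frame indices after frame {bad}")
        if self.ball_xy.shape != (n, 2):
            raise MalformedInputError("ball positions missing or mis-shaped")
        if np.isnan(self.ball_xy).any():
            bad = int(self.frame_index[int(np.argmax(np.isnan(self.ball_xy).any(axis=1)))])
            raise MalformedInputError(f"missing ball position at frame {bad}")
        for p in self.roster:
            if p.player_id not in self.positions:
                raise MalformedInputError(f"rostered player {p.player_id!r} has no positions")
            if self.positions[p.player_id].shape != (n, 2):
                raise MalformedInputError(f"positions of {p.player_id!r} mis-shaped")
        lo_x, hi_x = -self.margin_m, self.pitch.length_m + self.margin_m
        lo_y, hi_y = -self.margin_m, self.pitch.width_m + self.margin_m
        for pid, xy in list(self.positions.items()) + [("ball", self.ball_xy)]:
            finite = xy[~np.isnan(xy).any(axis=1)]
            if finite.size and (
                finite[:, 0].min() < lo_x
                or finite[:, 0].max() > hi_x
                or finite[:, 1].min() < lo_y
                or finite[:, 1].max() > hi_y
            ):
                raise MalformedInputError(
                    f"coordinates of {pid!r} outside pitch+margin bounds"
                )

    def equals(self, other: "TrackingDataset", atol: float = 0.0) -> bool:
        if (
            self.sampling_rate_hz != other.sampling_rate_hz
            or self.pitch != other.pitch
            or set(self.positions) != set(other.positions)
            or not np.array_equal(self.frame_index, other.frame_index)
        ):
            return False
        if not np.allclose(self.ball_xy, other.ball_xy, atol=atol, equal_nan=True):
            return False
        return all(
            np.allclose(self.positions[pid], other.positions[pid], atol=atol, equal_nan=True)
            for pid in self.positions
        )


@dataclass(frozen=True)
class Event:
    frame: int
    kind: str
    team: str = ""
    player_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise UsageError(f"unknown event kind {self.kind!r}")


@dataclass
class EventStream:
    """Ordered match events; possession_start/_end pairs must nest correctly."""

    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        frames = [e.frame for e in self.events]
        if any(b < a for a, b in zip(frames, frames[1:])):
            raise MalformedInputError("event frames must be non-decreasing")
        open_team: str | None = None
        for e in self.events:
            if e.kind == "possession_start":
                if open_team is not None:
                    raise MalformedInputError(
                        f"possession_start at frame {e.frame} while a possession is open"
                    )
                open_team = e.team
            elif e.kind == "possession_end":
                if open_team is None or e.team != open_team:
                    raise MalformedInputError(
                        f"unmatched possession_end at frame {e.frame}"
                    )
                open_team = None
        if open_team is not None:
            raise MalformedInputError("possession_start without a matching possession_end")

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of_kind(self, *kinds: str) -> list[Event]:
        return [e for e in self.events if e.kind in kinds]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _dataset_from_long(df: pd.DataFrame, sampling_rate_hz: float | None,
                       pitch: PitchSpec, margin_m: float) -> TrackingDataset:
    required = {"frame", "time_s", "entity_id", "team", "role", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedInputError(f"missing columns: {sorted(missing)}")
    df = df.copy()
    df["team"] = df["team"].fillna("")
    frames = np.sort(df["frame"].unique()).astype(np.int64)

    ball = df[df["entity_id"] == "ball"].set_index("frame")
    missing_ball = np.setdiff1d(frames, ball.index.to_numpy())
    if missing_ball.size:
        raise MalformedInputError(f"missing ball row in frame {int(missing_ball[0])}")

    # infer sampling rate from time deltas, cross-check against declared rate
    times = ball.loc[frames, "time_s"].to_numpy(dtype=float)
    if len(frames) >= 2:
        dt = np.median(np.diff(times) / np.diff(frames))
        inferred = 1.0 / dt if dt > 0 else float("nan")
    else:
        inferred = sampling_rate_hz or DEFAULT_SAMPLING_RATE_HZ
    rate = sampling_rate_hz if sampling_rate_hz is not None else inferred
    if sampling_rate_hz is not None and abs(inferred - rate) > 0.01 * rate:
        raise MalformedInputError(
            f"declared rate {rate} Hz inconsistent with time deltas ({inferred:.3f} Hz)"
        )

    players = df[df["entity_id"] != "ball"]
    roster = tuple(
        PlayerInfo(str(pid), str(grp["team"].iloc[0]), str(grp["role"].iloc[0]))
        for pid, grp in players.groupby("entity_id", sort=True)
    )
    pos_index = pd.Index(frames, name="frame")
    positions: dict[str, np.ndarray] = {}
    for p in roster:
        sub = players[players["entity_id"] == p.player_id].set_index("frame")
        xy = sub[["x", "y"]].reindex(pos_index).to_numpy(dtype=float)
        positions[p.player_id] = _interpolate_gaps(xy)

    ds = TrackingDataset(
        sampling_rate_hz=float(rate),
        pitch=pitch,
        roster=roster,
        frame_index=frames,
        ball_xy=ball.loc[frames, ["x", "y"]].to_numpy(dtype=float),
        positions=positions,
        margin_m=margin_m,
    )
    ds.validate()
    return ds


def _interpolate_gaps(xy: np.ndarray, max_gap: int = MAX_INTERP_GAP_FRAMES) -> np.ndarray:
    """Bridge per-player gaps of ≤ max_gap frames linearly; keep longer gaps NaN."""
    out = xy.astype(float).copy()
    nan = np.isnan(out).any(axis=1)
    if not nan.any() or nan.all():
        return out
    idx = np.arange(len(out))
    runs: list[tuple[int, int]] = []
    start = None
    for i, bad in enumerate(nan):
        if bad and start is None:
            start = i
        elif not bad and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(out) - 1))
    for lo, hi in runs:
        if hi - lo + 1 > max_gap or lo == 0 or hi == len(out) - 1:
            continue  # too long, or no anchor on one side — leave NaN
        for c in (0, 1):
            out[lo : hi + 1, c] = np.interp(
                idx[lo : hi + 1], [lo - 1, hi + 1], [out[lo - 1, c], out[hi + 1, c]]
            )
    return out


def read_tracking(
    path: str | Path,
    format: str = "csv",
    sampling_rate_hz: float | None = None,
    pitch: PitchSpec | None = None,
    margin_m: float = DEFAULT_MARGIN_M,
) -> TrackingDataset:
    """Read a tracking file in the long-CSV or JSON dialect.

    Parameters
    ----------
    path
        File to read.
    format
        ``"csv"`` (long form) or ``"json"``.
    sampling_rate_hz
        Declared sampling rate; when given it is checked against the rate
        inferred from time deltas, otherwise the inferred rate is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pitch = pitch or PitchSpec()
    if format == "csv":
        df = pd.read_csv(path, dtype={"entity_id": str, "team": str, "role": str})
        return _dataset_from_long(df, sampling_rate_hz, pitch, margin_m)
    if format == "json":
        doc = json.loads(path.read_text())
        pitch = PitchSpec(**doc.get("pitch", {})) if "pitch" in doc else pitch
        rows = []
        for fr in doc["frames"]:
            rows.append(
                {"frame": fr["frame"], "time_s": fr["time_s"], "entity_id": "ball",
                 "team": "", "role": "ball", "x": fr["ball"][0], "y": fr["ball"][1]}
            )
            for pid, xy in fr["players"].items():
                rows.append(
                    {"frame": fr["frame"], "time_s": fr["time_s"], "entity_id": pid,
                     "team": doc["roster"][pid]["team"], "role": doc["roster"][pid]["role"],
                     "x": xy[0], "y": xy[1]}
                )
        rate = sampling_rate_hz or doc.get("sampling_rate_hz")
        return _dataset_from_long(pd.DataFrame(rows), rate, pitch, margin_m)
    raise UsageError(f"unknown tracking dialect {format!r}")


def write_tracking(
    dataset: TrackingDataset,
    path: str | Path,
    format: str = "csv",
    precision: int = DEFAULT_PRECISION,
) -> None:
    """Write a dataset in the long-CSV or JSON dialect.

    Coordinates are rounded to ``precision`` decimals (default millimetre);
    the file round-trips through :func:`read_tracking` exactly at that
    precision.
    """
    if dataset.n_frames == 0:
        raise UsageError("refusing to write an empty dataset")
    path = Path(path)
    rnd = lambda a: np.round(a, precision)  # noqa: E731
    times = dataset.time_s
    if format == "csv":
        chunks = [
            pd.DataFrame(
                {"frame": dataset.frame_index, "time_s": times, "entity_id": "ball",
                 "team": "", "role": "ball",
                 "x": rnd(dataset.ball_xy[:, 0]), "y": rnd(dataset.ball_xy[:, 1])}
            )
        ]
        for p in dataset.roster:
            xy = dataset.positions[p.player_id]
            chunks.append(
                pd.DataFrame(
                    {"frame": dataset.frame_index, "time_s": times,
                     "entity_id": p.player_id, "team": p.team, "role": p.role,
                     "x": rnd(xy[:, 0]), "y": rnd(xy[:, 1])}
                )
            )
        out = pd.concat(chunks).sort_values(["frame", "entity_id"], kind="stable")
        out.to_csv(path, index=False, float_format=f"%.{precision}f")
        return
    if format == "json":
        doc = {
            "sampling_rate_hz": dataset.sampling_rate_hz,
            "pitch": {"length_m": dataset.pitch.length_m, "width_m": dataset.pitch.width_m},
            "roster": {
                p.player_id: {"team": p.team, "role": p.role} for p in dataset.roster
            },
            "frames": [
                {
                    "frame": int(f), "time_s": round(float(t), 6),
                    "ball": [round(float(v), precision) for v in dataset.ball_xy[i]],
                    "players": {
                        pid: [round(float(v), precision) for v in xy[i]]
                        for pid, xy in dataset.positions.items()
                    },
                }
                for i, (f, t) in enumerate(zip(dataset.frame_index, times))
            ],
        }
        Path(path).write_text(json.dumps(doc))
        return
    raise UsageError(f"unknown tracking dialect {format!r}")


def read_events(path: str | Path) -> EventStream:
    """Read an event CSV with header ``frame,kind,team,player_id``."""
    df = pd.read_csv(path, dtype={"team": str, "player_id": str}, keep_default_na=False)
    events = tuple(
        Event(int(r.frame), str(r.kind), str(r.team), str(r.player_id))
        for r in df.itertuples()
    )
    return EventStream(events)


def write_events(stream: EventStream, path: str | Path) -> None:
    pd.DataFrame(
        [{"frame": e.frame, "kind": e.kind, "team": e.team, "player_id": e.player_id}
         for e in stream]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# attack-direction normalization
# ---------------------------------------------------------------------------


def attack_direction(dataset: TrackingDataset, team: str) -> int:
    """+1 if *team* attacks toward increasing x, −1 otherwise.

    Orientation is inferred from the team's goalkeeper: a keeper whose mean
    x sits in the low half of the pitch guards the x=0 goal, so the team
    attacks toward +x. Falls back to the outfield centroid when no keeper is
    rostered.
    """
    if team not in dataset.teams:
        raise UsageError(f"unknown team {team!r}")
    gk = dataset.goalkeeper_id(team)
    if gk is not None:
        ref_x = float(np.nanmean(dataset.positions[gk][:, 0]))
    else:
        xs = [np.nanmean(dataset.positions[pid][:, 0]) for pid in dataset.outfield_ids(team)]
        ref_x = float(np.mean(xs))
    return 1 if ref_x <= dataset.pitch.length_m / 2 else -1


def normalize_attack_direction(
    dataset: TrackingDataset, team: str, attacking_positive: bool = True
) -> TrackingDataset:
    """Orient the pitch so *team* attacks toward increasing x.

    When a reflection is needed every coordinate maps
    ``(x, y) → (length_m − x, width_m − y)`` (a 180° rotation about the
    pitch centre, hence an isometry). Idempotent on an already-oriented
    dataset; applying it twice equals applying it once.
    """
    direction = attack_direction(dataset, team)
    want = 1 if attacking_positive else -1
    if direction == want:
        return dataset
    L, W = dataset.pitch.length_m, dataset.pitch.width_m
    flip = lambda xy: np.column_stack((L - xy[:, 0], W - xy[:, 1]))  # noqa: E731
    return TrackingDataset(
        sampling_rate_hz=dataset.sampling_rate_hz,
        pitch=dataset.pitch,
        roster=dataset.roster,
        frame_index=dataset.frame_index.copy(),
        ball_xy=flip(dataset.ball_xy),
        positions={pid: flip(xy) for pid, xy in dataset.positions.items()},
        margin_m=dataset.margin_m,
    )
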