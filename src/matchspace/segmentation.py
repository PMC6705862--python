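"""Cutting a match into team ball-possession sequences.

A possession starts when a player first acts on the ball and ends when the
ball is lost or goes out of the pitch after a shot; in the shot case the
sequence is truncated at the shot frame itself, not at the frame the ball
crosses the line. Sequences shorter than a configurable minimum (8 s at
25 Hz, i.e. 200 frames, by default) or containing a set piece are excluded
from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    Event,
    EventStream,
    MalformedInputError,
    TrackingDataset,
    UsageError,
)

logger = logging.getLogger("matchspace")


@dataclass
class SegmentationConfig:
    """Inclusion criteria and fallback-heuristic knobs.

    ``min_frames`` is derived from ``min_duration_s`` and the sampling rate
    (8 s × 25 Hz = 200 frames at the defaults). ``control_radius_m`` /
    ``control_frames`` parameterize the positional possession heuristic used
    only when no event stream is available.
    """

    min_duration_s: float = 8.0
    sampling_rate_hz: float = 25.0
    exclude_set_pieces: bool = True
    control_radius_m: float = 1.5
    control_frames: int = 5

    @property
    def min_frames(self) -> int:
        return round(self.min_duration_s * self.sampling_rate_hz)


@dataclass
class PossessionSequence:
    """One ball-possession episode with its tracking slice."""

    team: str
    start_frame: int
    end_frame: int
    tracking: TrackingDataset
    end_reason: str = "lost"  # "lost" | "ball_out_after_shot"
    contains_set_piece: bool = False
    possession_id: int = -1

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise UsageError("end_frame before start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.tracking.sampling_rate_hz

    @property
    def opponent(self) -> str:
        others = [t for t in self.tracking.teams if t != self.team]
        return others[0]


def end_frame_of(seq: PossessionSequence) -> int:
    """Final frame of a possession (the shot frame for shot-ended ones)."""
    return seq.end_frame


def _candidate_spans(events: EventStream, tracking: TrackingDataset) -> list[dict]:
    """All event-delimited possessions, before inclusion filtering."""
    lo, hi = int(tracking.frame_index[0]), int(tracking.frame_index[-1])
    for e in events:
        if e.frame < lo or e.frame > hi:
            raise MalformedInputError(
                f"event at frame {e.frame} outside tracking range [{lo}, {hi}]"
            )
    spans: list[dict] = []
    start: Event | None = None
    for e in events:
        if e.kind == "possession_start":
            start = e
        elif e.kind == "possession_end" and start is not None:
            spans.append({"team": start.team, "start": start.frame, "end": e.frame})
            start = None
    # annotate set pieces and shot truncation
    for span in spans:
        span["set_piece"] = any(
            s.frame >= span["start"] and s.frame <= span["end"]
            for s in events.of_kind("set_piece")
        )
        span["end_reason"] = "lost"
        shots = [
            s for s in events.of_kind("shot")
            if s.team == span["team"] and span["start"] <= s.frame <= span["end"]
        ]
        if shots:
            ball_out_after = any(
                b.frame > shots[-1].frame for b in events.of_kind("ball_out")
            )
            if ball_out_after or shots[-1].frame == span["end"]:
                span["end"] = shots[-1].frame
                span["end_reason"] = "ball_out_after_shot"
    return spans


def _has_tracking_gap(sl: TrackingDataset) -> bool:
    return any(np.isnan(xy).any() for xy in sl.positions.values())


def segment_possessions(
    events: EventStream,
    tracking: TrackingDataset,
    config: SegmentationConfig | None = None,
) -> list[PossessionSequence]:
    """Included possession sequences, ordered by start frame.

    Applies the inclusion criteria: span ≥ ``config.min_frames``, no set
    piece within the span (whole-sequence exclusion), and no unbridged
    tracking gap inside the slice.
    """
    config = config or SegmentationConfig(sampling_rate_hz=tracking.sampling_rate_hz)
    included: list[PossessionSequence] = []
    for i, span in enumerate(_candidate_spans(events, tracking)):
        n = span["end"] - span["start"] + 1
        if n < config.min_frames:
            continue
        if config.exclude_set_pieces and span["set_piece"]:
            continue
        sl = tracking.slice(span["start"], span["end"])
        if _has_tracking_gap(sl):
            logger.info("possession %d rejected: tracking gap", i)
            continue
        included.append(
            PossessionSequence(
                team=span["team"],
                start_frame=span["start"],
                end_frame=span["end"],
                tracking=sl,
                end_reason=span["end_reason"],
                contains_set_piece=span["set_piece"],
                possession_id=i,
            )
        )
    included.sort(key=lambda s: s.start_frame)
    return included


def possession_manifest(
    events: EventStream,
    tracking: TrackingDataset,
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Audit table of every candidate possession with inclusion bookkeeping.

    Columns: ``possession_id,team,start_frame,end_frame,duration_s,
    end_reason,included,exclusion_reason``.
    """
    config = config or SegmentationConfig(sampling_rate_hz=tracking.sampling_rate_hz)
    rows = []
    for i, span in enumerate(_candidate_spans(events, tracking)):
        n = span["end"] - span["start"] + 1
        reason = ""
        if n < config.min_frames:
            reason = "below_min_duration"
        elif config.exclude_set_pieces and span["set_piece"]:
            reason = "set_piece"
        elif _has_tracking_gap(tracking.slice(span["start"], span["end"])):
            reason = "tracking_gap"
        rows.append(
            {
                "possession_id": i,
                "team": span["team"],
                "start_frame": span["start"],
                "end_frame": span["end"],
                "duration_s": n / tracking.sampling_rate_hz,
                "end_reason": span["end_reason"],
                "included": reason == "",
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "possession_id", "team", "start_frame", "end_frame", "duration_s",
            "end_reason", "included", "exclusion_reason",
        ],
    )


def infer_possessions_from_touches(
    tracking: TrackingDataset, config: SegmentationConfig | None = None
) -> EventStream:
    """Positional fallback: derive possession events from proximity alone.

    A team gains possession once one of its players is the nearest to the
    ball within ``control_radius_m`` for at least ``control_frames``
    consecutive frames; possession ends when the other team does the same
    or the ball leaves the pitch bounds for more than ``control_frames``
    frames. This is a stand-in for annotated events, not a reproduction of
    manual possession coding.
    """
    config = config or SegmentationConfig(sampling_rate_hz=tracking.sampling_rate_hz)
    teams = tracking.teams
    n = tracking.n_frames
    # nearest-player team per frame, None when nobody is within the radius
    dists = {}
    for team in teams:
        pos = tracking.team_positions(team, "outfield")  # (n, k, 2)
        d = np.linalg.norm(pos - tracking.ball_xy[:, None, :], axis=2)
        dists[team] = np.nanmin(d, axis=1)
    cand = np.full(n, -1)
    stacked = np.column_stack([dists[t] for t in teams])
    nearest = np.argmin(stacked, axis=1)
    within = stacked[np.arange(n), nearest] <= config.control_radius_m
    cand[within] = nearest[within]

    L, W = tracking.pitch.length_m, tracking.pitch.width_m
    out_of_pitch = (
        (tracking.ball_xy[:, 0] < 0) | (tracking.ball_xy[:, 0] > L)
        | (tracking.ball_xy[:, 1] < 0) | (tracking.ball_xy[:, 1] > W)
    )

    events: list[Event] = []
    holder = -1          # team index currently in possession
    run_team, run_len, run_start = -1, 0, 0
    out_run = 0
    for i in range(n):
        f = int(tracking.frame_index[i])
        if holder >= 0:
            out_run = out_run + 1 if out_of_pitch[i] else 0
            if out_run > config.control_frames:
                events.append(Event(f, "ball_out"))
                events.append(Event(f, "possession_end", teams[holder]))
                holder, run_team, run_len, out_run = -1, -1, 0, 0
                continue
        c = cand[i]
        if c == run_team and c != -1:
            run_len += 1
        else:
            run_team, run_len, run_start = (int(c), 1, i) if c != -1 else (-1, 0, i)
        if run_team != -1 and run_team != holder and run_len >= config.control_frames:
            sf = int(tracking.frame_index[run_start])
            if holder >= 0:
                end = int(tracking.frame_index[max(run_start - 1, 0)])
                events.append(Event(end, "possession_end", teams[holder]))
                if sf <= end:
                    sf = int(tracking.frame_index[min(run_start, n - 1)])
            holder = run_team
            events.append(Event(sf, "possession_start", teams[holder]))
    if holder >= 0:
        events.append(Event(int(tracking.frame_index[-1]), "possession_end", teams[holder]))
    events.sort(key=lambda e: e.frame)
    return EventStream(tuple(events))
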