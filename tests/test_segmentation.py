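"""Possession segmentation: inclusion criteria, shot truncation, heuristics."""

import numpy as np
import pytest

from matchspace import (
    MalformedInputError,
    SegmentationConfig,
    end_frame_of,
    infer_possessions_from_touches,
    possession_manifest,
    segment_possessions,
)
from matchspace.io import Event, EventStream

from conftest import make_dataset


def _events(*evts):
    return EventStream(tuple(evts))


@pytest.fixture()
def tracking600():
    return make_dataset(n_frames=600, seed=1)


class TestInclusionCriteria:
    def test_full_length_possession_included(self, tracking600):
        events = _events(
            Event(0, "possession_start", "home"),
            Event(249, "possession_end", "home"),
            Event(250, "possession_start", "away"),
            Event(599, "possession_end", "away"),
        )
        seqs = segment_possessions(events, tracking600)
        assert [(s.team, s.n_frames) for s in seqs] == [("home", 250), ("away", 350)]

    def test_below_200_frames_excluded(self, tracking600):
        events = _events(
            Event(0, "possession_start", "home"),
            Event(189, "possession_end", "home"),  # 190 frames < 8 s × 25 Hz
        )
        assert segment_possessions(events, tracking600) == []

    def test_set_piece_excludes_whole_sequence(self, tracking600):
        events = _events(
            Event(0, "possession_start", "home"),
            Event(150, "set_piece", "home"),
            Event(299, "possession_end", "home"),
        )
        assert segment_possessions(events, tracking600) == []
        man = possession_manifest(events, tracking600)
        assert man.loc[0, "exclusion_reason"] == "set_piece"

    def test_min_frames_matches_duration_rule(self):
        cfg = SegmentationConfig(min_duration_s=8.0, sampling_rate_hz=25.0)
        assert cfg.min_frames == 200

    def test_monotone_filtering(self, small_match):
        tracking, events, _, _ = small_match
        counts = [
            len(segment_possessions(events, tracking,
                                    SegmentationConfig(min_duration_s=s)))
            for s in (4.0, 8.0, 12.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_included_durations_at_least_8s(self, small_match):
        tracking, events, _, _ = small_match
        for seq in segment_possessions(events, tracking):
            assert seq.duration_s >= 8.0

    def test_per_team_sequences_disjoint(self, small_match):
        tracking, events, _, _ = small_match
        seqs = segment_possessions(events, tracking)
        for team in ("home", "away"):
            spans = sorted(
                (s.start_frame, s.end_frame) for s in seqs if s.team == team
            )
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                assert a1 < b0

    def test_event_outside_tracking_range(self, tracking600):
        events = _events(
            Event(0, "possession_start", "home"),
            Event(700, "possession_end", "home"),
        )
        with pytest.raises(MalformedInputError, match="outside tracking range"):
            segment_possessions(events, tracking600)


class TestShotEnding:
    def test_shot_truncates_to_shot_frame(self, tracking600):
        events = _events(
            Event(0, "possession_start", "home"),
            Event(350, "shot", "home"),
            Event(380, "ball_out", ""),
            Event(380, "possession_end", "home"),
        )
        (seq,) = segment_possessions(events, tracking600)
        assert end_frame_of(seq) == 350
        assert seq.end_reason == "ball_out_after_shot"

    def test_plain_possession_end_frame(self, tracking600):
        events = _events(
            Event(100, "possession_start", "away"),
            Event(399, "possession_end", "away"),
        )
        (seq,) = segment_possessions(events, tracking600)
        assert end_frame_of(seq) == 399
        assert seq.end_reason == "lost"


class TestGroundTruthRecovery:
    def test_recovers_generated_possession_log(self, small_match):
        tracking, events, truth, _ = small_match
        seqs = segment_possessions(events, tracking)
        expected = truth.included
        assert len(seqs) == len(expected)
        for seq, row in zip(seqs, expected):
            assert seq.team == row["team"]
            assert seq.start_frame == row["start_frame"]
            assert seq.end_frame == row["end_frame"]
            assert seq.end_reason == row["end_reason"]

    def test_manifest_counts_cover_every_candidate(self, small_match):
        tracking, events, truth, scenario = small_match
        man = possession_manifest(events, tracking)
        assert len(man) == 2 * scenario.n_possessions_per_team
        assert int(man["included"].sum()) == len(truth.included)


class TestPositionalHeuristic:
    def _controlled_dataset(self, n_frames, controller="home_01", ball_path=None):
        ds = make_dataset(n_frames=n_frames, seed=2)
        if ball_path is None:
            ball_path = np.tile([50.0, 30.0], (n_frames, 1))
        ds.ball_xy = ball_path.astype(float)
        # park everyone far from the ball, then glue the controller to it
        for pid in ds.positions:
            ds.positions[pid] = ds.positions[pid] * 0 + [10.0, 60.0]
        ds.positions["home_gk"][:] = [3.0, 34.0]
        ds.positions["away_gk"][:] = [102.0, 34.0]
        ds.positions[controller] = ds.ball_xy + 0.3
        return ds

    def test_single_team_control_emits_one_possession(self):
        ds = self._controlled_dataset(75)  # 3 s of unambiguous control
        events = infer_possessions_from_touches(ds)
        kinds = [(e.kind, e.team) for e in events]
        assert kinds == [("possession_start", "home"), ("possession_end", "home")]

    def test_ball_out_of_bounds_ends_possession(self):
        n = 80
        ball = np.tile([50.0, 30.0], (n, 1))
        ball[60:] = [108.0, 30.0]  # leaves the pitch for 20 frames
        ds = self._controlled_dataset(n, ball_path=ball)
        ds.positions["home_01"][60:] = [95.0, 30.0]  # controller stays on pitch
        events = infer_possessions_from_touches(ds)
        assert [e.kind for e in events] == ["possession_start", "ball_out", "possession_end"]

    def test_rapid_alternation_below_hysteresis_emits_nothing(self):
        n = 60
        ds = make_dataset(n_frames=n, seed=3)
        ds.ball_xy = np.tile([50.0, 30.0], (n, 1))
        for pid in ds.positions:
            ds.positions[pid] = ds.positions[pid] * 0 + [10.0, 60.0]
        ds.positions["home_gk"][:] = [3.0, 34.0]
        ds.positions["away_gk"][:] = [102.0, 34.0]
        # teams swap the nearest player every 2 frames (< control_frames = 5)
        near, far = [50.3, 30.3], [90.0, 60.0]
        for t in range(n):
            a, b = (near, far) if (t // 2) % 2 == 0 else (far, near)
            ds.positions["home_01"][t] = a
            ds.positions["away_01"][t] = b
        events = infer_possessions_from_touches(ds)
        assert len(events) == 0

    def test_deterministic(self):
        ds = self._controlled_dataset(75)
        e1 = infer_possessions_from_touches(ds)
        e2 = infer_possessions_from_touches(ds)
        assert e1.events == e2.events
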