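"""Per-possession variables: closed-form fixtures, oracles, invariances."""

import math

import numpy as np
import pytest

from matchspace import (
    UsageError,
    ball_distance,
    ball_speed_series,
    cv_percent,
    deepest_location,
    eps_series,
    game_bounds_series,
    hull_area,
    lw_ratio,
    offensive_available_space,
    opponents_in_space,
    scripted_possession,
    summarize_possession,
)


def hull_area_bruteforce(points):
    """Brute-force convex hull: an ordered pair is a hull edge iff every
    other point lies strictly to its left; chain edges, then shoelace."""
    pts = [tuple(map(float, p)) for p in points]
    n = len(pts)
    edges = {}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            ax, ay = pts[i]
            bx, by = pts[j]
            left = right = False
            for k in range(n):
                if k in (i, j):
                    continue
                cx, cy = pts[k]
                cross = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
                if cross > 0:
                    left = True
                elif cross < 0:
                    right = True
            if left and not right:
                edges[i] = j
    if not edges:
        return 0.0
    start = next(iter(edges))
    order = [start]
    cur = edges[start]
    while cur != start:
        order.append(cur)
        cur = edges[cur]
    xs = [pts[i][0] for i in order]
    ys = [pts[i][1] for i in order]
    m = len(order)
    return 0.5 * abs(
        sum(xs[i] * ys[(i + 1) % m] - xs[(i + 1) % m] * ys[i] for i in range(m))
    )


class TestBallPath:
    def test_straight_line_distance(self, square_layout, default_defenders):
        seq = scripted_possession([(30.0, 20.0), (40.0, 20.0)],
                                  square_layout, default_defenders, n_frames=201)
        assert abs(ball_distance(seq) - 10.0) < 1e-9

    def test_l_shape_additivity(self, l_shaped_possession):
        assert abs(ball_distance(l_shaped_possession) - 45.0) < 1e-9

    def test_l_shape_over_ten_seconds(self, square_layout, default_defenders):
        # 45 m in 10 s → mean speed 16.2 km/h (the corner falls between
        # samples, so the path is short by less than one 0.18 m step)
        seq = scripted_possession([(30.0, 20.0), (60.0, 20.0), (60.0, 35.0)],
                                  square_layout, default_defenders, n_frames=251)
        assert abs(ball_distance(seq) - 45.0) < 0.05
        assert abs(float(np.mean(ball_speed_series(seq).values)) - 16.2) < 0.02
        assert abs(lw_ratio(seq) - 2.0) < 1e-9

    def test_stationary_ball(self, square_layout, default_defenders):
        seq = scripted_possession([(30.0, 20.0), (30.0, 20.0)],
                                  square_layout, default_defenders, n_frames=201)
        assert ball_distance(seq) == 0.0
        assert np.all(ball_speed_series(seq).values == 0.0)

    def test_constant_speed_unit_conversion(self, square_layout, default_defenders):
        # 5 m/s for 8 s: 40 m straight over 201 frames at 25 Hz
        seq = scripted_possession([(30.0, 20.0), (70.0, 20.0)],
                                  square_layout, default_defenders, n_frames=201)
        speeds = ball_speed_series(seq).values
        assert np.allclose(speeds, 18.0)  # 5 m/s × 3.6

    def test_l_shape_mean_speed(self, l_shaped_possession):
        # 45 m over 12 s (301 frames) → 3.75 m/s = 13.5 km/h, every step equal
        speeds = ball_speed_series(l_shaped_possession).values
        assert abs(float(np.mean(speeds)) - 13.5) < 1e-9

    def test_speed_series_matches_displacement_oracle(self, small_match):
        from matchspace import segment_possessions
        tracking, events, _, _ = small_match
        seq = segment_possessions(events, tracking)[0]
        xy = seq.tracking.ball_xy
        oracle = [
            math.hypot(xy[i + 1, 0] - xy[i, 0], xy[i + 1, 1] - xy[i, 1]) * 25.0 * 3.6
            for i in range(len(xy) - 1)
        ]
        assert np.abs(ball_speed_series(seq).values - oracle).max() < 1e-9

    def test_smoothing_window_validation(self, l_shaped_possession):
        with pytest.raises(UsageError):
            ball_speed_series(l_shaped_possession, smoothing_window=4)
        with pytest.raises(UsageError):
            ball_speed_series(l_shaped_possession, smoothing_window=1001)

    def test_lw_ratio_cases(self, square_layout, default_defenders):
        mk = lambda poly: scripted_possession(  # noqa: E731
            poly, square_layout, default_defenders, n_frames=201)
        assert abs(lw_ratio(mk([(30, 20), (60, 20), (60, 35)])) - 2.0) < 1e-9
        assert abs(lw_ratio(mk([(30, 20), (50, 40)])) - 1.0) < 1e-9
        assert lw_ratio(mk([(50, 20), (50, 40)])) == 0.0
        assert math.isnan(lw_ratio(mk([(30, 20), (60, 20)])))  # no width movement

    def test_lw_ratio_axis_swap_reciprocal(self, square_layout, default_defenders):
        poly = [(30.0, 20.0), (55.0, 30.0), (40.0, 45.0)]
        swapped = [(y, x) for x, y in poly]
        a = lw_ratio(scripted_possession(poly, square_layout, default_defenders,
                                         n_frames=201))
        b = lw_ratio(scripted_possession(swapped, square_layout, default_defenders,
                                         n_frames=201))
        assert abs(a - 1.0 / b) < 1e-9


class TestCV:
    def test_constant_series_zero(self):
        assert cv_percent([4.0] * 10) == 0.0

    def test_hand_computed_value(self):
        assert abs(cv_percent([1.0, 2.0, 3.0]) - 50.0) < 1e-12

    def test_matches_definition_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1.0, 5.0, 100)
        mean = sum(x) / len(x)
        sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (len(x) - 1))
        assert abs(cv_percent(x) - 100.0 * sd / mean) < 1e-9

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1.0, 3.0, 50)
        base = cv_percent(x)
        for c in (0.001, 2.5, 1e4):
            assert abs(cv_percent(c * x) - base) < 1e-9

    def test_zero_mean_flagged_not_raised(self):
        assert math.isnan(cv_percent([-1.0, 1.0]))


class TestSpace:
    def test_square_hull(self, square_layout, default_defenders):
        seq = scripted_possession([(30, 20), (40, 20)], square_layout,
                                  default_defenders, n_frames=201)
        areas = eps_series(seq)
        assert np.allclose(areas, 100.0)
        assert cv_percent(areas) == 0.0

    def test_collinear_players_degenerate(self, default_defenders):
        collinear = np.column_stack([np.linspace(30, 60, 10), np.full(10, 30.0)])
        seq = scripted_possession([(30, 20), (40, 20)], collinear,
                                  default_defenders, n_frames=201)
        assert np.all(eps_series(seq) == 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_hull_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform([0, 0], [105, 68], (10, 2))
        assert abs(hull_area(pts) - hull_area_bruteforce(pts)) < 1e-6

    def test_game_bounds_example(self, default_defenders):
        atk = np.column_stack([np.linspace(30, 68, 10), np.linspace(10, 53, 10)])
        dfd = np.column_stack([np.linspace(35, 60, 10), np.linspace(15, 50, 10)])
        seq = scripted_possession([(40, 30), (50, 30)], atk, dfd, n_frames=201)
        length, width = game_bounds_series(seq)
        assert np.allclose(length, 38.0)
        assert np.allclose(width, 43.0)

    def test_bounds_translation_invariance(self, square_layout, default_defenders):
        seq = scripted_possession([(40, 30), (50, 30)], square_layout,
                                  default_defenders, n_frames=201)
        shifted = scripted_possession([(45, 35), (55, 35)], square_layout + 5.0,
                                      default_defenders + 5.0, n_frames=201)
        for a, b in zip(game_bounds_series(seq), game_bounds_series(shifted)):
            assert np.allclose(a, b)

    def test_hull_inside_bounding_box(self, small_match):
        from matchspace import segment_possessions
        tracking, events, _, _ = small_match
        seq = segment_possessions(events, tracking)[0]
        areas = eps_series(seq)
        length, width = game_bounds_series(seq)
        assert np.all(areas <= length * width + 1e-9)


class TestEndOfPossession:
    def test_deepest_is_max_attacker_x(self, default_defenders):
        atk = np.column_stack([np.linspace(40, 60, 10), np.linspace(20, 48, 10)])
        atk[4] = [83.2, 30.0]
        seq = scripted_possession([(40, 30), (50, 30)], atk, default_defenders,
                                  n_frames=201)
        assert abs(deepest_location(seq) - 83.2) < 1e-9

    def test_offensive_space_rectangle(self, default_defenders):
        atk = np.column_stack([np.linspace(40, 60, 10), np.linspace(20, 48, 10)])
        atk[0] = [83.24, 30.0]
        seq = scripted_possession([(40, 30), (50, 30)], atk, default_defenders,
                                  n_frames=201)
        assert abs(offensive_available_space(seq) - (105.0 - 83.24) * 68.0) < 1e-9

    def test_offensive_space_boundaries(self, default_defenders):
        atk = np.column_stack([np.linspace(40, 60, 10), np.linspace(20, 48, 10)])
        atk[0] = [105.0, 34.0]
        seq = scripted_possession([(40, 30), (50, 30)], atk, default_defenders,
                                  n_frames=201)
        assert offensive_available_space(seq) == 0.0
        atk2 = np.tile([0.0, 34.0], (10, 1))
        seq2 = scripted_possession([(40, 30), (50, 30)],
                                   atk2 + np.column_stack([np.zeros(10),
                                                           np.linspace(-10, 10, 10)]),
                                   default_defenders, n_frames=201)
        assert offensive_available_space(seq2) == 105.0 * 68.0

    def test_opponents_in_space_excludes_goalkeeper(self, square_layout):
        # deepest attacker at x = 50; two defenders beyond; away GK at 104 ignored
        dfd = np.column_stack([np.linspace(20, 45, 10), np.linspace(15, 50, 10)])
        dfd[8] = [60.0, 30.0]
        dfd[9] = [70.0, 40.0]
        seq = scripted_possession([(40, 30), (45, 30)], square_layout, dfd,
                                  n_frames=201)
        assert opponents_in_space(seq) == 2

    def test_no_opponents_beyond_deepest(self, square_layout):
        dfd = np.column_stack([np.linspace(10, 40, 10), np.linspace(15, 50, 10)])
        seq = scripted_possession([(40, 30), (45, 30)], square_layout, dfd,
                                  n_frames=201)
        assert opponents_in_space(seq) == 0


class TestSummary:
    def test_closed_form_scripted_possession(self, l_shaped_possession):
        # 30 m lengthwise + 15 m widthwise over 12 s, static players
        seq = l_shaped_possession
        f = summarize_possession(seq)
        assert abs(f.duration_s - 301 / 25.0) < 1e-9
        assert abs(f.ball_distance_m - 45.0) < 1e-9
        assert abs(f.ball_speed_mean_kmh - 13.5) < 1e-9
        assert abs(f.ball_speed_cv_pct) < 1e-9
        assert f.ball_speed_apen_au == 0.0  # constant speed is perfectly regular
        assert abs(f.ball_lw_ratio_au - 2.0) < 1e-9
        assert abs(f.eps_mean_m2 - 100.0) < 1e-9
        assert abs(f.eps_cv_pct) < 1e-12
        assert abs(f.game_length_mean_m - (90.0 - 40.0)) < 1e-9
        assert abs(f.game_width_mean_m - (48.0 - 20.0)) < 1e-9
        assert abs(f.deepest_location_m - 50.0) < 1e-9
        assert abs(f.offensive_space_m2 - (105.0 - 50.0) * 68.0) < 1e-9
        assert f.n_opponents_in_space == 10.0  # defenders span x ∈ [60, 90]

    def test_short_possession_rejected(self, square_layout, default_defenders):
        seq = scripted_possession([(30, 20), (40, 20)], square_layout,
                                  default_defenders, n_frames=199, allow_short=True)
        with pytest.raises(UsageError, match="inclusion floor"):
            summarize_possession(seq)

    def test_invariant_under_double_reflection(self, small_match):
        from matchspace import normalize_attack_direction, segment_possessions
        from matchspace.segmentation import PossessionSequence

        tracking, events, _, _ = small_match
        seq = segment_possessions(events, tracking)[1]
        twice = PossessionSequence(
            team=seq.team, start_frame=seq.start_frame, end_frame=seq.end_frame,
            tracking=normalize_attack_direction(
                normalize_attack_direction(seq.tracking, seq.team), seq.team),
            end_reason=seq.end_reason, possession_id=seq.possession_id,
        )
        fa = summarize_possession(seq)
        fb = summarize_possession(twice)
        for name, va in fa.as_dict().items():
            assert va == pytest.approx(fb.as_dict()[name], abs=1e-9), name
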