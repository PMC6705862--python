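"""Synthetic match generator with ground-truth sidecars.

Real optical-tracking feeds are proprietary, so every stage of the pipeline
is exercised against simulated matches that reproduce the *measured*
statistical structure of elite-match possessions — not tactical realism:

* 25 Hz sampling on a 105 × 68 m pitch, 10 outfield players + goalkeeper
  per team;
* possession episodes with log-normal durations (including a share below
  the 8 s inclusion floor) and optional set pieces / shot endings;
* outfield players as mean-reverting (OU) noise around formation anchors,
  rescaled so the time-averaged effective playing space, game length/width
  and end-of-possession deepest location hit scenario targets;
* a ball alternating dwell phases at the holder with straight passes at
  jittered flight speeds, which yields realistic speed variability and
  entropy gradients.

Everything is reproducible from the scenario seed, and a ground-truth
possession log is returned for exact recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Event,
    EventStream,
    PitchSpec,
    PlayerInfo,
    TrackingDataset,
    UsageError,
)
from .segmentation import PossessionSequence

logger = logging.getLogger("matchspace")


@dataclass
class FeatureTargets:
    """Per-team targets the generator calibrates toward (match-play scales)."""

    eps_mean_m2: float = 985.0
    game_length_m: float = 38.0
    game_width_m: float = 44.0
    deepest_location_m: float = 83.0
    ball_speed_mean_kmh: float = 22.5
    duration_mean_s: float = 29.0
    duration_sd_s: float = 18.0


@dataclass
class MatchScenario:
    """Everything the generator needs; the seed is mandatory."""

    seed: int
    pitch: PitchSpec = field(default_factory=PitchSpec)
    n_possessions_per_team: int = 30
    sampling_rate_hz: float = 25.0
    targets: dict[str, FeatureTargets] = field(
        default_factory=lambda: {
            "home": FeatureTargets(eps_mean_m2=985.0),
            "away": FeatureTargets(eps_mean_m2=909.0),
        }
    )
    set_piece_prob: float = 0.1
    shot_prob: float = 0.15
    short_fraction: float = 0.2  # share of possessions drawn below 8 s
    gap_frames: int = 30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise UsageError("scenario seed is mandatory")
        for prob in (self.set_piece_prob, self.shot_prob, self.short_fraction):
            if not 0.0 <= prob <= 1.0:
                raise UsageError("probabilities must lie in [0, 1]")
        for team, t in self.targets.items():
            if t.eps_mean_m2 >= self.pitch.area_m2:
                raise UsageError(f"EPS target for {team!r} exceeds the pitch area")
            if not 0 < t.deepest_location_m < self.pitch.length_m:
                raise UsageError(f"deepest-location target for {team!r} off the pitch")


@dataclass
class GroundTruth:
    """Sidecar the tests compare against: one row per generated possession."""

    possessions: list[dict]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"possessions": self.possessions}, indent=1))

    @property
    def included(self) -> list[dict]:
        return [p for p in self.possessions if p["included_expected"]]


# ---------------------------------------------------------------------------
# player-cloud machinery
# ---------------------------------------------------------------------------

# 10-anchor formation (4-4-2-ish) in local coords, roughly centred on 0
_FORMATION = np.array(
    [
        [-14.0, -18.0], [-15.0, -6.0], [-15.0, 6.0], [-14.0, 18.0],
        [-2.0, -15.0], [-3.0, -5.0], [-3.0, 5.0], [-2.0, 15.0],
        [10.0, -7.0], [10.0, 7.0],
    ]
)


def _ou_offsets(rng: np.random.Generator, n_frames: int, n_players: int,
                sd_m: float = 2.5, step_sd_m: float = 0.06) -> np.ndarray:
    """Mean-reverting positional noise, stationary SD ≈ sd_m per axis.

    ``step_sd_m`` is the per-frame innovation (0.06 m at 25 Hz ≈ a 1.5 m/s
    RMS wander, a realistic off-ball movement speed); the reversion rate
    follows from the stationary-variance identity σ_w² = σ_s²·θ(2−θ).
    """
    ratio2 = min((step_sd_m / sd_m) ** 2, 1.0)
    theta = 1.0 - np.sqrt(1.0 - ratio2)
    out = np.empty((n_frames, n_players, 2))
    out[0] = rng.normal(0.0, sd_m, (n_players, 2))
    shocks = rng.normal(0.0, step_sd_m, (n_frames - 1, n_players, 2))
    for i in range(1, n_frames):
        out[i] = out[i - 1] * (1 - theta) + shocks[i - 1]
    return out


def _shoelace(points: np.ndarray) -> float:
    """Convex-hull area via Andrew's monotone chain + shoelace (no deps)."""
    pts = points[np.lexsort((points[:, 1], points[:, 0]))]

    def half(iterable):
        chain: list[np.ndarray] = []
        for p in iterable:
            while len(chain) >= 2:
                a, b = chain[-1] - chain[-2], p - chain[-2]
                if a[0] * b[1] - a[1] * b[0] > 0:
                    break
                chain.pop()
            chain.append(p)
        return chain

    hull = half(pts)[:-1] + half(pts[::-1])[:-1]
    if len(hull) < 3:
        return 0.0
    h = np.array(hull)
    x, y = h[:, 0], h[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _possession_clouds(
    rng: np.random.Generator,
    n_frames: int,
    targets: FeatureTargets,
    pitch: PitchSpec,
    eps_target_m2: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Attacker and defender absolute positions for one possession.

    Returns (attackers, defenders) of shape (n_frames, 10, 2) plus the
    deepest-location value scripted for the final frame.
    """
    atk = _FORMATION[None] + _ou_offsets(rng, n_frames, 10, sd_m=2.5)
    dfd = _FORMATION[None] * np.array([0.8, 0.9]) + _ou_offsets(rng, n_frames, 10, sd_m=2.5)
    shift = np.array([8.0, 0.0])  # defenders sit goal-side of the attack

    # slow expansion/contraction of both blocks so the hull "breathes"
    # (area CV ≈ √2·amplitude; 0.12 gives the ~17% seen in match play)
    t = np.arange(n_frames) / 25.0
    for cloud in (atk, dfd):
        period = rng.uniform(8.0, 20.0)
        breathe = 1.0 + 0.12 * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
        cloud *= breathe[:, None, None]

    # 1) anisotropic rescale of the 20-player union toward game length/width
    union = np.concatenate([atk, dfd + shift], axis=1)
    length = union[:, :, 0].max(axis=1) - union[:, :, 0].min(axis=1)
    width = union[:, :, 1].max(axis=1) - union[:, :, 1].min(axis=1)
    scale = np.array([targets.game_length_m / length.mean(),
                      targets.game_width_m / width.mean()])
    atk, dfd, shift = atk * scale, dfd * scale, shift * scale

    # 2) exact isotropic rescale of attacker spread toward this
    #    possession's EPS target
    eps_target = eps_target_m2 if eps_target_m2 is not None else targets.eps_mean_m2
    centroid = atk.mean(axis=1, keepdims=True)
    rel = atk - centroid
    areas = np.array([_shoelace(f) for f in rel[:, :, :]])
    s = np.sqrt(eps_target / areas.mean())
    atk = centroid + rel * s

    # 3) translate both teams so the attack drifts toward the opponents'
    #    goal and the end-frame deepest attacker lands near the target
    deep_draw = float(np.clip(rng.normal(targets.deepest_location_m, 6.0),
                              0.55 * pitch.length_m, pitch.length_m - 2.0))
    end_max_x = atk[-1, :, 0].max()
    x_end = deep_draw - end_max_x
    x_start = x_end - rng.uniform(5.0, 20.0)
    y_mid = pitch.width_m / 2 + rng.normal(0.0, 3.0)
    tpath = np.column_stack(
        [np.linspace(x_start, x_end, n_frames), np.full(n_frames, y_mid)]
    )
    atk = atk + tpath[:, None, :]
    dfd = dfd + shift + tpath[:, None, :]

    lo = np.array([0.5, 0.5])
    hi = np.array([pitch.length_m - 0.5, pitch.width_m - 0.5])
    return np.clip(atk, lo, hi), np.clip(dfd, lo, hi), deep_draw


def _ball_path(
    rng: np.random.Generator,
    attackers: np.ndarray,
    sampling_rate_hz: float,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Dwell-and-pass ball trajectory chasing attacking players.

    Returns the (n_frames, 2) ball track and the (frame, receiver) touch
    list. Dwells keep the ball glued to the holder (plus jitter); passes
    fly straight to the receiver's current position at a jittered speed.
    """
    n_frames, n_players, _ = attackers.shape
    dt = 1.0 / sampling_rate_hz
    ball = np.empty((n_frames, 2))
    holder = int(rng.integers(n_players))
    touches: list[tuple[int, int]] = [(0, holder)]
    ball[0] = attackers[0, holder]
    mode = "dwell"
    dwell_left = int(rng.uniform(0.5, 2.5) * sampling_rate_hz)
    target = holder
    speed = 0.0
    for i in range(1, n_frames):
        if mode == "dwell":
            ball[i] = attackers[i, holder] + rng.normal(0.0, 0.03, 2)
            dwell_left -= 1
            if dwell_left <= 0 and n_frames - i > 10:
                choices = [j for j in range(n_players) if j != holder]
                # weight receivers by lengthwise separation so circulation
                # runs predominantly goal-to-goal, as in match play
                dx = np.abs(attackers[i, choices, 0] - attackers[i, holder, 0])
                dy = np.abs(attackers[i, choices, 1] - attackers[i, holder, 1])
                w = 0.5 + dx**1.5 / (1.0 + dy)
                target = int(rng.choice(choices, p=w / w.sum()))
                speed = float(np.clip(rng.normal(13.0, 3.0), 7.0, 30.0))
                mode = "pass"
        if mode == "pass":
            to = attackers[i, target] - ball[i - 1]
            dist = float(np.hypot(*to))
            step = speed * dt
            if dist <= max(step, 0.5):
                ball[i] = attackers[i, target]
                holder = target
                touches.append((i, holder))
                mode = "dwell"
                dwell_left = int(rng.uniform(0.8, 3.2) * sampling_rate_hz)
            else:
                ball[i] = ball[i - 1] + to / dist * step
    return ball, touches


# ---------------------------------------------------------------------------
# match assembly
# ---------------------------------------------------------------------------


def _roster(teams: tuple[str, str]) -> tuple[PlayerInfo, ...]:
    players: list[PlayerInfo] = []
    for team in teams:
        players.extend(
            PlayerInfo(f"{team}_{k:02d}", team, "outfield") for k in range(1, 11)
        )
        players.append(PlayerInfo(f"{team}_gk", team, "goalkeeper"))
    return tuple(players)


def generate_match(
    scenario: MatchScenario,
) -> tuple[TrackingDataset, EventStream, GroundTruth]:
    """Simulate one match: tracking, events and the ground-truth log.

    Possessions alternate between the two teams; the full frame axis is
    gapless, with short neutral gaps (player/ball interpolation) between
    possessions. Both teams play in a shared corner-origin frame in which
    the possessing team always attacks toward +x for the home team and
    toward −x for the away team (away positions are reflected into its own
    attacking orientation), so downstream attack normalization is
    exercised for one of the two teams.
    """
    rng = np.random.default_rng(scenario.seed)
    teams = tuple(scenario.targets.keys())
    if len(teams) != 2:
        raise UsageError("scenario needs exactly two teams")
    pitch = scenario.pitch
    rate = scenario.sampling_rate_hz
    order = [teams[i % 2] for i in range(2 * scenario.n_possessions_per_team)]

    # per-possession EPS targets: ~12% between-possession spread, recentred
    # multiplicatively so each team's match-level mean sits on the scenario
    # target (the pipeline's pooled estimate then tracks it closely)
    eps_draws: dict[str, list[float]] = {}
    for team in teams:
        draws = scenario.targets[team].eps_mean_m2 * rng.normal(
            1.0, 0.12, scenario.n_possessions_per_team
        ).clip(0.5, 1.5)
        eps_draws[team] = list(draws * scenario.targets[team].eps_mean_m2 / draws.mean())
    pieces: list[dict] = []
    for team in order:
        t = scenario.targets[team]
        if rng.uniform() < scenario.short_fraction:
            dur = rng.uniform(2.0, 7.5)
        else:
            sigma2 = np.log(1 + (t.duration_sd_s / t.duration_mean_s) ** 2)
            mu = np.log(t.duration_mean_s) - sigma2 / 2
            dur = float(np.clip(rng.lognormal(mu, np.sqrt(sigma2)), 8.5, 90.0))
        n_f = max(int(round(dur * rate)), 8)
        atk, dfd, deep = _possession_clouds(
            rng, n_f, t, pitch, eps_target_m2=eps_draws[team].pop(0)
        )
        if team == teams[1]:
            # away team attacks the other goal: reflect its possession
            atk = np.stack([pitch.length_m - atk[..., 0], pitch.width_m - atk[..., 1]], -1)
            dfd = np.stack([pitch.length_m - dfd[..., 0], pitch.width_m - dfd[..., 1]], -1)
        ball, touches = _ball_path(rng, atk, rate)
        pieces.append(
            {
                "team": team, "n_frames": n_f, "atk": atk, "dfd": dfd,
                "ball": ball, "touches": touches, "deep": deep,
                "set_piece": bool(rng.uniform() < scenario.set_piece_prob),
                "shot": bool(rng.uniform() < scenario.shot_prob),
            }
        )

    total = sum(p["n_frames"] for p in pieces) + scenario.gap_frames * (len(pieces) - 1)
    ids = {team: [f"{team}_{k:02d}" for k in range(1, 11)] for team in teams}
    positions = {pid: np.empty((total, 2)) for team in teams for pid in ids[team]}
    for team in teams:
        positions[f"{team}_gk"] = np.empty((total, 2))
    ball_xy = np.empty((total, 2))

    gk_home_x, gk_away_x = 3.0, pitch.length_m - 3.0
    events: list[Event] = []
    gt_rows: list[dict] = []
    cursor = 0
    prev_end_state: dict[str, np.ndarray] | None = None
    for k, piece in enumerate(pieces):
        team = piece["team"]
        other = teams[1] if team == teams[0] else teams[0]
        n_f = piece["n_frames"]
        start, end = cursor, cursor + n_f - 1
        # per-player assignment (attackers → possessing team)
        state_start: dict[str, np.ndarray] = {}
        state_end: dict[str, np.ndarray] = {}
        for j, pid in enumerate(ids[team]):
            positions[pid][start : end + 1] = piece["atk"][:, j]
            state_start[pid], state_end[pid] = piece["atk"][0, j], piece["atk"][-1, j]
        for j, pid in enumerate(ids[other]):
            positions[pid][start : end + 1] = piece["dfd"][:, j]
            state_start[pid], state_end[pid] = piece["dfd"][0, j], piece["dfd"][-1, j]
        for tm, gx in ((teams[0], gk_home_x), (teams[1], gk_away_x)):
            gk = f"{tm}_gk"
            track = np.column_stack(
                [np.full(n_f, gx), pitch.width_m / 2 + 2.0 * np.sin(np.arange(n_f) / 80.0)]
            )
            positions[gk][start : end + 1] = track
            state_start[gk], state_end[gk] = track[0], track[-1]
        ball_xy[start : end + 1] = piece["ball"]

        # fill the gap before this possession by linear interpolation
        if prev_end_state is not None:
            g0, g1 = start - scenario.gap_frames, start - 1
            w = np.linspace(0.0, 1.0, scenario.gap_frames + 2)[1:-1]
            for pid in positions:
                a, b = prev_end_state[pid], state_start[pid]
                positions[pid][g0 : g1 + 1] = a + w[:, None] * (b - a)
            a, b = prev_end_state["ball"], piece["ball"][0]
            ball_xy[g0 : g1 + 1] = a + w[:, None] * (b - a)

        events.append(Event(start, "possession_start", team))
        for fi, j in piece["touches"][1:]:
            events.append(Event(start + fi, "touch", team, ids[team][j]))
        if piece["set_piece"]:
            events.append(Event(int(start + n_f // 2), "set_piece", team))
        end_reason = "lost"
        if piece["shot"]:
            events.append(Event(end, "shot", team))
            end_reason = "ball_out_after_shot"
        events.append(Event(end, "possession_end", team))
        if piece["shot"] and k < len(pieces) - 1:
            events.append(Event(end + scenario.gap_frames // 2, "ball_out", ""))

        dur = n_f / rate
        gt_rows.append(
            {
                "possession_id": k, "team": team,
                "start_frame": start, "end_frame": end,
                "duration_s": dur, "set_piece": piece["set_piece"],
                "end_reason": end_reason,
                "deepest_target_m": piece["deep"],
                "eps_target_m2": scenario.targets[team].eps_mean_m2,
                "included_expected": dur >= 8.0 and not piece["set_piece"],
            }
        )
        prev_end_state = dict(state_end)
        prev_end_state["ball"] = piece["ball"][-1]
        cursor = end + 1 + (scenario.gap_frames if k < len(pieces) - 1 else 0)

    events.sort(key=lambda e: e.frame)
    tracking = TrackingDataset(
        sampling_rate_hz=rate,
        pitch=pitch,
        roster=_roster(teams),
        frame_index=np.arange(total, dtype=np.int64),
        ball_xy=ball_xy,
        positions=positions,
    )
    tracking.validate()
    return tracking, EventStream(tuple(events)), GroundTruth(gt_rows)


# ---------------------------------------------------------------------------
# scripted fixtures (closed-form features)
# ---------------------------------------------------------------------------


def scripted_possession(
    ball_polyline,
    attackers,
    defenders,
    n_frames: int = 250,
    team: str = "home",
    opponent: str = "away",
    pitch: PitchSpec | None = None,
    sampling_rate_hz: float = 25.0,
    allow_short: bool = False,
) -> PossessionSequence:
    """A single possession whose features are closed-form from the inputs.

    Players stay static at the given coordinates (10 outfield per side;
    goalkeepers are added on the goal lines), while the ball traverses the
    polyline at constant speed over ``n_frames`` frames. Ball distance,
    length/width ratio, mean speed, EPS, game bounds, deepest location and
    offensive space all follow directly from the layout.
    """
    pitch = pitch or PitchSpec()
    if n_frames < 200 and not allow_short:
        raise UsageError("scripted possession below 200 frames (pass allow_short=True)")
    poly = np.asarray(ball_polyline, dtype=float)
    atk = np.asarray(attackers, dtype=float)
    dfd = np.asarray(defenders, dtype=float)
    if atk.shape != (10, 2) or dfd.shape != (10, 2):
        raise UsageError("need exactly 10 outfield coordinates per team")
    for pts, what in ((poly, "ball polyline"), (atk, "attackers"), (dfd, "defenders")):
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > pitch.length_m
                or pts[:, 1].min() < 0 or pts[:, 1].max() > pitch.width_m):
            raise UsageError(f"{what} leaves the pitch")

    # arc-length parameterization: equal steps along the polyline
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.linspace(0.0, cum[-1], n_frames)
    ball = np.column_stack(
        [np.interp(s, cum, poly[:, 0]), np.interp(s, cum, poly[:, 1])]
    )

    positions: dict[str, np.ndarray] = {}
    for j in range(10):
        positions[f"{team}_{j + 1:02d}"] = np.tile(atk[j], (n_frames, 1))
        positions[f"{opponent}_{j + 1:02d}"] = np.tile(dfd[j], (n_frames, 1))
    positions[f"{team}_gk"] = np.tile([1.0, pitch.width_m / 2], (n_frames, 1))
    positions[f"{opponent}_gk"] = np.tile(
        [pitch.length_m - 1.0, pitch.width_m / 2], (n_frames, 1)
    )
    tracking = TrackingDataset(
        sampling_rate_hz=sampling_rate_hz,
        pitch=pitch,
        roster=_roster((team, opponent)),
        frame_index=np.arange(n_frames, dtype=np.int64),
        ball_xy=ball,
        positions=positions,
    )
    tracking.validate()
    return PossessionSequence(
        team=team, start_frame=0, end_frame=n_frames - 1, tracking=tracking,
        possession_id=0,
    )


# ---------------------------------------------------------------------------
# tabular generator for the statistical stages
# ---------------------------------------------------------------------------

#: default 5-block latent structure on the 15 features (log scale):
#: ball-speed block, end-of-possession block, space block, tempo block, CV block
_DEFAULT_BLOCKS = (
    ("ball_speed_mean_kmh", "ball_speed_cv_pct", "ball_speed_apen_au"),
    ("deepest_location_m", "offensive_space_m2", "n_opponents_in_space"),
    ("eps_mean_m2", "game_width_mean_m", "game_length_mean_m"),
    ("duration_s", "ball_distance_m", "ball_lw_ratio_au"),
    ("eps_cv_pct", "game_length_cv_pct", "game_width_cv_pct"),
)


def default_factor_structure(loading: float = 0.85) -> pd.DataFrame:
    """15 × 5 latent loading matrix used by the tabular generator."""
    from .features import FEATURE_COLUMNS

    L = pd.DataFrame(
        0.0, index=FEATURE_COLUMNS, columns=[f"F{i + 1}" for i in range(5)]
    )
    for i, block in enumerate(_DEFAULT_BLOCKS):
        for var in block:
            L.loc[var, f"F{i + 1}"] = loading
    return L


#: rough log-scale medians per feature (match-play magnitudes)
_LOG_MEDIANS = {
    "duration_s": np.log(28.0), "ball_distance_m": np.log(170.0),
    "ball_speed_mean_kmh": np.log(22.0), "ball_speed_cv_pct": np.log(95.0),
    "ball_speed_apen_au": np.log(0.33), "ball_lw_ratio_au": np.log(1.7),
    "eps_mean_m2": np.log(950.0), "eps_cv_pct": np.log(18.0),
    "game_length_mean_m": np.log(38.0), "game_length_cv_pct": np.log(11.5),
    "game_width_mean_m": np.log(44.0), "game_width_cv_pct": np.log(11.0),
    "deepest_location_m": np.log(82.0), "offensive_space_m2": np.log(1500.0),
    "n_opponents_in_space": np.log(1.4),
}


def generate_two_group_features(
    effect_sizes: dict[str, float] | None,
    n_per_group: int,
    seed: int,
    context: str = "TOP",
    log_sd: float = 0.35,
    structure: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two-group features table with planted effects and latent structure.

    Each variable is log-normal: on the log scale the rows follow a latent
    factor model ``z = Λ f + √(1 − h²) ε`` (unit variance), scaled by
    ``log_sd`` and shifted by the variable's typical log-median. Group "b"
    (the opponent rows) is shifted by the requested standardized effect
    size per variable. Used to drive sign-recovery, null-calibration and
    PCA structure-recovery tests.
    """
    from .features import FEATURE_COLUMNS

    if n_per_group < 2:
        raise UsageError("n_per_group must be ≥ 2")
    rng = np.random.default_rng(seed)
    effect_sizes = effect_sizes or {}
    L = (structure if structure is not None else default_factor_structure()).to_numpy()
    variables = FEATURE_COLUMNS
    uniq = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 1e-6, None))

    frames = []
    for label, shift_sign in (("team", 0.0), ("opponent", 1.0)):
        f = rng.standard_normal((n_per_group, L.shape[1]))
        eps = rng.standard_normal((n_per_group, len(variables)))
        z = f @ L.T + eps * uniq
        data = {}
        for v, var in enumerate(variables):
            d = effect_sizes.get(var, 0.0) * shift_sign
            data[var] = np.exp(_LOG_MEDIANS[var] + log_sd * (z[:, v] + d))
        df = pd.DataFrame(data)
        df.insert(0, "team", label)
        df.insert(1, "opponent_quality", context)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "possession_id", np.arange(len(out)))
    return out
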