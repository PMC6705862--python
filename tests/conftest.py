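"""Shared fixtures: small synthetic matches, scripted layouts, tiny datasets."""

from __future__ import annotations

import numpy as np
import pytest

from matchspace import (
    FAConfig,
    FeatureTargets,
    MatchEntry,
    MatchScenario,
    PitchSpec,
    PlayerInfo,
    RunConfig,
    TrackingDataset,
    generate_match,
    run_pipeline,
    scripted_possession,
)


def make_dataset(n_frames: int = 2, seed: int = 0, rate: float = 25.0) -> TrackingDataset:
    """A tiny valid dataset: 22 players (incl. 2 GKs) + ball, random positions."""
    rng = np.random.default_rng(seed)
    pitch = PitchSpec()
    roster = []
    positions = {}
    for team, gk_x in (("home", 3.0), ("away", 102.0)):
        for k in range(1, 11):
            pid = f"{team}_{k:02d}"
            roster.append(PlayerInfo(pid, team, "outfield"))
            base = rng.uniform([10, 5], [95, 63])
            positions[pid] = base + rng.normal(0, 0.5, (n_frames, 2))
        gk = f"{team}_gk"
        roster.append(PlayerInfo(gk, team, "goalkeeper"))
        positions[gk] = np.tile([gk_x, 34.0], (n_frames, 1)) + rng.normal(0, 0.1, (n_frames, 2))
    return TrackingDataset(
        sampling_rate_hz=rate,
        pitch=pitch,
        roster=tuple(roster),
        frame_index=np.arange(n_frames, dtype=np.int64),
        ball_xy=rng.uniform([5, 5], [100, 63], (n_frames, 2)),
        positions=positions,
    )


@pytest.fixture(scope="session")
def small_match():
    """One simulated match reused by segmentation / recovery tests."""
    scenario = MatchScenario(seed=11, n_possessions_per_team=12)
    return generate_match(scenario) + (scenario,)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full two-context pipeline run on synthetic matches (TOP and BOTTOM)."""
    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(
        matches=[
            MatchEntry(context="TOP", scenario=MatchScenario(
                seed=101, n_possessions_per_team=40,
                targets={"home": FeatureTargets(eps_mean_m2=985.0),
                         "away": FeatureTargets(eps_mean_m2=909.0)})),
            MatchEntry(context="BOTTOM", scenario=MatchScenario(
                seed=202, n_possessions_per_team=40,
                targets={"home": FeatureTargets(eps_mean_m2=1058.0, game_width_m=47.0),
                         "away": FeatureTargets(eps_mean_m2=864.0, deepest_location_m=77.0)})),
        ],
        out_dir=str(out / "run1"),
        seed=7,
    )
    manifest = run_pipeline(config)
    return manifest, out / "run1", config


@pytest.fixture()
def square_layout():
    """10 attackers: 4 on a 10 × 10 m square, 6 strictly inside."""
    corners = np.array([[40.0, 30.0], [50.0, 30.0], [50.0, 40.0], [40.0, 40.0]])
    inside = np.array(
        [[43.0, 33.0], [46.0, 36.0], [44.0, 37.0], [47.0, 32.0], [42.0, 35.0], [45.0, 34.0]]
    )
    return np.vstack([corners, inside])


@pytest.fixture()
def default_defenders():
    xs = np.linspace(60.0, 90.0, 10)
    return np.column_stack([xs, np.linspace(20.0, 48.0, 10)])


@pytest.fixture()
def l_shaped_possession(square_layout, default_defenders):
    """Ball runs 30 m lengthwise then 15 m widthwise at constant speed.

    301 frames put the corner exactly on a sample (step 0.15 m), so path
    length, speeds and the length/width ratio are exact closed forms.
    """
    poly = [(30.0, 20.0), (60.0, 20.0), (60.0, 35.0)]
    return scripted_possession(poly, square_layout, default_defenders, n_frames=301)
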