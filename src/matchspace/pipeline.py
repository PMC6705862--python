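"""End-to-end orchestration: read → normalize → segment → features →
per-context comparisons → factor analysis, with a reproducible manifest.

A run consumes one or more matches, each labelled with exactly one
opponent-quality context (e.g. TOP / BOTTOM, opponents from the top or
bottom of the league table), either from tracking/event files or from
synthetic scenarios. It writes:

* ``possessions.csv`` — the possession manifest with exclusion bookkeeping;
* ``features.csv`` — one row per included possession, 15 variables;
* ``comparison_<context>.csv`` — the descriptive + MBI + t-test table per
  context (reference team vs its opponents);
* ``factor_<context>_<side>.csv`` — rotated loadings, eigenvalues and
  adequacy statistics per context and side;
* ``manifest.json`` — seed, configuration, counts at every filter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .factor import FAConfig, FactorModel, pca_varimax
from .features import FEATURE_COLUMNS, FeatureConfig, features_table
from .inference import MBIConfig, compare_all, comparison_frame
from .io import UsageError, read_events, read_tracking
from .segmentation import SegmentationConfig, possession_manifest, segment_possessions
from .synthetic import MatchScenario, generate_match

logger = logging.getLogger("matchspace")


@dataclass
class MatchEntry:
    """One match: either file paths or a synthetic scenario, plus a context."""

    context: str
    tracking_path: str | None = None
    events_path: str | None = None
    scenario: MatchScenario | None = None

    def __post_init__(self) -> None:
        if not self.context:
            raise UsageError("every match needs exactly one context label")
        has_files = self.tracking_path is not None and self.events_path is not None
        if has_files == (self.scenario is not None):
            raise UsageError("give either tracking+events paths or a scenario")


@dataclass
class RunConfig:
    matches: list[MatchEntry]
    out_dir: str = "matchspace_out"
    seed: int = 0
    team_label: str = "home"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    mbi: MBIConfig = field(default_factory=MBIConfig)
    fa: FAConfig = field(default_factory=FAConfig)

    def validate(self) -> None:
        if not self.matches:
            raise UsageError("no matches configured")
        for m in self.matches:
            if m.tracking_path is not None and not Path(m.tracking_path).exists():
                raise UsageError(f"missing tracking file {m.tracking_path}")
            if m.events_path is not None and not Path(m.events_path).exists():
                raise UsageError(f"missing events file {m.events_path}")


def _load_match(entry: MatchEntry, seed_offset: int):
    if entry.scenario is not None:
        scen = dataclasses.replace(entry.scenario, seed=entry.scenario.seed + seed_offset)
        tracking, events, _ = generate_match(scen)
        return tracking, events
    return read_tracking(entry.tracking_path), read_events(entry.events_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Any stage failure propagates as an exception after logging the stage
    name (the CLI maps this to a nonzero exit code).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "segmentation"
        manifests, feat_frames = [], []
        for i, entry in enumerate(config.matches):
            tracking, events = _load_match(entry, seed_offset=i)
            seg_cfg = dataclasses.replace(
                config.segmentation, sampling_rate_hz=tracking.sampling_rate_hz
            )
            man = possession_manifest(events, tracking, seg_cfg)
            man.insert(0, "match", i)
            man.insert(1, "context", entry.context)
            manifests.append(man)
            possessions = segment_possessions(events, tracking, seg_cfg)
            logger.info(
                "match %d (%s): %d candidates, %d included",
                i, entry.context, len(man), len(possessions),
            )
            stage = "features"
            ft = features_table(possessions, context=entry.context, config=config.features)
            ft["team"] = np.where(ft["team"] == config.team_label, "team", "opponent")
            ft.insert(0, "match", i)
            feat_frames.append(ft)
            stage = "segmentation"
        manifest_df = pd.concat(manifests, ignore_index=True)
        features_df = pd.concat(feat_frames, ignore_index=True)
        manifest_df.to_csv(out / "possessions.csv", index=False)
        features_df.to_csv(out / "features.csv", index=False)

        stage = "inference"
        rows = compare_all(features_df, grouping="opponent_quality",
                           team_label="team", config=config.mbi)
        group_sizes: dict[str, dict[str, int]] = {}
        for context, sub in comparison_frame(rows).groupby("context"):
            sub.to_csv(out / f"comparison_{context}.csv", index=False)
            group_sizes[context] = {
                "team": int(sub["n_a"].iloc[0]),
                "opponent": int(sub["n_b"].iloc[0]),
            }

        stage = "factor_analysis"
        factor_outputs = []
        for context in sorted(features_df["opponent_quality"].unique()):
            for side in ("team", "opponent"):
                sub = features_df[
                    (features_df["opponent_quality"] == context)
                    & (features_df["team"] == side)
                ]
                model = pca_varimax(sub, config.fa, variables=FEATURE_COLUMNS)
                name = f"factor_{context}_{side}.csv"
                _write_factor_csv(model, out / name)
                clean = lambda v: None if np.isnan(v) else float(v)  # noqa: E731
                factor_outputs.append(
                    {"context": context, "side": side, "file": name,
                     "n_retained": model.n_retained,
                     "cumulative_pct": float(model.cumulative_pct[-1]),
                     "kmo_overall": clean(model.kmo_overall),
                     "bartlett_chi2": clean(model.bartlett_chi2),
                     "bartlett_p": clean(model.bartlett_p)}
                )

        stage = "manifest"
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "team_label": config.team_label,
            "n_matches": len(config.matches),
            "contexts": [m.context for m in config.matches],
            "min_frames": config.segmentation.min_frames,
            "candidates_total": int(len(manifest_df)),
            "included_total": int(manifest_df["included"].sum()),
            "excluded_by_reason": (
                manifest_df.loc[~manifest_df["included"], "exclusion_reason"]
                .value_counts().to_dict()
            ),
            "group_sizes": group_sizes,
            "factor_models": factor_outputs,
        }
        # bookkeeping identity: the manifest total must equal the sum of the
        # per-context group sizes in the comparison tables
        assert manifest["included_total"] == sum(
            n for sizes in group_sizes.values() for n in sizes.values()
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise


def _write_factor_csv(model: FactorModel, path: Path) -> None:
    frame = model.to_frame()
    frame.index.name = "variable"
    extra = pd.DataFrame(
        {
            col: [model.bartlett_chi2 if col == model.loadings.columns[0] else "",
                  model.bartlett_df if col == model.loadings.columns[0] else "",
                  model.bartlett_p if col == model.loadings.columns[0] else "",
                  model.kmo_overall if col == model.loadings.columns[0] else ""]
            for col in frame.columns
        },
        index=["bartlett_chi2", "bartlett_df", "bartlett_p", "kmo_overall"],
    )
    pd.concat([frame, extra]).to_csv(path)
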