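"""Two-group statistics: t-tests, standardized differences, and
magnitude-based inference (MBI).

The comparison of each possession variable between the reference team and
its opponents uses three complementary lenses:

* a null-hypothesis independent t-test (Welch form by default, pooled by
  flag), recomputable from printed mean ± SD and n alone;
* Cohen's d with a noncentral-t confidence interval and the qualitative
  bands trivial < 0.2 ≤ small < 0.6 ≤ moderate < 1.2 ≤ large < 2.0 ≤ very
  large;
* MBI: variables are log-transformed (uniformity of error), the group
  difference is expressed as a percent change with 95% confidence limits,
  and the probabilities that the true difference exceeds ± the smallest
  worthwhile change (SWC = 0.2 × between-subject SD on the log scale) are
  mapped onto a probabilistic vocabulary (most unlikely … most likely).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .features import FEATURE_COLUMNS
from .io import UsageError

logger = logging.getLogger("matchspace")

#: MBI probability band edges (percent) and their vocabulary.
MBI_BAND_EDGES = (0.5, 5.0, 25.0, 75.0, 95.0, 99.0)
MBI_BAND_LABELS = (
    "most unlikely", "very unlikely", "unlikely", "possibly",
    "likely", "very likely", "most likely",
)
#: |d| thresholds for the effect-size vocabulary.
EFFECT_SIZE_EDGES = (0.2, 0.6, 1.2, 2.0)
EFFECT_SIZE_LABELS = ("trivial", "small", "moderate", "large", "very large")


@dataclass
class GroupSummary:
    """Sufficient statistics of one group (raw values optional)."""

    n: int
    mean: float
    sd: float
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise UsageError("group needs n ≥ 2")
        if self.sd < 0:
            raise UsageError("sd must be ≥ 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        x = np.asarray(values, dtype=float).ravel()
        x = x[~np.isnan(x)]
        if len(x) < 2:
            raise UsageError("group needs n ≥ 2 non-missing values")
        return cls(n=len(x), mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)), values=x)


@dataclass
class MBIConfig:
    swc_factor: float = 0.2
    cl_level: float = 0.95
    log_transform: bool = True
    band_edges: tuple[float, ...] = MBI_BAND_EDGES
    band_labels: tuple[str, ...] = MBI_BAND_LABELS
    welch: bool = True  # pooled-variance t when False
    fdr_correction: bool = False  # optional Benjamini–Hochberg on p-values

    def __post_init__(self) -> None:
        edges = self.band_edges
        if any(b <= a for a, b in zip(edges, edges[1:])) or edges[0] <= 0 or edges[-1] >= 100:
            raise UsageError("band edges must be strictly increasing within (0, 100)")


@dataclass
class ComparisonRow:
    """One variable's two-group comparison (descriptives + MBI + t + d)."""

    variable: str
    context: str
    group_a: GroupSummary
    group_b: GroupSummary
    percent_diff: float
    percent_cl: float
    p_lower: float
    p_trivial: float
    p_higher: float
    mbi_label: str
    t_statistic: float
    df: float
    p_value: float
    cohens_d: float
    d_ci: tuple[float, float]
    d_band: str


# ---------------------------------------------------------------------------
# t-test and effect size
# ---------------------------------------------------------------------------


def welch_t(a: GroupSummary, b: GroupSummary, welch: bool = True) -> tuple[float, float, float]:
    """t, df and two-sided p for mean_b − mean_a from summary statistics.

    Welch form by default (Welch–Satterthwaite df); ``welch=False`` gives
    the pooled-variance Student form.
    """
    if a.sd == 0 and b.sd == 0:
        logger.info("t undefined: both groups have zero variance")
        return math.nan, math.nan, math.nan
    res = stats.ttest_ind_from_stats(
        b.mean, b.sd, b.n, a.mean, a.sd, a.n, equal_var=not welch
    )
    if welch:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    else:
        df = a.n + b.n - 2
    return float(res.statistic), float(df), float(res.pvalue)


def _effect_band(d: float) -> str:
    idx = int(np.searchsorted(EFFECT_SIZE_EDGES, abs(d), side="left"))
    return EFFECT_SIZE_LABELS[idx]


def cohens_d(a: GroupSummary, b: GroupSummary, cl_level: float = 0.95
             ) -> tuple[float, tuple[float, float], str]:
    """Standardized difference (mean_b − mean_a) / pooled SD with CI and band.

    The CI inverts the noncentral t distribution of the two-sample t
    statistic (exact under normality), falling back to a normal
    approximation if the inversion fails numerically.
    """
    pooled = math.sqrt(
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    )
    if pooled == 0:
        logger.info("Cohen's d undefined: pooled SD is 0")
        return math.nan, (math.nan, math.nan), "undefined"
    d = (b.mean - a.mean) / pooled
    scale = math.sqrt(1 / a.n + 1 / b.n)
    t_obs = d / scale
    df = a.n + b.n - 2
    alpha = 1 - cl_level

    def _ncp(target_prob: float) -> float:
        f = lambda nc: stats.nct.cdf(t_obs, df, nc) - target_prob  # noqa: E731
        lo, hi = t_obs - 10 - 10 * scale, t_obs + 10 + 10 * scale
        return optimize.brentq(f, lo, hi)

    try:
        ci = (_ncp(1 - alpha / 2) * scale, _ncp(alpha / 2) * scale)
    except ValueError:  # bracket failure on extreme inputs
        se = math.sqrt(scale**2 + d**2 / (2 * df))
        z = stats.norm.ppf(1 - alpha / 2)
        ci = (d - z * se, d + z * se)
    return d, ci, _effect_band(d)


# ---------------------------------------------------------------------------
# magnitude-based inference
# ---------------------------------------------------------------------------


def _band_word(prob_pct: float, config: MBIConfig) -> str:
    return config.band_labels[int(np.searchsorted(config.band_edges, prob_pct, side="right"))]


def mbi_compare(a_values, b_values, config: MBIConfig | None = None) -> dict:
    """MBI fragment for b relative to a: percent difference ± CL,
    probability triplet and the qualitative label.

    With ``log_transform`` on, the difference of log-means back-transforms
    to a percent change and the SWC is 0.2 × the pooled between-subject SD
    of the logs; probabilities come from the t distribution of the
    difference. Label: the band word of the largest of the three
    probabilities suffixed with its direction, or "unclear" when both
    substantial directions exceed 5%.
    """
    config = config or MBIConfig()
    a = np.asarray(a_values, dtype=float).ravel()
    b = np.asarray(b_values, dtype=float).ravel()
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise UsageError("MBI needs n ≥ 2 per group")
    if config.log_transform:
        for name, x in (("a", a), ("b", b)):
            if np.any(x <= 0):
                raise UsageError(
                    f"log transform requires positive values; group {name} violates this"
                )
        la, lb = np.log(a), np.log(b)
    else:
        la, lb = a, b
    sa = GroupSummary.from_values(la)
    sb = GroupSummary.from_values(lb)
    diff = sb.mean - sa.mean
    se = math.sqrt(sa.sd**2 / sa.n + sb.sd**2 / sb.n)
    _, df, _ = welch_t(sa, sb, welch=config.welch)
    if not config.welch:
        df = sa.n + sb.n - 2
    swc = config.swc_factor * math.sqrt(
        ((sa.n - 1) * sa.sd**2 + (sb.n - 1) * sb.sd**2) / (sa.n + sb.n - 2)
    )
    if se == 0:
        p_higher = 1.0 if diff > swc else 0.0
        p_lower = 1.0 if diff < -swc else 0.0
    else:
        p_higher = float(stats.t.sf((swc - diff) / se, df))
        p_lower = float(stats.t.cdf((-swc - diff) / se, df))
    p_trivial = max(1.0 - p_higher - p_lower, 0.0)

    if p_higher > 0.05 and p_lower > 0.05:
        label = "unclear"
    else:
        probs = {"+": p_higher, "trivial": p_trivial, "-": p_lower}
        direction = max(probs, key=probs.get)
        label = f"{_band_word(100 * probs[direction], config)} {direction}"

    t_crit = stats.t.ppf(1 - (1 - config.cl_level) / 2, df)
    if config.log_transform:
        pct = 100.0 * (math.exp(diff) - 1.0)
        cl = 100.0 * (math.exp(t_crit * se) - 1.0)
    else:
        pct, cl = diff, t_crit * se
    probs_sum = p_higher + p_trivial + p_lower
    assert abs(probs_sum - 1.0) < 1e-9
    return {
        "percent_diff": pct,
        "percent_cl": cl,
        "p_lower": p_lower,
        "p_trivial": p_trivial,
        "p_higher": p_higher,
        "mbi_label": label,
        "swc": swc,
    }


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------


def compare_all(
    table: pd.DataFrame,
    grouping: str = "opponent_quality",
    team_label: str = "team",
    config: MBIConfig | None = None,
    variables: list[str] | None = None,
) -> list[ComparisonRow]:
    """One ComparisonRow per feature per opponent-quality context.

    Within each context the reference team's possessions (``team ==
    team_label``) are group a and the opponents' are group b, mirroring the
    descriptive-table layout. Missing values are excluded listwise per
    variable, with counts logged.
    """
    config = config or MBIConfig()
    variables = variables or [c for c in FEATURE_COLUMNS if c in table.columns]
    if grouping not in table.columns or "team" not in table.columns:
        raise UsageError(f"table must carry 'team' and {grouping!r} columns")
    rows: list[ComparisonRow] = []
    pvals: list[float] = []
    for context, sub in table.groupby(grouping, sort=True):
        mask = sub["team"] == team_label
        if mask.all() or not mask.any():
            raise UsageError(f"context {context!r} does not contain two groups")
        for var in variables:
            a = sub.loc[mask, var].to_numpy(dtype=float)
            b = sub.loc[~mask, var].to_numpy(dtype=float)
            n_drop = int(np.isnan(a).sum() + np.isnan(b).sum())
            if n_drop:
                logger.info("%s/%s: %d missing values dropped", context, var, n_drop)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) < 2 or len(b) < 2:
                raise UsageError(f"context {context!r}, variable {var!r}: group n < 2")
            sa, sb = GroupSummary.from_values(a), GroupSummary.from_values(b)
            t, df, p = welch_t(sa, sb, welch=config.welch)
            d, ci, band = cohens_d(sa, sb, config.cl_level)
            cfg_var = config
            if config.log_transform and (np.any(a <= 0) or np.any(b <= 0)):
                # count-like variables with zeros: MBI on the raw scale
                logger.info("%s/%s: non-positive values; MBI without log transform",
                            context, var)
                cfg_var = dataclasses.replace(config, log_transform=False)
            frag = mbi_compare(a, b, cfg_var)
            rows.append(
                ComparisonRow(
                    variable=var, context=str(context), group_a=sa, group_b=sb,
                    percent_diff=frag["percent_diff"], percent_cl=frag["percent_cl"],
                    p_lower=frag["p_lower"], p_trivial=frag["p_trivial"],
                    p_higher=frag["p_higher"], mbi_label=frag["mbi_label"],
                    t_statistic=t, df=df, p_value=p,
                    cohens_d=d, d_ci=ci, d_band=band,
                )
            )
            pvals.append(p)
    if config.fdr_correction and pvals:
        adjusted = stats.false_discovery_control(np.asarray(pvals), method="bh")
        for row, q in zip(rows, adjusted):
            row.p_value = float(q)
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a CSV-ready DataFrame mirroring the report layout."""
    return pd.DataFrame(
        [
            {
                "context": r.context, "variable": r.variable,
                "n_a": r.group_a.n, "mean_a": r.group_a.mean, "sd_a": r.group_a.sd,
                "n_b": r.group_b.n, "mean_b": r.group_b.mean, "sd_b": r.group_b.sd,
                "percent_diff": r.percent_diff, "percent_cl": r.percent_cl,
                "p_lower": r.p_lower, "p_trivial": r.p_trivial, "p_higher": r.p_higher,
                "mbi_label": r.mbi_label,
                "t": r.t_statistic, "df": r.df, "p": r.p_value,
                "cohens_d": r.cohens_d, "d_lo": r.d_ci[0], "d_hi": r.d_ci[1],
                "d_band": r.d_band,
            }
            for r in rows
        ]
    )
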