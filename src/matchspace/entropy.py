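"""Approximate entropy (ApEn) of ball-speed series.

Classic Pincus ApEn: embed the series in m-dimensional template vectors,
count neighbours under the Chebyshev metric within a tolerance r (here
r = r_factor × sample SD, self-matches included), and report
Φ_m − Φ_{m+1}. Low values mean a regular, predictable series; the reported
normalized variant is bounded in [0, 2] arbitrary units.

Because the tolerance scales with the series SD, ApEn is invariant under
affine transforms of the input; the default "normalized" mode (z-scoring
the series first) therefore equals plain ApEn up to floating error and is
asserted to do so. An optional surrogate mode instead expresses ApEn
relative to the mean ApEn of shuffled copies of the series (which destroys
temporal structure while keeping the amplitude distribution), rescaled so
white noise sits near the top of the [0, 2] range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import UsageError

logger = logging.getLogger("matchspace")


@dataclass
class ApEnParams:
    """ApEn inputs: embedding length m, tolerance factor r, length policy.

    ``m=2`` and ``r_factor=0.2`` (0.2 × series SD) are the field-standard
    settings for human-movement series; ``min_length=200`` frames is the
    reliability floor used by the possession inclusion rule. ``shuffles=0``
    selects the z-score normalization mode; ``shuffles>0`` the surrogate
    mode, seeded by ``seed``.
    """

    m: int = 2
    r_factor: float = 0.2
    min_length: int = 200
    shuffles: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise UsageError("embedding length m must be ≥ 1")
        if self.r_factor <= 0:
            raise UsageError("tolerance factor r must be positive")
        if self.min_length <= self.m + 1:
            raise UsageError("min_length must exceed m + 1")


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Mean log fraction of templates within Chebyshev distance r (self-matches in)."""
    n = len(x) - m + 1
    # (n, m) template matrix; pairwise Chebyshev distances via broadcasting
    templ = np.lib.stride_tricks.sliding_window_view(x, m)
    d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
    c = np.count_nonzero(d <= r, axis=1) / n
    return float(np.mean(np.log(c)))


def apen(
    series, params: ApEnParams | None = None, allow_short: bool = False
) -> float:
    """Approximate entropy Φ_m − Φ_{m+1} of a 1-D series.

    Constant series return exactly 0.0 (every template matches every other
    at zero tolerance). Series shorter than ``params.min_length`` are
    rejected unless ``allow_short`` is set.
    """
    params = params or ApEnParams()
    x = np.asarray(series, dtype=float).ravel()
    if len(x) <= params.m + 1:
        raise UsageError(f"series of length {len(x)} too short for m={params.m}")
    if len(x) < params.min_length and not allow_short:
        raise UsageError(
            f"series of length {len(x)} below reliability floor "
            f"{params.min_length}; pass allow_short=True to override"
        )
    sd = float(np.std(x, ddof=1))
    if sd <= 1e-9 * max(abs(float(np.mean(x))), 1.0):
        # constant series (up to floating rounding): all templates match,
        # Φ_m = Φ_{m+1} = 0; the floor keeps rounding noise from being
        # amplified into spurious irregularity
        return 0.0
    r = params.r_factor * sd
    return _phi(x, params.m, r) - _phi(x, params.m + 1, r)


def normalized_apen(
    series, params: ApEnParams | None = None, allow_short: bool = False
) -> float:
    """ApEn normalized for cross-possession comparability, in [0, 2] a.u.

    Default mode (``params.shuffles == 0``): ApEn of the z-scored series.
    Since the tolerance already scales with the SD this equals plain ApEn
    up to floating error, which is asserted; the z-scoring makes the
    amplitude normalization explicit.

    Surrogate mode (``shuffles > 0``): ApEn divided by the mean ApEn of
    ``shuffles`` random permutations of the series, times 2 — a white-noise
    series is statistically unchanged by shuffling, so its value sits near
    2, while strongly regular series fall toward 0. Output clipped to
    [0, 2] with a warning when clipping fires.
    """
    params = params or ApEnParams()
    x = np.asarray(series, dtype=float).ravel()
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    if sd <= 1e-9 * max(abs(float(np.mean(x))) if len(x) else 0.0, 1.0):
        # degenerate/constant series: perfectly regular in both modes
        if len(x) <= params.m + 1:
            raise UsageError("series too short")
        return 0.0
    raw = apen(x, params, allow_short=allow_short)
    if params.shuffles <= 0:
        z = (x - np.mean(x)) / sd
        value = apen(z, params, allow_short=allow_short)
        assert abs(value - raw) < 1e-9, "z-scoring must not change SD-scaled ApEn"
    else:
        rng = np.random.default_rng(params.seed)
        surrogate = np.mean(
            [apen(rng.permutation(x), params, allow_short=allow_short)
             for _ in range(params.shuffles)]
        )
        if surrogate == 0.0:
            logger.warning("surrogate ApEn of 0; returning 0")
            return 0.0
        value = 2.0 * raw / float(surrogate)
    if value < 0.0 or value > 2.0:
        warnings.warn(f"normalized ApEn {value:.4f} clipped into [0, 2]", stacklevel=2)
        value = min(max(value, 0.0), 2.0)
    return float(value)
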