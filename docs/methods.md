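# Methods

## Coordinate model and data contract

All positions are 2-D metres on a corner-origin pitch: x ∈ [0, length_m]
runs goal line to goal line (default 105), y ∈ [0, width_m] touchline to
touchline (default 68). Frames are sampled at a fixed rate (default 25 Hz),
strictly increasing and gapless within a period; every frame carries the
ball and one position per rostered player. The ball may leave the pitch by
up to a configurable margin (10 m). Goalkeepers are carried in the data but
flagged, because every spatial metric here is defined over *outfield*
players only.

Attack direction is normalized per possession so the possessing team
attacks toward increasing x; "deepest location" and "offensive available
space" are only meaningful after this step. Orientation is inferred from
the team's goalkeeper (mean x in the low half ⇒ attacking +x; the outfield
centroid is the fallback when no keeper is rostered). A reflection maps
(x, y) → (length − x, width − y), a 180° rotation about the pitch centre:
an isometry, an involution, and idempotent once oriented.

Missing single-player samples are bridged by linear interpolation when the
gap is ≤ 5 frames (0.2 s) — routine for optical tracking dropouts — and
left missing otherwise; a possession containing an unbridged gap is
rejected rather than spliced.

## Possession segmentation

A possession starts at a player's first action on the ball and ends when
the ball is lost, or — for possessions ending in a shot after which the
ball leaves the pitch — at the shot frame itself, so end-of-possession
metrics describe the moment of the shot, not the dead ball. Inclusion
requires ≥ `min_frames` = round(8 s × rate) = 200 frames and no set piece
anywhere in the span (whole-sequence exclusion: a restart changes the
game context, so trimming around it would mix regimes). Every candidate is
written to a manifest with its exclusion reason, because group-size
bookkeeping is part of the analysis contract.

When only positions are available, a clearly flagged heuristic infers
possession events: a team gains the ball once one of its players is
nearest to it within 1.5 m for ≥ 5 consecutive frames, and loses it when
the other team achieves the same or the ball stays out of bounds beyond
the hysteresis window. This stand-in is deterministic but not a substitute
for annotated events; the event-driven path is authoritative.

## The fifteen variables

Per included possession (units in brackets): duration [s]; ball distance
[m] (summed frame displacements); ball speed [km/h] (displacement × rate ×
3.6, per transition; mean reported; an optional odd-window centred moving
average exists but defaults off so CV% and entropy act on raw kinematics);
ball speed CV [%]; ball speed regularity [a.u.] (normalized ApEn of the
speed series); length/width ratio [a.u.] = Σ|Δx| / Σ|Δy| of the ball path
— cumulative rather than net displacement, so closed paths stay defined
and the measure reflects circulation direction; EPS mean and CV [m², %]
(convex-hull area of the in-possession team's ten outfield players, per
frame); game length / width mean and CV [m, %] (x/y extents over all 20
outfield players); deepest location [m] (max attacker x at the end frame);
offensive available space [m²] = (length_m − deepest) × width_m, a
full-width rectangle to the goal line — a deliberate, documented
approximation of the "space left in front" that makes the variable an
exact linear complement of deepest location; and the number of opposing
outfield players strictly beyond the deepest attacker (goalkeeper
excluded).

Undefined ratios (zero denominators: a ball that never moves across the
width, a zero-mean series) become NaN, are logged, and are excluded
listwise downstream — never raised as errors mid-pipeline.

## Approximate entropy

Classic Pincus ApEn with self-matches: Φ_m(r) is the mean over i of
log(C_i), C_i the fraction of length-m templates within Chebyshev distance
r = 0.2 × sample SD; ApEn = Φ_m − Φ_{m+1}, m = 2. A constant series gives
exactly 0; series whose SD is below 1e−9 of their scale are treated as
constant so floating rounding cannot masquerade as irregularity. Series
shorter than 200 samples are refused unless explicitly overridden (tests
use 120-sample series with the override).

Because r scales with the SD, ApEn is invariant under affine transforms of
the series. "Normalized" ApEn therefore has two modes: the default
z-scores the series first (equal to raw ApEn up to floating error —
asserted — but makes the amplitude normalization explicit), and a
surrogate mode (`shuffles` > 0, seeded, default 20 when enabled) divides
by the mean ApEn of shuffled copies and rescales by 2, placing white noise
near the top of the [0, 2] contract range and strongly periodic signals
near 0. Outputs are clipped into [0, 2] with a warning; the default mode's
observed values sit comfortably inside the range. The z-score mode is the
one used by the feature pipeline.

ApEn saturates once noise dominates structure, so monotonicity checks
(sine + noise) are run on amplitudes below the plateau.

## Two-group statistics

Welch is the default t-test (Welch–Satterthwaite df), computable from
n/mean/SD alone; the pooled-variance form is a flag. Cohen's d uses the
pooled SD, bands at |d| = 0.2/0.6/1.2/2.0, and a CI from inverting the
noncentral t distribution (normal approximation as a numerical fallback).

MBI: variables are log-transformed (possession metrics are positive and
right-skewed, and log scaling uniformizes error), the group difference of
log-means is back-transformed to a percent difference with symmetric 95%
confidence limits, and SWC = 0.2 × pooled log-scale SD. The probabilities
that the true difference exceeds +SWC, lies within ±SWC, or falls below
−SWC come from the t distribution of the difference; the label is the
band word (most unlikely <0.5%, very unlikely 0.5–5%, unlikely 5–25%,
possibly 25–75%, likely 75–95%, very likely 95–99%, most likely >99%) of
the largest probability suffixed with its direction, or "unclear" when
both substantial directions exceed 5%. Count-like variables containing
zeros (opponents in the offensive space) fall back to raw-scale MBI for
that variable, logged. No multiplicity correction is applied by default
(a Benjamini–Hochberg flag exists).

## Factor analysis

Correlation-matrix PCA on complete-case rows (listwise deletion, counts
logged). Retention is eigenvalue-strict (> 1.0) with a warning when the
retained components explain < 60% cumulative variance — the two published
rules can disagree, and the eigenvalue rule is given precedence. Loadings
are eigenvectors × √eigenvalue; varimax uses Kaiser row normalization and
the classical pairwise closed-form rotation angle, swept until a full
cycle moves < 1e−8 radians (the popular SVD-update iteration stalls on
two-component problems with 45° starts, which is exactly the planted-
structure test case). Presentation is deterministic: components ordered by
rotated variance, largest-|loading| entry made positive. Rotation is
orthogonal, so per-variable communalities are preserved (checked to
1e−8).

Because offensive available space is an exact linear complement of deepest
location, each side's 15-variable correlation matrix is singular by
construction; Bartlett's χ² (−(n−1−(2p+5)/6)·ln det R) and KMO (raw vs
anti-image partial correlations) are then undefined and reported as NaN
with a warning, while the PCA itself proceeds on the eigenspectrum. The
standalone `bartlett_sphericity` / `kmo` operations remain strict and
raise on singular input.

## Synthetic match generator

The generator reproduces the *measured* statistical structure of elite
possessions, not tactics. Defaults emulate the study conditions: 25 Hz,
105 × 68 m, 10 outfield + keeper per side, possession durations log-normal
(mean 29 s, SD 18 s) with a 20% share drawn below the 8 s floor, 10%
set-piece and 15% shot-ending probabilities, and per-team feature targets
at match-play scales (EPS 985 vs 909 m², game length 38 m, width 44 m,
deepest location 83 m).

Players are mean-reverting (OU) clouds around a 4-4-2-ish anchor formation
(stationary spread 2.5 m per axis, 0.06 m per-frame innovation ≈ 1.5 m/s
wander), with a slow sinusoidal expansion/contraction (amplitude 0.12,
period 8–20 s) so the hull "breathes" at realistic CV. Calibration per
possession: (1) anisotropic rescale of the 20-player union toward the game
length/width targets; (2) exact isotropic rescale of the attacker offsets
toward that possession's EPS target — targets are drawn with 12%
between-possession spread and recentred so the match-level mean equals the
scenario target; (3) a linear translation of both teams so the end-frame
deepest attacker lands on a draw centred on the deepest-location target.
The ball alternates dwells at the holder (0.8–3.2 s, 3 cm jitter) with
straight passes at N(13, 3) m/s to receivers chosen with lengthwise-
weighted probability; this produces mean speeds near 25 km/h, speed CVs
near 70–75% and a clear dwell/pass entropy gradient. Everything is driven
by one seeded generator, so identical seeds give bit-identical matches.

What the generator does *not* emulate: pressing and tactical interaction,
player roles beyond the anchor grid, ball flight height, measurement
noise, or the full between-possession variance of real data (its speed CV
and ApEn levels sit somewhat below and above published match values,
respectively). Tests passing on synthetic data therefore validate the
*computational* contract — segmentation bookkeeping, geometry, entropy,
statistics — not ecological validity of any coaching interpretation.

The tabular generator (`generate_two_group_features`) drives the
statistical stages directly: log-normal variables with a planted 5-block
latent structure (loading 0.85) mirroring the empirical variable blocks,
optional standardized mean shifts per variable, and seeded determinism.

## Problem sizes and numerical choices in the test suite

Simulated matches in tests use 12–40 possessions per team per context —
enough for stable group comparisons and ≥ variables + 1 complete rows per
factor model — and the acceptance properties use 1,000 random frames for
the hull oracle, 50 length-120 series for the entropy oracle, n = 2,000
for rotation recovery, n = 10,000 per group for the MBI null, and 200
permutation replicates for the type-I check. Tolerances: hull vs oracle
1e−6 m²; ApEn vs oracle 1e−9; communalities 1e−8; published t values
±0.02 (printed inputs are rounded to 2 decimals); EPS calibration within
3% of target. Scripted fixtures place polyline corners on sample points
(301 frames for the 45 m L-path) so closed forms are exact.

## Known limitations

* The offensive-available-space rectangle is one of several defensible
  geometries; published means for that variable differ from the
  rectangle's value at the printed deepest-location mean, so cross-study
  comparisons should check definitions.
* The surrogate-normalization mode of ApEn is one reading of "normalized";
  the z-score mode is the default and the two are reported explicitly.
* The positional possession heuristic has no notion of duels, deflections
  or aerial balls; treat its output as provisional annotation.
* MBI is reported because it is the field's convention; the same tables
  carry Welch t, p and Cohen's d with CIs so users can rely on either
  framework.
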