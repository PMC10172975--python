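# Methods

This note documents the models, numerical choices, and defaults behind the
`dfi` package: a Digital Frailty Index (DFI) computed from home-cage video
annotations, benchmarked against a manual frailty index (MFI) and
chronological age.

## The frailty model

A frailty index is an average of deficit scores, each in [0, 1], across a
panel of health-related traits; higher means frailer. The MFI consumed
here is the 29-item clinical panel scored 0 / 0.5 / 1 per item by a human
rater, averaged. The DFI mirrors that structure with eight video-derived
measurements spanning four functional arenas:

| component | arena | units | deficit direction |
|---|---|---|---|
| wheel_distance | physical capability | m/day | low |
| wheel_gait_speed | physical capability | m/s | low |
| floor_gait_speed | physical capability | cm/s | low |
| wheel_circadian | circadian rhythm | dark-phase fraction | low |
| floor_circadian | circadian rhythm | dark-phase fraction | low |
| weight_change | body condition | g/day | loss (negative slope) |
| coat_roughness | body condition | gradient intensity | high |
| nest_movement | environmental engagement | cm/h | low |

Each raw measurement v is parameterized by a threshold-linear map anchored
at a healthy value v0 (score 0) and a frail value v1 (score 1):

    score = clamp((v - v0) / (v1 - v0), 0, 1)

The ordering of (v0, v1) encodes the deficit direction. The DFI is the
unweighted mean of the eight scores; an *optimized* DFI averages a named
five-component subset (default: the three gait/wheel components plus the
two circadian components, the arenas that correlate best with the
benchmarks); a *combined* FI averages a paired MFI and DFI value.

Missing-component policy: the default is strict (all eight present,
matching the mean-of-8 definition); a lenient mode averages the present
components when at least `min_components` are available, recording the
absentees.

### Threshold anchors

The study that motivates this package set its thresholds ad hoc on
age-stratified training cohorts whose values are not public. The shipped
defaults are therefore **simulator-calibrated placeholders**: each anchor
is the mean raw measurement of the simulator's healthy (latent 0) or frail
(latent 1) endpoint phenotype over six seeded two-day runs. Real
deployments must recalibrate on their own reference animals via the config
file.

## Measurement definitions

**Wheel decoding.** The wheel carries one stripe; a classifier emits
per-frame P(stripe at top). A two-state hidden Markov model with symmetric
self-transition probability `p_stay` (default 0.98) and emission
likelihoods P(obs|top)=p_top, P(obs|bottom)=1−p_top is decoded with the
Viterbi algorithm in log space (exact with certain emissions; safe for
millions of frames). Ties break toward remaining in the current state.
Each bottom→top transition is one revolution; direction is not observable
from a single stripe.

- distance/day = rotations × circumference / full days.
- wheel gait speed = the 90th percentile of per-rotation speeds
  (circumference / inter-event interval) within running bouts. The bout
  gap default is 15 s, matched to the simulator's marker dynamics (see
  below); with real 24 fps footage and ~1 s rotations a ~2 s gap is the
  natural choice.
- circadian = dark-phase fraction of rotation events, reported only when
  the period holds more than 10 rotations (otherwise missing:
  "insufficient activity").

**Floor tracking.** Centroid samples below the confidence floor (0.5) are
dropped; the track splits at gaps > 2 s or jumps > 20 cm/frame. Steps
shorter than `min_step_cm` (default 0.2 cm) count as zero distance —
sub-pixel tracker jitter otherwise accumulates into hundreds of cm/h of
phantom travel. Floor gait speed tiles each segment with 1 s windows
(in-window path length / window length) and reports the 90th percentile of
windows above 0.5 cm/s; the "sliding" window is implemented as this
non-overlapping tiling because it is deterministic and exactly
re-derivable by an independent oracle. Floor circadian applies the wheel
circadian definition to hourly binned distance, with a 10 cm minimum.

**Body weight.** Per-minute weight estimates carry confidence weights from
the upstream error-detection models (an input contract here). The trend is
the slope of the closed-form weighted least-squares line with time in days
as the independent variable, in g/day; degenerate fits (all weights zero,
no time spread) propagate as missing.

**Coat.** Per-frame roughness is the mean Sobel gradient magnitude
sqrt(Gx²+Gy²) over the masked mouse, excluding the 1-pixel image border so
every contributing pixel has a complete 3×3 neighborhood (no padding
dialect). The period summary is the median over frames, requiring ≥ 100
samples. High roughness is scored as frail.

**Nest.** The nest-mask centroid's mean speed over consecutive valid
samples (area > 100 px, gaps ≤ 2 h), in cm/h; low movement is scored as
frail (reduced nest redistribution). Cadence default is one sample per
10 min.

## Measurement periods and benchmarking

Occupancy records (which mouse, which cage position, when) define
episodes; coverage dropouts under 60 s are bridged. A "full day" is a
local calendar day (configurable UTC offset) completely covered by
recording; incomplete edge days are excluded. Two modes:

- `jdo`: one period per episode of min(full days, 6), discarded below 2
  full days; the measurement date is the first full day.
- `consecutive`: up to three abutting 6-day (144 h) periods from the first
  full day.

DFI records pair with the same mouse's closest-dated MFI; pairs are kept
only when strictly fewer than 8 whole days apart, with equidistant ties
resolved to the earlier MFI. Regressions use ordinary least squares with
Pearson R and the two-sided p value from the t statistic (n−2 df). For
age-normalized comparison, MFI and DFI are each regressed on age over the
paired subset and the MFI residuals are correlated against the DFI
residuals. Trait-correlation matrices use pairwise-complete Pearson
correlation (≥ 3 pairs), excluding MFI items observed non-zero five or
fewer times; hierarchical clustering is WPGMA (weighted average linkage)
on distances d = 1 − R (the transform is configurable to 1 − |R|, since
correlation-as-similarity admits both readings).

## The synthetic cage

The simulator emulates the *statistical structure* of the annotation
channels, not video. Per mouse:

- **Wheel**: running bouts initiate as a piecewise-constant-rate Poisson
  process (dark vs light rates; thinning), each holding a geometric
  (mean 20) number of rotations at the phenotype's in-bout speed with
  log-normal (σ = 0.15) interval jitter. The marker enters "top" at each
  rotation for min(half the gap, 2.5 s); frames sample that state and flip
  with probability 0.1, emitting p_top 0.9/0.1.
- **Track**: rest/move alternation (move bouts mean 10 s, phase-dependent
  initiation rates) with a heading random walk at the phenotype's speed,
  reflected inside a 40 × 20 cm floor, plus 0.9 px Gaussian jitter, a
  confidence stream, and occasional low-confidence bursts.
- **Weight**: linear trajectory + 1.5 g Gaussian estimate noise at 1/min,
  confidence weights uniform with 5 % exact zeros.
- **Coat / nest**: stationary Gaussian roughness; nest centroid random
  walk at the phenotype's cm/h rate with 3 % area dropouts.

A latent frailty value in [0, 1] linearly interpolates all phenotype
fields between a healthy and a frail endpoint (e.g. dark-phase wheel rate
300 → 30 rot/h; floor speed 8 → 2 cm/s; weight slope 0 → −0.5 g/day; coat
roughness 10 → 20; nest speed 5 → 0.5 cm/h). Cohorts draw ages uniformly,
set latent = clip(0.1 + 0.8·effect·age_norm + N(0, 0.15)), and simulate
MFI items as Bernoulli deficits whose probability increases with the same
latent (values 0.5 or 1 when present) — giving MFI and DFI a shared
non-age frailty component, the structure needed to test age-normalized
residual correlation. All randomness descends from one seed
(`numpy.random.SeedSequence` spawning per-mouse streams); equal seeds give
byte-identical outputs.

### Deliberate departures from real data

- **Frame rates**: 4 Hz wheel-emission and 2 Hz track channels (real
  systems run ~24 fps) keep channels small. Consequently the simulated
  in-bout rotation period is 5 s (healthy) to 10 s (frail) — slowed so
  each marker phase spans several frames at 4 Hz, which is what the real
  24 fps system achieves at realistic ~1 s rotations. The wheel bout-gap
  default (15 s) matches these dynamics. All downstream code is
  rate-agnostic.
- Rotations within 1 s of a period edge, or closer than 0.8 s to their
  predecessor (overlapping bouts), are merged/trimmed in the ground truth:
  no frame could sample their marker phases at 4 Hz.
- The phenotype adds two fields beyond the obvious behavioral rates:
  `wheel_speed_m_s` (a pure Poisson rotation stream has no in-bout speed
  structure, so wheel gait speed needs an explicit speed parameter) and
  separate dark/light floor bout rates (a single rate would leave the
  floor circadian fraction without a frailty effect).
- Not modeled: group housing, perspective distortion, weather/handling
  disturbances, non-stationary behavior within a period, and coat or
  grimace image content (coat roughness is simulated at the measurement
  level, with the Sobel operator tested separately on raster fixtures).

Passing tests therefore demonstrate that the *pipeline machinery* is
correct and that the scoring recovers known ground truth under this noise
model; they do not validate the thresholds or effect sizes against real
mice.

## Problem sizes and numerics

- Simulated cohorts use two-day periods (the minimum eligible window):
  60 mice for effect-recovery and residual-correlation checks, and
  30 mice × 50 seeds for the null (zero age effect) calibration of the
  DFI~age regression.
- Viterbi runs in log space; certain emissions (p ∈ {0, 1}) produce −inf
  log-likelihoods handled exactly. An optional numba-jitted kernel
  accelerates long streams; a pure-Python fallback is complete.
- Percentiles use linear interpolation (numpy default). The weighted
  least-squares solution is the closed form on centered sums, which is
  numerically stable at these scales and matched to a normal-equations
  oracle at 1e-9 relative in tests.
- WPGMA heights follow scipy's `linkage(method="weighted")`; merge
  indices follow scipy's convention (leaves 0..n−1 in input column order,
  internal nodes continuing upward).
- File timestamps are ISO-8601 UTC at microsecond precision; channel
  round-trips preserve values to that precision.

## Known limitations

- Threshold defaults encode the simulator, not any animal population.
- Wheel rotation direction is unobservable from one stripe; counter-
  rotation counts as running.
- The Sobel roughness is sensitive to illumination texture in real
  footage (IR night vs RGB day); no normalization beyond grayscale is
  applied here.
- The pairing rule keeps at most one MFI per DFI record; an MFI may pair
  with several DFI records, as in the source study design.
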