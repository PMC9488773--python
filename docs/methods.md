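# Methods

## Detection model

Each session is an ordered stack of 8-bit grey frames at 300 × 400 pixels
(height × width). Colour inputs are converted to luminance with ITU-R
BT.601 weights (0.299 R + 0.587 G + 0.114 B) *before* resizing; the resize
is an area-averaging (local-mean) interpolation, chosen because it is
deterministic, anti-aliased, and idempotent on an already-standard frame.
Values are rounded and clipped to [0, 255] and stored as integers — a
deliberate choice, see *Numerical choices*.

The background at index `i` is the pixel-wise mean of the frames in the
centred window `[i − ⌊w/2⌋, i + ⌈w/2⌉ − 1]` (default `w = 50`, ≈ 25 min of
wall time at the nominal 30-s interval), truncated — never padded — at the
sequence edges, and *including* frame `i` itself. Window width trades
responsiveness against self-contamination: it must be long relative to a
typical animal crossing (a few frames) so the visitor never becomes its own
background, and short relative to illumination changes.

A pixel is *changed* when its absolute grey-level difference from the
background strictly exceeds 70 (of 255). The absolute value makes the
comparison symmetric in sign, so animals darker or brighter than the tile
are detected alike. The changed-pixel proportion per frame is then screened
adaptively: frame `i` is selected for review when its proportion strictly
exceeds `μ_i + k·σ_i`, with `μ` and `σ` the rolling mean and *population*
standard deviation of the proportion over a window of the same shape
(default 50 frames) and `k = 2` by default. Strict inequalities mean a
constant trace (σ = 0) selects nothing. `calibrate_multiplier` supports
choosing `k` from sessions with known event frames, reporting recall
(ground-truth frames within ±1 index of a selection) against review load
and keeping the largest `k` with full recall.

**Self-inclusion bias.** Because frame `i` contributes 1/m of its own
background (m = effective window size), a single-frame intruder of contrast
`c` produces a pixel difference of `c·(m−1)/m`, not `c`. The effective
single-frame contrast cutoff is therefore `70·m/(m−1)` ≈ 71.4 interior and
≈ 72.9 in the most truncated edge window (m = 25). Contrasts in
(70, ≈73] are thus undetectable for one-frame visits by construction; the
guaranteed-detection tests use contrasts ≥ 75. Multi-frame visits shorter
than ~half the window are barely affected. The alternative — excluding
frame `i` from its own window — removes the bias but was rejected to keep
the background a plain rolling mean.

**Guaranteed detection.** For a single spike `p > 0` in an otherwise-zero
window of m frames, `μ + 2σ = p(1 + 2√(m−1))/m < p` whenever m ≥ 11, so an
isolated intrusion whose contrast clears the (effective) pixel cutoff and
covers any nonzero area is always selected at `k = 2` on a static
background. Flash failures (globally dark frames) are not special-cased:
they legitimately trigger selection and are resolved at review.

## Event analysis

Annotations carry one row per (session, frame, species): species label
(empty when only the weevil count is being recorded), a feeding flag, and
the number of weevils still visible (0–2). Appearances are maximal runs of
consecutive annotated indices per species; any gap splits. Each unit drop
of the visible-weevil count between consecutive annotated frames is one
predation event at the later frame; a drop of two yields two events at the
same index. An increase is rejected as an annotation error (tethered prey
cannot reappear).

Attribution is symmetric: a species qualifies if one of its appearances
overlaps ±4 frames (2 min) around the disappearance. The window is applied
on both sides because predators may linger before or after a take. A
feeding observation at the disappearance frame overrides frame distance;
an exact distance tie between two species raises an error that lists the
candidates, forcing the same manual adjudication the field workflow uses.
Unattributed events get the predator label `"unseen"`.

Predation frequency uses each appearance as one "individual": identity
across non-consecutive appearances is unknowable from annotations, so the
denominator slightly overcounts individuals that re-entered the view. This
is an acknowledged approximation, not a bug.

**Percentage convention.** Printed shares are *truncated* (floored) at one
decimal place (55/82 → 67.0 %, 18/82 → 21.9 %, 59/82 → 71.9 %), matching
the reporting convention of the study whose tallies the acceptance checks
reproduce. Note one internal inconsistency in that convention: 4/82 =
4.878 % floors to 4.8 %, whereas the study prints 4.9 %; the floored value
is what this package reports.

## Hour-of-day model

Per-hour event counts (24 bins, floor of the local clock hour; camera-local
time, no timezone conversion) are fit with a log-link Poisson GLM on
first-order circular harmonics: `log λ(h) = b₀ + b_s sin(2πh/24) +
b_c cos(2πh/24)`. Harmonics were chosen over a 24-level hour factor, which
would be saturated on 24 bins, and over a linear hour term, which cannot
represent the midnight wrap. The fit reports the activity amplitude
`A = √(b_s² + b_c²)` (delta-method standard error), the peak hour
`(24/2π)·atan2(b_s, b_c) mod 24`, and a 2-df likelihood-ratio p-value
against the intercept-only model. With n ≈ 200 events the amplitude
estimator is unbiased well within its SE and the LRT holds its nominal 5 %
size (measured 4–6 % over 1 000 uniform-hour replicates). All events in a
single hour make the harmonic fit effectively separated; it is returned
flagged non-converged with a warning rather than an error.

## Synthetic data

The generator emulates the field setup — a fixed overhead camera on a
light-grey ceramic tile with two tethered weevils, one frame per 30 s for
24 h starting at 16:00 — at whatever frame count is requested (`n_frames`
frames always span 24 h, so reduced sequences keep the diurnal geometry).
Scene defaults: background level 150 grey, frozen per-pixel grain ±10 grey
(the tile's rough texture), one-cycle sinusoidal illumination drift of
amplitude 5 grey, flash-failure probability 0.002/frame (a failed flash
multiplies intensities by 0.2), per-frame Gaussian sensor noise SD 2 grey.
Animals are flat elliptical blobs (2:1 aspect) darker than the tile by a
configurable contrast; weevils are two ~40-pixel dark marks that vanish
from the take frame onward. Blobs are deliberately not textured or moving
within a visit: they exercise every branch of the detection math (size,
contrast, duration, edge windows, overlap) without claiming photorealism.
Consequently, passing tests demonstrate correctness of the *computation*,
not detector performance on real imagery with shadows, rain, vegetation
motion or animals resembling the background.

The study scenario draws per-species visit counts per session from Poisson
rates (shrew 2.0, mouse 0.5, lizard 0.5, toad 0.2 crossings/session),
visit hours from per-species 24-bin intensities `exp(1.5·cos(2π(h−h₀)/24))`
with nocturnal peaks for shrew (22 h), mouse (1 h) and toad (23 h) and a
diurnal peak for the lizard (13 h); visits take a weevil with probability
0.175 while any remain (both at once with probability 0.35 given both
remain), and off-camera "unseen" takes arrive at 0.085/session. The take
and unseen rates were calibrated by simulation so a full 125-session study
yields ≈ 82 predation events in expectation (measured 82.6 ± 0.9 over 100
studies), the scale of the field data the summary statistics are designed
for. Visits are kept ≥ 5 frames apart so synthetic studies never produce
attribution ties, which would (correctly) halt the unattended pipeline.

All randomness descends from one seed via `numpy.random.SeedSequence`
spawning, one child stream per session; any session can be re-rendered
independently and bit-identically.

## Numerical choices

* Frames are 8-bit integers and all window sums are accumulated in int64.
  Integer sums are order-independent, so the incremental rolling
  implementation is *bit-exactly* equal to brute-force per-index
  recomputation — the equivalence tests assert `array_equal`, not
  `allclose`.
* The changed-pixel test is evaluated in integers as
  `|S − m·p_i| > 70·m` (S the window sum), which is algebraically equal to
  `|S/m − p_i| > 70` and cannot disagree with the float form: achievable
  differences are spaced 1/m apart, ~12 orders of magnitude above float64
  rounding at this scale.
* Rolling σ uses the population formula from exact integer moment sums,
  `σ = √(S₂/m − (S₁/m)²)/N`, clipped at 0 against rounding; a width-1
  window gives σ = 0.
* Percentages are computed with decimal arithmetic (no binary-float
  rounding surprises) and floored at one decimal.
* Timestamp precedence is EXIF DateTimeOriginal, then the manifest CSV,
  then an error; file modification times are never used. Corrupt frames
  are skipped with a logged warning and indices reassigned contiguously.

## Problem sizes

The shipped analyses and tests run on reduced studies: 8 sessions of 600
frames (the full diurnal span at a 144-s interval) for end-to-end round
trips, sequences ≤ 300 frames for the brute-force equivalence checks, 200
events for GLM recovery and 1 000 replicates for its calibration — sizes
chosen to exercise every code path at full strength while keeping a
complete run on a laptop in minutes. The detector itself streams one
session at a time and handles full 2 880-frame sessions without
modification.

## Known limitations

* Species identification is entirely external; the package never infers
  identity from pixels, by design.
* The 4-frame attribution window cannot distinguish a predator from a
  scavenger arriving just after an unseen take; the feeding flag is the
  only counter-evidence.
* Appearance-level "individuals" overcount true individuals that re-enter
  the view (see above); predation frequencies are correspondingly
  conservative.
* The detector's μ+2σ rule adapts to slow drift but a step change in
  illumination (sunrise without flash) produces a burst of selections;
  these cost review time, not correctness.
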