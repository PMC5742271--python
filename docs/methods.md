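# Methods

This note records the model, the conventions, the defaults and the design
choices behind `dyadrec`, and what its synthetic benchmarks do and do not
establish about real recordings.

## Input model and trajectory repair

The unit of input is one tracked feature's bounding-box trajectory: frames
0…N−1 at a fixed sampling rate (default 25 frames/s), each frame carrying a
top-left corner (x, y), a size (w, h) in pixels and a validity flag.  Pixel
coordinates follow the image convention (origin top-left, y increasing
downward); all downstream geometry uses box centers (x + w/2, y + h/2).

Tracker quality is scored as the percentage of valid frames *before* any
repair.  Invalid frames are repaired by linear interpolation of the center
and size between the nearest valid frames on each side, which encodes the
assumption that the feature moved linearly while unobserved — a reasonable
approximation for the smooth object sweeps this pipeline targets, a poor
one for saccadic motion across long gaps.  Gaps touching the first or last
frame have no bracketing sample on one side; they are filled by
nearest-valid constant extrapolation with a warning.  Interpolated
coordinates are not rounded to integer pixels.  Interpolation is
idempotent, and repaired trajectories are fully valid by construction.

## Movement categorization

Each frame transition is coded from the sign of its displacement
components with a per-axis dead-zone `eps` (default 0): a component of
magnitude ≤ eps counts as no movement on that axis.  The simple system
uses only the horizontal component (0 none / 1 right / 2 left); the
detailed system maps the sign pair to the 8 compass codes plus 0, with
"up" meaning decreasing y.  Boundaries are deliberately sign-based rather
than angular sectors: sign logic is exactly reproducible and matches how
quantized tracker output behaves.  The simple code is a deterministic
projection of the detailed code ({4,5,6}→1, {1,2,8}→2, {0,3,7}→0).  An
optional horizontal mirror (left↔right code swap) is available for
mirrored-camera geometries and is applied explicitly to one series rather
than silently.

`eps = 0` treats any nonzero displacement as movement, which is right for
integer-quantized trackers; for sub-pixel trackers a small eps suppresses
jitter, and raising eps can only grow the no-movement count (monotone
dead-zone).

## Cross-recurrence and the lag profile

Two equal-length categorical series recur where their codes match.  The
recurrence plot puts the parent on the horizontal axis and the infant on
the vertical axis.  The lag profile is

RR(τ) = 100/(N−|τ|) · Σ_t 1[p(t) = f(t−τ)],  τ = −L…L,

so a parent lead of Δ frames peaks at τ = −Δ (negative = parent-leading).
Choices worth stating:

- **Per-diagonal normalization** by N−|τ| rather than a global constant,
  so recurrence rates remain comparable at large |τ| where the overlap
  shrinks.  Exposed as the `n_overlap` field for sensitivity checks.
- **Exact equality contract**: rr is always computed as `100·count/n`, so
  the production O(N·L) shifted-comparison path, the matrix-diagonal path
  and a brute-force double loop agree bitwise, not approximately.
- **Trimming**: unequal series are trimmed at the tail to the shorter
  length, preserving alignment at episode onset.
- **Peak ties** resolve to the lag nearest 0, then to the negative side,
  always with a warning; ties are essentially impossible on real data but
  common on tiny synthetic examples.
- **Subsampling** keeps every (fps/target)-th lag (lag 0 always retained;
  the ±4 s endpoints survive exactly when L is a multiple of the stride,
  as it is for 25 fps → 6.25 Hz: 201 → 51 bins).
- Cohort averages report the per-lag mean and the population SD (ddof 0)
  across dyads, so a single profile has SD 0.

## Surrogate baselines

The shuffled baseline permutes the infant series uniformly and recomputes
the profile against the intact parent, preserving both marginals exactly;
its expectation is the chance level 100·Σ_c p_c q_c at every lag, so it is
flat.  The default is a single shuffle per dyad (the literal surrogate);
`n_shuffles` can be raised to reduce its Monte-Carlo variance, and per-dyad
surrogate profiles are averaged before any cohort averaging.  The
random-pair baseline averages the parent's profile against k (default 5)
non-partner infants sampled without replacement, each pair trimmed to its
common length; it captures recurrence produced by the shared task rather
than the dyad.  A single pipeline seed fans out to per-dyad streams via
deterministic seed spawning, so cohort results do not depend on iteration
order.

## Anisotropic measures

Vertical (infant-axis) and horizontal (parent-axis) maximal runs of
recurrent points of length ≥ lmin are collected per orientation;
LAM = Σlengths/total recurrent points, TT = mean length, MaxL = max
length.  Defaults and conventions: lmin = 2 (the usual recurrence-toolbox
convention; the choice is exposed); lines do not wrap at borders; the main
diagonal is kept, because cross-recurrence between two different systems
has no trivial self-match line.  Orientations with no qualifying line
report 0 with `defined=False` rather than being dropped, keeping cohort
tables rectangular.  Exact invariants — transpose duality
(vertical(a,b) = horizontal(b,a)), conservation
(Σ lengths = LAM · recurrent points) and MaxL ≥ TT ≥ lmin — are enforced
in tests against an independent run-length enumeration.

Line lengths are reported in recurrence points; the provided ms conversion
is 1000/fps per point (40 ms at 25 fps).  Published figures in this
literature sometimes use 25 ms per point at a nominal 25 fps; with the
conversion kept separate from the point counts, either time base can be
applied explicitly.

Group-level asymmetry is tested with paired t-tests on per-dyad
vertical−horizontal differences for LAM, TT and MaxL; negative t means
horizontal dominance.  Paired Cohen's d = mean(diff)/SD(diff); a
zero-variance nonzero difference yields an undefined flag rather than an
infinite statistic.

## Mixed-model inference

Per-dyad real and baseline profiles on the 51-level subsampled grid are
stacked into a long table and fitted (maximum likelihood, random intercept
per dyad, via the statsmodels mixed-model backend behind a thin adapter)
as the ladder null `rr ~ 1`, additive `rr ~ condition + lag`, full
`rr ~ condition × lag`, all `+ (1|dyad)`.  Lag is an unordered factor with
the most negative lag (−4 s) as reference, condition reference = baseline,
so each interaction coefficient contrasts the real condition at one lag
against baseline at −4 s.  The full model on the 51-level grid has 102
fixed coefficients; the comparisons have df 50 (full vs additive) and 51
(additive vs null).

Numerical points:

- When the dyad variance is near zero the MLE sits on the parameter
  boundary and some optimizers return a non-finite log-likelihood; the
  adapter tries the default gradient method, falls back to Powell, and
  keeps the best finite fit.
- The plain chi-square reference for a 50-df fixed-effects LRT is
  anti-conservative at cohort scale (the ML residual-variance bias
  inflates the deviance by ≈ n/(n−p); measured ~8 % rejection at nominal
  5 % with 21 dyads).  The default p-value therefore maps the deviance
  difference to its normal-theory F statistic,
  F = (exp(χ²/n) − 1)(n − p)/df on (df, n − p) df, which restores
  near-nominal levels; the uncorrected chi-square p is always reported
  alongside (`p_chisq`, or `correction=None`).
- Coefficient t-tests use residual degrees of freedom (the backend offers
  no Satterthwaite approximation; with thousands of profile rows the two
  are close, and the substitution is logged).  The per-coefficient
  standardized effect is the estimate in residual-SD units.
- The LRT effect size is the Cramér's-V-style index sqrt(χ²/(N·df)).  It
  is an interpretation, not a canonical statistic, and is labelled as
  such.
- The significance window is the set of contiguous grid lags whose
  interaction coefficients pass |t| at α; its endpoints are therefore
  multiples of the grid step (0.16 s at 6.25 Hz).

The windowed procedure splits the grid into n_windows (default 4)
near-equal windows, remainder to the last.  With a cohort it pairs each
dyad's window-mean rr with its own baseline (each dyad contributes both
conditions, so pairing is the natural choice); with a single profile pair
it pairs lag-by-lag within the window, reproducing the per-episode variant
(a 50-lag window gives df 49).  A window is significant iff
p < α/n_windows; no correction beyond Bonferroni is applied.

## Synthetic generator

The generator emulates the target setting: a leader (hand-held object)
sweeping sinusoidally left–right (default 120 px amplitude, 4 s period,
random phase) with a small, slower vertical undulation (6 px, 2.7 s), and
a follower whose step *direction* (sign pair) copies the leader's at a
fixed frame lag (default 6 frames = 240 ms), with per-frame magnitudes
resampled.  Copying direction rather than position puts the ground-truth
coupling exactly in the categorical space the pipeline measures, so
noise-free recovery is exact by construction rather than approximate.
Degradations: with probability `noise_p` (default 0.1) a follower step's
direction is replaced by a uniformly random one of the nine cells; each
frame is independently invalidated with probability `dropout_p` (default
0.05), first and last frames kept valid (a tracker is initialised on its
first frame).  Cohorts (default 21 dyads) draw episode lengths uniformly
from 15–41 s (375–1027 frames at 25 fps) and derive per-dyad seeds from a
master seed.

What the generator does *not* emulate: genuinely two-dimensional infant
motion, bidirectional coupling, drifting lags, tracker false positives
(boxes locked on the wrong object), or burst-structured dropout.  Passing
tests therefore establish that the pipeline measures what it claims on
data whose coupling is known and purely directional — not that any
particular real dyad is coupled.  The near-periodic leader also makes real
lag profiles oscillate across the ±4 s window, so interaction
significance extends beyond the injected-lag neighbourhood; assertions
about localisation always check *containment* of the true lag, not
exclusivity.

The statistical calibration harness generates profile tables directly from
a Gaussian random-intercept process (dyad SD 2, residual SD 1.5 in rr
percentage points, both conditions identically distributed under the
null), which isolates the test-level properties of the inference machinery
from generator idiosyncrasies.

## Problem sizes in tests

The default suite uses episodes of 320–1027 frames, cohorts of 4–21 dyads,
200 null cohorts for LRT calibration, 500 replicates for familywise-error
calibration, and 20 seeds for recovery rates — sizes at which the measured
rates have binomial MC standard errors of 1–1.5 percentage points, which
the test bounds account for (nominal level + 2.5 SE).

## Known limitations

- Linear gap interpolation biases movement categories toward sustained
  directions inside long gaps; tracking accuracy is reported so users can
  screen dyads (the field convention is to inspect low-accuracy tracks).
- `eps` interacts with tracker quantization; there is no universal
  default, and the chance level of the simple coding depends strongly on
  the marginal share of code 0.
- The mixed model treats rr percentages as Gaussian; at saturation
  (rr → 100) or tiny overlaps this is rough.  Per-lag overlaps below ~50
  pairs make profile tails noisy; the lag window should stay well under
  the episode length (the generator enforces n_frames > lag + 2·L).
- Random-pair baselines with small pools (k close to the cohort size)
  reuse infants across parents, correlating baseline profiles across
  dyads; the mixed model's dyad intercept absorbs only part of that.
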