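# dyadrec

Quantify behavioral coupling between two interacting partners — typically a
parent and an infant — from the bounding boxes an object tracker (such as
TLD) emits for each video frame.  `dyadrec` turns each tracked trajectory
into a categorical movement-direction time series, measures how tightly and
at what delay the two series are coupled with diagonal-wise cross-recurrence
analysis, validates the coupling against shuffled and random-pair
surrogates, characterises its asymmetry with anisotropic recurrence
measures, and runs the matching mixed-model inference.  It is aimed at
developmental and interaction researchers who want frame-level movement
coding without manual annotation.

## Method

Each frame-to-frame displacement of a tracked box center is coded under a
**simple** (0 none, 1 right, 2 left) or **detailed** scheme (0 none plus the
8 compass directions, image coordinates, y down).  For a parent series
*p(t)* and infant series *f(t)* of common length *N* at *fps* frames/s, the
diagonal-wise recurrence rate at lag τ is

    RR(τ) = 100 / (N − |τ|) · Σ_t 1[ p(t) = f(t − τ) ],   τ = −L … +L

so an infant echoing the parent Δ frames late peaks at τ = −Δ: **negative
peak lags mean the parent leads**.  A ±4 s window at 25 fps gives 201 lags
(51 after 6.25 Hz subsampling for modelling).  Two surrogates calibrate the
profile: shuffling the infant series (chance level `100·Σ_c p_c q_c`) and
re-pairing the parent with non-partner infants (task-driven recurrence).

Because categorical recurrence plots organise into rectangular blocks
rather than diagonals, coupling *quality* is read from the vertical and
horizontal line structures (anisotropic CRQA): laminarity **LAM** (share of
recurrent points on lines of length ≥ lmin), trapping time **TT** (mean
line length) and **MaxL** (longest line), computed separately per
orientation; horizontal > vertical means the parent dwells longer in
matching states than the infant.  Inference uses linear mixed models of RR
with Condition and Lag (categorical, reference −4 s) as fixed effects and
Dyad as a random intercept, likelihood-ratio model comparison
(`rr ~ condition × lag` vs `+` vs `1`, with `(1|dyad)` throughout), per-lag
interaction t-tests, and four-window Bonferroni t-tests.

A synthetic generator produces leader–follower dyads whose coupling lives
exactly in the categorical space the pipeline measures (the follower copies
the leader's movement *direction* after a known frame lag, with
configurable direction noise and tracker dropout), so every stage is
testable with known ground truth.

## Worked example

```python
from dyadrec import (
    DyadSimParams, generate_dyad, interpolate_gaps, tracking_accuracy,
    categorize, trim_pair, lag_profile, peak_lag,
    cross_recurrence_matrix, acrqa_measures, shuffled_baseline,
)

params = DyadSimParams(lag_frames=6, noise_p=0.1, dropout_p=0.05, seed=42)
parent_traj, infant_traj, truth = generate_dyad(params)
print(f"tracker accuracy: parent {tracking_accuracy(parent_traj):.1f}%, "
      f"infant {tracking_accuracy(infant_traj):.1f}%")

parent = categorize(interpolate_gaps(parent_traj)[0], "simple")
infant = categorize(interpolate_gaps(infant_traj)[0], "simple")
parent, infant = trim_pair(parent, infant)

profile = lag_profile(parent, infant, max_lag_s=4.0)
lag_ms, leader = peak_lag(profile)
print(f"profile peak: {lag_ms:+.0f} ms ({leader}), rr = {profile.rr.max():.1f}%")

baseline = shuffled_baseline(parent, infant, max_lag_s=4.0, seed=0)
print(f"shuffled baseline mean rr: {baseline.mean_rr():.1f}%")

m = acrqa_measures(cross_recurrence_matrix(parent, infant), lmin=2)
print(f"LAM_v={m.lam_v:.2f}  LAM_h={m.lam_h:.2f}  "
      f"TT_v={m.tt_v:.2f}  TT_h={m.tt_h:.2f}  MaxL_v={m.maxl_v}  MaxL_h={m.maxl_h}")
```

prints

```
tracker accuracy: parent 94.6%, infant 94.6%
profile peak: -240 ms (parent-leading), rr = 94.1%
shuffled baseline mean rr: 48.6%
LAM_v=0.96  LAM_h=1.00  TT_v=14.09  TT_h=48.94  MaxL_v=52  MaxL_h=50
```

The injected 6-frame (240 ms) parent lead is recovered as the profile peak
at −240 ms, far above the ~49 % chance level of the 3-category coding of
this episode; the horizontal line measures exceed the vertical ones because
direction noise fragments the follower's dwell episodes.

The same analysis runs from the shell over a config file (simulated or real
trajectory CSVs with columns `frame,x,y,w,h,valid`):

```bash
dyadrec simulate -c config.yaml -o sim/      # write trajectory CSVs + truth
dyadrec analyze  -c config.yaml -o run/      # full pipeline, all artifacts
dyadrec report   -r run/                     # one-line summary per system
```

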