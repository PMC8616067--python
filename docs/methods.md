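# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `emgcycle`.  It is written for users who need to judge
whether the pipeline's assumptions fit their data, and for maintainers who
need to know why each default is what it is.

## Signal chain

### Linear envelopes

Raw sEMG is converted to a linear envelope per muscle: zero-phase high-pass
at 10 Hz (drift and motion-artifact removal), full-wave rectification, and
zero-phase low-pass at 10 Hz (amplitude envelope).  Both filters are
4th-order Butterworth applied forward–backward (`scipy.signal.sosfiltfilt`):
the field-standard choice for linear envelopes, chosen because zero-phase
filtering preserves burst timing, which the segmentation and anchor stages
depend on.  Filter cutoffs are configuration (`preprocessing.highpass_hz`,
`lowpass_hz`), defaulting to 10 Hz / 10 Hz.  Negative post-filter overshoot
is clipped to zero because the envelopes feed a non-negative factorization.

Envelopes are standardized by a single scalar: the median rectified
amplitude pooled over all muscles and all trials of a session, taken on the
post-rectification, pre-smoothing signal.  This preserves inter-muscle
amplitude ratios (everything is divided by the same number) while making
sessions comparable without maximum-voluntary-contraction normalization.
Whether the median should be computed before or after smoothing is a
genuine ambiguity; pre-smoothing is the default here and the alternative
can be had by standardizing `EnvelopeMatrix.values` manually.

### Cycle segmentation

Cycles are delimited by local minima of the composite envelope (the
per-sample sum over muscles) — no kinematic channel is needed.  Two
numerical choices matter:

* **Cadence estimation.**  The nominal cycle period is the dominant
  autocorrelation lag, searched in 0.2–5 s.  Naive peak-picking fails in
  two ways on burst-structured envelopes: the ACF has sub-period peaks at
  the burst spacing within a cycle, and finite-sample noise can push an
  integer multiple of the true period marginally above it.  The estimator
  therefore unbiases the ACF by lag, scores each strong peak by the mean
  ACF over its harmonics (candidates are capped so at least two multiples
  are averaged), and returns the earliest lag scoring within 15% of the
  best — the fundamental and its octaves score alike, and the fundamental
  is the smallest such lag.
* **Minima selection.**  Candidate boundaries are local minima with
  prominence of at least 10% of the envelope range (`prominence_frac`).
  Selection exploits periodicity: starting from the deepest candidate, the
  walk steps one cadence at a time in both directions and accepts the
  deepest candidate within ±¼ cadence of the expected position (one window
  doubling is allowed to tolerate a single misplaced trough; ties go to
  the earlier index).  A plain deepest-first greedy selection with a
  half-cadence spacing floor was tried first and discarded: the dips
  between successive bursts within a cycle sit about half a cadence apart
  and, under amplitude jitter, are occasionally deeper than a genuine
  cycle trough, which derails any selection rule that ignores where the
  next boundary is expected.

Cycles are half-open `[start, next_start)`, 0-based; concatenating the
cycles of a trial reproduces the spanned envelope exactly.  Partial cycles
before the first and after the last minimum are discarded.

### Time normalization and anchor-aligned averaging

Each cycle is resampled to `t_norm = 200` points by linear interpolation
(endpoints preserved).  Per muscle and cycle, activation anchors are
detected: onset = first sample above 20% of the per-cycle maximum
(`onset_frac`, a common sEMG onset convention), offset = last such sample,
peak = argmax; an all-zero trace yields null anchors.  For averaging, each
cycle is piecewise-linearly warped so its anchors land on the median anchor
positions across cycles (cycle endpoints fixed; anchor pairs that would
break strict monotonicity in either axis are dropped, so the warp never
reorders time), and the warped traces are averaged pointwise.  Median
targets rather than means keep one outlier cycle from dragging the
template.  On identical cycles the warp is the identity and the average
equals the input.  This anchor-warp scheme is this package's declared
integration of temporal and spatial inter-cycle variation; dynamic time
warping was deliberately left out of scope as heavier than the problem
requires.

### Phase factorization

NMF is fitted by Lee–Seung multiplicative updates for the Frobenius loss —
the classical algorithm family for muscle-synergy extraction — implemented
in-package because the pipeline's contracts need per-restart loss
sequences, a seeded restart policy, and the monotone-loss guarantee
(`sklearn.decomposition.NMF` is used in the test suite as an independent
cross-check of reconstruction error, never as the implementation).
Numerical choices:

* initialization uniform in (0, 1] scaled by `sqrt(mean(M)/n)`; NMF is
  non-convex, so each fit is the best of `restarts = 10` seeded restarts
  (3 for the cheaper per-cycle fits);
* convergence when the relative loss decrease falls below `tol = 1e-6`
  (`1e-5` per-cycle) or after `max_iter = 1000` (500) iterations; a small
  `eps = 1e-12` in the update denominators guards against division by zero;
* VAF is global and uncentered (`1 − ‖M − WH‖²_F/‖M‖²_F`), not per-muscle:
  the order criterion is a property of the whole decomposition;
* order selection returns the smallest `n` whose VAF reaches the threshold
  (0.95 default); if none does, an error carrying the best order/VAF found
  is raised so callers can decide.

The decomposition input is the concatenation of a condition's
time-normalized cycles (not the average cycle), so that per-cycle patterns
exist for the stability indices; the average cycle can be decomposed
separately for display.  For display, each `H` row is normalized to unit
maximum with the scale transferred to the matching `W` column, leaving the
reconstruction unchanged.  Phases of different fits are aligned by a
greedy one-to-one assignment maximizing the correlation of temporal
patterns (ties: spatial correlation, then lower index).

### Phase metrics

The relative contribution enters with the time integral of each `H` row:
`C_i ∝ (Σ_m W_mi)(Σ_t H_i(t))`, normalized to sum to 1.  Multiplying the
muscle-weight sum by the activation's time-sum makes `C_i` the fraction of
total reconstructed amplitude, invariant to the W/H scale transfer and to
joint rescaling.

Stability indices are the mean zero-lag Pearson correlation over all
unordered pairs of cycles — between per-cycle `H` rows (temporal) and
per-cycle `W` columns (spatial).  Lag-scanning cross-correlation was
rejected because cycles are already time-normalized; correlating each
cycle against a template was rejected in favour of the pairwise mean,
which has no privileged cycle.  Zero-variance traces make a pair's
correlation undefined; such pairs are skipped with a warning, and an
all-skipped input is an error.  Per-cycle patterns come from independent
per-cycle NMF fits matched to the condition's reference model
(`stability.mode = "nmf"`); a fixed-`W` non-negative projection of each
cycle is available as a cheaper alternative (`"projection"`).

### Group statistics

All unordered pairs of condition levels are compared with a two-sided
Mann–Whitney U test: exact null enumeration when both samples have ≤ 20
observations and no ties, otherwise the tie-corrected normal approximation
with continuity correction (both via `scipy.stats.mannwhitneyu`).  The
unpaired U test is the package default by deliberate choice; a Wilcoxon
signed-rank option (`stats.paired`) exists for strictly paired readings of
a repeated-measures design, and Holm correction (`stats.holm`) is provided
but off by default since the reference analysis style reports raw p-values
at α = 0.05.  The observation unit matters (cycles, trials, or
participants give very different test sizes); the pipeline uses cycles for
contributions and trials for stability indices, and the tables carry the
unit columns so users can re-test at another unit.

## Synthetic generator

The generator emulates a force-modulated pedaling experiment: 4 muscles
(knee extensor VLAT, hamstring BF, tibialis TA, calf GAM analogs), 3
phases per cycle with truncated-Gaussian bursts (centers 0.20/0.50/0.80 of
the cycle, width 0.08, truncated at 4 SD), cadence 1 s at 1500 Hz
sampling, 12 cycles per trial by default.  The summed planted envelope
amplitude-modulates band-limited (20–450 Hz) Gaussian carrier noise — the
standard surrogate for the raw sEMG interference pattern — normalized so
the carrier's rectified mean is 1, making the planted envelope the exact
linear envelope of the clean signal; sensor noise is added at a
configurable envelope SNR (30 dB default).  Jitter: burst centers and
widths perturbed per cycle and phase (timing jitter SD 0.02 of the cycle
by default), and amplitudes perturbed by independent lognormal factors per
cycle, phase *and muscle* (SD 0.10).  Making amplitude jitter per-muscle
is deliberate: a per-phase scalar would rescale whole `W` columns and be
invisible to the correlation-based spatial stability index, whereas real
inter-cycle variability perturbs muscles individually.

Each trial is padded on both sides exactly to the nearest burst of a
virtual neighbouring cycle, so the composite envelope has genuine troughs
bracketing the first and last cycle (n cycles ↔ n+1 detectable minima) and
is monotone at the trial edges.

Resistance levels 2–5 modify the baseline by documented monotone schedules
(package constants): timing jitter 0.030 → 0.012, amplitude jitter 0.20 →
0.08, VLAT early-power weight ×1.00 → ×1.75, BF late-power weight ×1.00 →
×2.35, GAM late-power weight ×1.00 → ×0.76 (BF overtakes GAM at the top
levels).  The directions encode the qualitative experimental findings; the
magnitudes are this package's defaults, chosen once to produce effect
sizes detectable at desk scale, since no quantitative per-level effect
sizes are published.

What the generator does **not** emulate: motor-unit biophysics,
electrode-skin impedance drift, movement artifacts, muscle fatigue,
crosstalk between channels, or inter-participant anatomical variability.
Tests passing on this generator therefore demonstrate that the pipeline
recovers the planted coordination structure under realistic noise, jitter
and amplitude variability — not that it is robust to every artifact of
real recordings.

A note on envelope recovery: the linear envelope of amplitude-modulated
Gaussian noise has an irreducible relative fluctuation of about 11% at
these bandwidths (≈ √((1−2/π)/(2/π) · ENBW/B)), independent of sensor
SNR.  Per-sample envelope comparisons are therefore bounded at that level,
while the cycle-averaged envelope recovers the planted shape to within a
few percent — the tests are written accordingly.

## Problem sizes

Default trials are 12 cycles (~13 s at 1 s cadence); the simulated study
is 4 levels × 3 trials, mirroring the reference protocol's trials per
level.  Monte-Carlo properties in the test suite use 20–100 trials and 50
seeds per grid point — sizes chosen as the package's own desk-scale
defaults at which every planted effect is comfortably detectable.  With 3
trials per level, stability comparisons cannot reach p < 0.05 under an
exact U test (the floor is p = 0.1); contribution comparisons, which use
cycles as units, can.  This mirrors the general caution above about
choosing the observation unit.

## Known limitations

* Segmentation assumes a quasi-constant cadence within a trial (the
  periodic walk tolerates ~±25% cycle-to-cycle deviation); strongly
  accelerating tasks would need a time-varying period model.
* Composite-envelope segmentation can fail when one muscle's burst spans
  the cycle boundary of another's trough; per-muscle segmentation is out
  of scope.
* Pearson correlation over 4 muscle weights (spatial stability) has only
  two effective degrees of freedom and is accordingly noisy; with larger
  electrode sets it stabilizes.
* The NMF order criterion is a global VAF threshold; per-muscle VAF
  criteria found in parts of the synergy literature are not implemented.
* HDF5 containers are not implemented; all I/O is CSV/YAML text.
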