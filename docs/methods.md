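# Methods

## Decoding model

Each sample of a multi-channel fNIRS recording is one classification
instance, labeled +1 while a task block is on (behavioral ground truth,
not hemodynamic), −1 during rest. A linear soft-margin SVM (hinge loss,
penalty C, default 128) is trained on the first ⌈n/2⌉ trials and evaluated
on the rest. The split boundary sits at the first test block's onset;
the rest period between the halves belongs to the training half. History
windows of test rows may reach back across the boundary — those are past
*observations*, available to any causal decoder at deployment, not label
leakage. Predictions are `sign(w·x + b)` with a decision value of exactly
0 mapped to −1.

The solver is liblinear's dual coordinate descent (`LinearSVC(loss=
"hinge")`, tolerance 1e-6, fixed permutation seed, iteration cap 5·10⁶),
which satisfies the decoding contract deterministically; on separable toys
its solutions match libsvm's to solver tolerance, and it remains fast in
the regime — near-unregularized C on strongly overlapping classes — where
libsvm's working-set solver can stall. Features are not standardized by
default; an unscaled replicate-first pipeline is the reference behavior.
No class weighting is applied despite the 1:2 task:rest imbalance.

## Preprocessing

Every channel and chromophore is filtered with the EMA band-pass
`g = S − L`: exponential moving averages with spans α_S = 20 and
α_L = 100 samples, both seeded with the first sample (so `g(0) = 0` and
there is no startup transient), recursion weight `λ = 2/(α+1)` by default
(`1/α` available as `lambda_rule="reciprocal"`; at 10 Hz the default makes
the short window the conventional 2 s). The filter is linear, causal, and
invariant to constant offsets. Filtering precedes all feature
construction, CNR computation included.

## Feature spaces

Per channel and selected series, the amplitude representation stacks lags
0..y (y = round(history_s·fs)); the gradient representations keep the
lag-0 amplitude plus y finite-difference columns at lags 0..y−1, so all
three representations have identical dimensionality at a given y, and the
gradient spaces are invertible linear maps of the amplitude space (a
property the tests verify — it is why a linear classifier performs
identically with either). Rows lacking complete history are masked out
rather than zero-padded; padding would inject a spurious transient into
early-trial classification. The CBSI weight α is estimated on the
training portion only and reused for test features.

## CNR channel ranking

`CNR = (mean_task − mean_rest)/s_pooled` over half-open windows 6–12 s
after block onset (task, accounting for the hemodynamic delay) and −5–0 s
(rest), pooling raw samples across the training trials; `s_pooled` is the
classical two-sample pooled SD. A block-averaged variant is available
(`mode="block_average"`). Ranking uses oxy-Hb on filtered signals by
default (both configurable) and never sees test trials. Two CNR values
within a relative 1e-9 are treated as tied and keep the original channel
order — floating-point rounding must not reorder channels that differ
only by a positive gain.

A known structural limitation: when every channel carries the same
response template scaled by a gain, CNR saturates toward the
channel-independent value Δ/s_template as noise vanishes, so the *exact*
full ordering is recovered either in the strictly noiseless limit (via
the tie policy) or when channel-independent noise dominates the
within-window signal variance. In between, expected CNR is still strictly
monotone in amplitude, but adjacent-channel separations shrink as O(σ²)
while estimation fluctuations shrink only as O(σ).

## Evaluation

Accuracy is the fraction of valid test samples correctly labeled. Onset
delay per test block is the time from block onset to the first +1
prediction searched forward up to the next block's onset (detections
during the preceding rest do not count); offset delay likewise from block
offset to the first −1. Blocks with no qualifying sample are censored and
excluded from means (censor counts reported); standard errors across
trials use the n−1 denominator. The channel-count condition keeps the
accuracy-maximizing count *evaluated on the test half* — faithful to the
original sweep procedure and therefore optimistic as a deployment
estimate; per-count metrics are reported so users can apply their own
selection.

## Synthetic data generator

The generator emulates a motor block-design optical-topography session:
10 trials of 10 s task alternating with 20 s rest at 10 Hz (a lead-in and
trailing rest frame the schedule), 48 channels by default. Channel c's
oxy trace is `amp_c · (boxcar ⊛ HRF)` — rescaled so an isolated block
peaks at `amp_c` — plus drift and white noise; deoxy is the response
scaled by −0.35 (optionally lagged) with independent drift/noise. Channel
gains decay geometrically (`amp_c = 1.0 · 0.85^c`) so ranking has a
well-defined true order. Drift is 3 random-phase sinusoids below 0.05 Hz
plus a linear trend (amplitude 0.1); noise is i.i.d. Gaussian, SD 0.15.

The HRF is a double gamma: gamma densities with modes at the peak delay
(6 s) and undershoot delay (16 s), undershoot ratio 0.4, common time
scale (dispersion) 0.5 s, normalized to unit peak. The brisk dispersion
and pronounced undershoot model a strong motor response that returns
promptly after block offset. This choice is load-bearing: with a broad,
weakly-undershooting response, the EMA-filtered signal keeps so much
positive mass after block offset that the optimal single-threshold
decoder is *always-rest* — the baseline condition would never detect
anything. The defaults were fixed, before the evaluation suite was
written, as the parameter set under which a single-threshold baseline
detects onsets near the hemodynamic peak delay, which is the qualitative
behavior of real recordings the generator exists to emulate. Signal
units are arbitrary (concentration change × pathlength); absolute
amplitudes are not meaningful, only amplitude:noise ratios.

What the generator does **not** model: cardiac/respiratory/Mayer-wave
physiology, motion artifacts (CBSI is implemented but its motion benefit
is not exercised), spatially correlated noise across channels, and
between-trial response variability. Consequently, passing tests show the
pipeline's correctness and the direction of its effects under clean
block-design assumptions — not performance on any particular human
dataset. Two knock-on effects worth knowing: with *independent*
per-channel noise, adding channels helps mainly when the single-channel
decoder is noise-limited (with a strong quiet channel, the C=128 SVM's
extra dimensions cost more than they add); and per-channel drift acts as
a low-dof confound that degrades CNR ordering more than white noise of
the same amplitude.

## Numerical choices

* Windows are half-open `[start, end)`; sample k sits at `t0 + k/fs`;
  discretization uses `ceil(t·fs − 1e-9)`.
* Decision value 0 → −1 (documented tie rule); CNR ties at relative 1e-9
  keep input order; sweep optima take the first value on ties.
* Text round-trips are value-exact: writing uses 17 significant digits and
  reading uses round-trip float parsing.
* Recordings containing NaN/Inf are rejected at load; the loader never
  imputes silently.
* The cohort runner caps the channel sweep at 16 channels by default
  (configurable), which comfortably brackets the accuracy peak under the
  default design while keeping a six-recording report in minutes on one
  CPU.
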