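# Methods

## Model and estimation

For a minute-indexed heart-rate series h_1..h_N (bpm), the order-m
autoregression predicts h*_{k+1} = a_0 + Σ_{i=1..m} a_i h_{k+1−i}, with a_1
attached to the most recent observation (a literal reading of the lag
index). Parameters are estimated by ordinary least squares over every
one-step relation inside the current window — targets h_{m+1}..h_k — with
no weighting or regularization. Among all least-squares minimizers the
minimum Euclidean-norm one is returned, computed by an SVD-based solver
(`scipy.linalg.lstsq`, `gelsd`) with singular values below 1e−10 × s_max
treated as zero. The minimum-norm convention is not cosmetic: constant
heart-rate stretches make the lag design exactly rank deficient (all lag
columns equal), and the constant-series solution has the closed form
a = c·(1, c, …, c)/(1 + m c²), which the tests check.

Fitting starts at the smallest window end k = 2m+1 (no extra burn-in) and
is repeated at every minute up to k = N−1, giving N−1−2m fits and one-step
predictions covering minutes 2m+2..N. Within the first `window` minutes
(default 1440 = 24 h) the window grows from the start of the series; past
that it slides at fixed length `window`.

### The rolling solver

Re-solving ~1430 least-squares problems per series per order from scratch
is O(N²) work, so `rolling_fit` maintains prefix sums of XᵀX and Xᵀy over
the lag rows (lag columns centred at the series mean, which keeps the Gram
matrices well conditioned at heart-rate scales) and solves all windows in
one batched call. Any window whose Gram matrix has eigenvalue ratio below
1e−8 — i.e. whose design is rank deficient or conditioned badly enough
that normal equations could lose more than ~8 digits — is recomputed with
the SVD minimum-norm solver on the raw (uncentred) design, which is also
the path that defines the estimator. On full-rank windows the two routes
agree to ~1e−13 relative (tested at orders 1, 3, 5); the constant series
exercises the fallback at every window.

Predictions are real-valued; they are never rounded to integer bpm, because
the error statistic is a real-valued mean absolute difference.

## Evaluation, convergence, inference, selection

* **Err** = mean |h*_t − h_t| over the last `eval_fraction` of the
  prediction stream, with eval_count = ⌈eval_fraction × n_predictions⌉
  (default 0.2). This is an out-of-sample statistic: each prediction came
  from a model fit strictly on earlier minutes. The tail fraction is
  deliberately the post-convergence part of the day — early fits on tiny
  windows would contaminate the error with transient estimation noise.
  The denominator counts predictions, not minutes; for N = 1440 the two
  differ by at most 2m out of ~1430 and the distinction is immaterial.
* **Parameter stability**: mean and sample SD (denominator n−1; a length-1
  slice reports SD 0) of each parameter over the final `stability_fraction`
  of the trajectory (default 0.2, matching the Err window; configurable up
  to the full trajectory). Small tail SDs are the convergence diagnostic.
* **p-values**: classical two-sided t-tests from an OLS fit on the final
  window (statsmodels). Rank-deficient designs and exact fits (zero
  residual variance) yield NaN rather than a fabricated number. No
  multiple-testing correction is applied. These are conditional,
  in-sample linear-model p-values — on strongly autocorrelated data they
  are near zero by construction, which is a statement about signal
  presence, not about forecast skill.
* **Order selection** fits m = 1..m_max (default 5) on identical data and
  keeps the smallest Err; Err values equal to within 1 part in 1e9 count
  as tied and go to the smaller m, so exactly-fit series select m = 1
  instead of whichever order accumulated the least round-off. On noisy
  data genuine near-ties are resolved by the sample, so selection among
  statistically indistinguishable orders carries Monte-Carlo noise — the
  white-noise study in the acceptance checks quantifies exactly this.

## Synthetic generator

`SyntheticSpec` defines a stationary AR(m₀) core (Gaussian innovations —
the choice that makes least squares the maximum-likelihood estimator, so
recovery tests are clean), initialized at the process mean
a_0/(1 − Σa_i) when stationary (at 70 bpm otherwise, with a warning; a
stationarity check via the characteristic-polynomial roots is built in).
On top of the AR core, optionally:

* a circadian sinusoid (amplitude in bpm, period default 1440 min),
* activity bursts: a Poisson process (events/hour) each adding
  `magnitude · exp(−Δt/decay)` bpm from its onset,
* clipping to 30–220 bpm and rounding to integer bpm (default on —
  consumer smartwatches report integers).

Clipping and rounding apply to the emitted values only and are not fed back
into the recursion, so the recorded spec remains the exact generating truth
for the latent process.

Presets are anchored at published cohort operating points (true orders 1,
2, 3 and 5; e.g. the strongly persistent AR(1) point a_0 = 6.55,
a_1 = 0.916) with innovation SD 3 bpm. The 23-series cohort fixture cycles
presets and innovation SDs 2/3/4 bpm and layers mild realism on every
series (circadian amplitude 2.5 bpm; bursts at 0.5/h, 15 bpm, 10-min
decay) — values chosen once as a plausible mix of resting drift and
occasional movement for a largely sedentary cohort. Seeds derive from a
single base seed via `numpy.random.SeedSequence`, so fixtures are exactly
reproducible.

What the generator does **not** emulate: measurement dropout, sensor
artefacts, heart-rate-variability microstructure, true activity-coupled
dynamics, medication effects, or inter-day nonstationarity. Tests passing
on this generator therefore show that the pipeline recovers the structure
it models and behaves sensibly under mild model violation — not that real
wearable data obeys an AR(5).

## Problem sizes in the checks

The Monte-Carlo checks run at the study's native scale (N = 1440, 100
seeds) since the batched solver makes a full 5-order selection run ~0.4 s;
the whole acceptance script completes in well under a minute on one CPU.
Observed behaviour: AR(1) recovery coverage at 3 classical SEs is 98–99 of
100 seeds; lag-3-dominant data selects m ≥ 3 in ~100 of 100 seeds; on white
noise Err is near-flat across m (mean relative spread ~0.6%) and m = 1 is
the modal selection at roughly half the seeds, the rest scattering over
m = 2..5 by sampling noise — the expected behaviour of an argmin over
statistically tied alternatives with an exact-tie preference for small m.

## Ingestion rules

Input tables carry `participant_id`, `minute_index` (1-based integer or
ISO-8601 timestamp, floored to the minute), `heart_rate_bpm`. Rows outside
the sanity bounds (default 20–250 bpm) are dropped with a logged reason.
Gaps are an error by default — silent imputation would corrupt the lag
structure — or forward-filled up to a per-gap cap (default 5 min) under
`gap_policy: ffill`, each fill logged. Each participant is truncated to the
first `window` minutes. Every knob lands in the run manifest; reruns on
identical inputs are byte-identical.

## Known limitations

* The model is linear, univariate and exogenous-free: physical activity,
  symptoms and blood pressure/weight channels are out of scope.
* Best-order clustering is indicative only; no clinical meaning attaches
  to the groups, and no event outcomes are modelled.
* Published per-participant Err and parameter values cannot be reproduced
  here because the underlying streams are not public; the package instead
  verifies its machinery against closed forms, independent oracles and
  simulation, and checks qualitatively that synthetic-cohort Err lands in
  the published 2–7 bpm band.
* p-values ignore the sequential re-use of overlapping windows; treat them
  as descriptive.
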