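# hrtwin

Rolling autoregressive models of minute-level wearable heart rate — a
lightweight "digital twin" of a person's heart rhythm for at-home monitoring
of people with heart failure (or any condition observed through a
per-minute heart-rate stream).

## The problem and the model

A smartwatch reports heart rate h_k (beats per minute, bpm) once per minute,
k = 1, 2, 3, … Given the first k observations, we predict the next minute
with an order-m autoregression:

    h*_{k+1} = a_0(k) + Σ_{i=1..m} a_i(k) · h_{k+1−i},        1 ≤ m ≤ 5

where a_1 weighs the most recent minute. Because the fit is a small linear
least-squares problem, the model is re-estimated **every minute** on the
window of data seen so far (growing up to 1440 minutes = 24 h, then sliding),
by minimizing Σ_{i=m+1..k} (h*_i − h_i)²; when the lag design is rank
deficient — constant heart-rate stretches do this — the **minimum-norm**
solution is taken. Fitting starts at k = 2m+1 so every window supports a
reliable estimate.

The per-minute parameter stream a(k) is the twin: its convergence is
summarized by the mean ± SD of each parameter over the trajectory tail, and
predictive quality by

    Err = mean |h*_t − h_t|   over the last 20% of the one-step predictions,

in bpm. For each person the order m ∈ {1..5} with the smallest Err is the
"best model" (ties go to the smaller m), and a cohort can be grouped —
indicatively, with no clinical claim — by that best complexity.

Real study streams of this kind are not public, so the package ships a
synthetic generator (`hrtwin.synthetic`) that emulates 24 h smartwatch
series: a stationary AR core at published cohort operating points, plus
optional circadian drift, Poisson activity bursts, physiological clipping
and integer rounding. The published 23-person summary table (best orders,
Err values, parameter means) is embedded in `hrtwin.datasets` as the
real-data anchor.

## Worked example

```bash
hrtwin simulate --participants 4 --seed 11 --output-dir data
hrtwin cohort --input data/heart_rate.csv --output-dir results
hrtwin report --results-dir results
```

prints (abbreviated):

```
4 participants; cluster sizes {1: 1, 3: 1, 4: 1, 5: 1}
Cohort summary (best model per participant):
participant_id  best_order  err_bpm  a0_mean  a0_sd  a1_mean   a1_sd ...
  synthetic-01           5     1.81     5.71  0.104    0.907 0.00726 ...
  synthetic-02           1     2.49     12.8  0.196    0.844 0.00205 ...
  synthetic-03           3     3.51     11.1  0.246    0.184  0.0125 ...
  synthetic-04           4     2.02     4.38  0.166    0.356 0.00943 ...

Clusters by best-model complexity m:
  m=1 (1): synthetic-02
  m=3 (1): synthetic-03
  m=4 (1): synthetic-04
  m=5 (1): synthetic-01
```

Reading the first row: participant `synthetic-01` is best described by an
order-5 model whose one-step predictions miss the actual heart rate by
1.81 bpm on average over the final 20% of the day; `a1_mean ± a1_sd` is the
mean ± SD of the a_1 trajectory over its tail — an SD of 0.007 means the
parameter has settled. `results/` also holds per-participant parameter
trajectories, predicted-vs-actual tables and a YAML manifest of every
setting used.

The same pipeline from Python:

```python
import hrtwin as ht

series = ht.generate_ar_series(ht.PRESETS["participant2"], "demo")  # 24 h AR(1)
summary = ht.select_best_order(series)          # fits m = 1..5, picks min Err
print(summary.order, summary.err)               # e.g. 1  2.62
```

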