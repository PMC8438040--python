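# storyrecall

Behavioral and neural analysis of **one-shot naturalistic learning**: when
people listen to the same spoken story twice, a single exposure is enough to
anticipate what comes next.  This package quantifies that anticipation at
three levels —

- **Event segmentation.** Raters press a key at perceived event boundaries on
  both listenings.  Responses are coded as binary vectors at 1 kHz (1 wherever
  a press falls within the surrounding second); their across-rater mean is the
  *agreement time-course*.  Learning appears as increased leave-one-out cosine
  consensus on run 2 and as a negative lag of the run-2 agreement curve
  (cross-correlation against run 1), i.e. earlier boundary detection.
- **Word prediction.** Naive vs. previously-exposed groups predict each
  upcoming word of the transcript; the per-word increase in prediction
  probability is the behavioral measure of predictive recall (paired *t*
  across words, independent *t* across participants, Cohen's *d* = *t*/√N and
  2*t*/√df respectively).
- **Neural predictive recall.** For every electrode, the high-gamma
  (70–200 Hz) amplitude of the two listening runs enters a trivariate
  vector-autoregression conditioned on the stimulus audio envelope *Z*.  The
  cross-run Granger statistic

  F<sub>Y→X|Z</sub> = ln ( σ̂′<sub>xx</sub> / σ̂<sub>xx</sub> )

  compares the residual variance of the model with and without the other
  run's past.  If the listener recalls upcoming content, information appears
  *earlier* in run 2, so the past of run 2 predicts the future of run 1 but
  not vice versa: the per-channel asymmetry ΔF = F<sub>2→1|Z</sub> −
  F<sub>1→2|Z</sub> is the neural predictive-recall statistic.  Channels are
  selected by a two-component Gaussian mixture on ΔF (posterior ratio ≥ 10).
  Applying only the cross-run coefficient block of the fitted model
  (X̂′<sub>t</sub> = Σ<sub>k</sub> A<sub>xy,k</sub> Y<sub>t−k</sub>) and
  projecting it onto the observed data yields a moment-by-moment recall
  time-course; lagged Gaussian-copula conditional mutual information between
  the selected cortical pattern and hippocampal channels, around event
  boundaries and recall peaks, resolves the direction and timing of
  hippocampo-cortical information flow.

A synthetic-data generator (`storyrecall.synth`) emulates every input —
press logs with run-2 advancement, word tables with learning increments,
two-run multichannel amplitude recordings with a time-advanced shared latent
and lag-coupled hippocampal channels — with exact, recoverable ground truth,
so the whole pipeline runs and is tested without any data download.

## Worked example

Plant a 200 ms run-2 anticipation on 4 of 16 channels and recover it:

```python
import numpy as np
from storyrecall.synth import SimulationTruth, gen_two_run_recording
from storyrecall.preprocess import clean_and_align
from storyrecall.granger import cross_run_gc, sign_flip_test, select_cpr_channels

shifts = np.zeros(16)
shifts[:4] = 200.0                      # four channels anticipate run 2 by 200 ms
truth = SimulationTruth(shifts, np.arange(4), [1000.0], 0.0, [], seed=7)
run1, run2, env, _ = gen_two_run_recording(16, 0, 120.0, truth, snr=1.0)
run1, run2, env = clean_and_align(run1, run2, env)

table, models = cross_run_gc(run1, run2, env, p_max=25)
print(table[["channel", "F_21", "F_12", "delta_F"]].round(4).head(6).to_string(index=False))
flip = sign_flip_test(table["delta_F"].to_numpy(), n_perm=1000, seed=0)
sel = select_cpr_channels(table["delta_F"].to_numpy(), posterior_ratio=10, seed=0)
print(f"model order: {table['order'].iloc[0]} samples "
      f"({table['order'].iloc[0] * 10} ms at 100 Hz)")
print(f"sign-flip p = {flip['p']:.3f}; CPR channels: {sel['selected'].tolist()}")
```

which prints

```
channel   F_21   F_12  delta_F
  ch000 0.0942 0.0018   0.0923
  ch001 0.0926 0.0023   0.0903
  ch002 0.0952 0.0019   0.0932
  ch003 0.0941 0.0010   0.0931
  ch004 0.0405 0.0422  -0.0017
  ch005 0.0391 0.0375   0.0017
model order: 23 samples (230 ms at 100 Hz)
sign-flip p = 0.026; CPR channels: [0, 1, 2, 3]
```

The four planted channels show a strong positive ΔF (run 2 predicts run 1's
future, not vice versa), the AIC-selected model order covers the planted
200 ms advance, the channel-level sign-flip permutation rejects the null, and
the Gaussian-mixture selection recovers exactly the planted channel set.

The end-to-end pipeline is also available from the shell:

```bash
storyrecall all --seed 7 --out out/        # simulate → behavior → gc → timecourse → connectivity
```

writing every artifact (press logs, word table, recording container, GC
table, recall time-course, MI maps, cluster statistics) plus a
machine-readable `summary.json`.

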