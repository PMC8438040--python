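# Methods

This note documents the models, estimators, and numerical conventions the
package implements, the design choices made where several readings were
defensible, and what the synthetic data do and do not establish.

## Behavioral measures

**Response coding.** A press at time *t* (ms) marks the half-open interval
[*t* − 500, *t* + 500) of a binary 1 kHz response vector ("within the
surrounding second" read as a symmetric window; half-open so adjacent
millisecond bins never overlap).  Presses outside the story are dropped with
a warning.  The agreement time-course is the plain across-rater mean.

**Consensus.** Per rater and run, the cosine similarity between the rater's
vector and the mean vector of the other *n* − 1 raters; zero-norm vectors
yield 0 with a warning.  The learning test compares the mean run-2 − run-1
cosine difference against 1000 independent per-rater run-label swaps, and a
one-sided binomial test asks whether the fraction of improving raters exceeds
0.5.  (One-sided because the hypothesis is directional — improvement; the
two-sided p for 126/205 would exceed 0.001.)  Internally the leave-one-out
cosines are computed from the three Gram matrices of the run-1/run-2 vector
stacks, so a full permutation pass costs O(n²) instead of O(n·T); a direct
per-rater computation is kept as a test oracle.

**Cross-correlation lag.** At each integer-millisecond lag the shifted run-2
agreement curve is Pearson-correlated with run 1 over the overlapping
samples (per-lag normalization, not raw zero-padded cross-correlation — the
statistic of interest is an *r* value).  The sign convention makes earlier
run-2 responses a negative lag.  Significance comes from re-computing the
best lag under per-rater run-label swaps and counting permuted |lags| ≥
observed.

**Exclusion.** Participants whose correctness vector has cosine ≤ 0.6 to the
mean of the others are removed, the pass repeating on the reduced set until
stable (word-prediction replication); a single-pass variant with threshold
0.15 handles segmentation outliers.

**Permutation p-values** are reported throughout as count(null ≥ observed) /
n_perm, without +1 smoothing; a smoothed option exists on `perm_pvalue`.

## Preprocessing

All filters are 4th-order Butterworth designs applied forward–backward
(zero phase; effective attenuation doubled).  Band amplitudes are the
magnitude of the analytic signal, computed on a 1 s reflection-padded copy to
suppress Hilbert edge artifacts.  Everything is resampled to the 100 Hz
analysis rate (polyphase, anti-aliased).  The two runs are truncated to a
common length, linearly detrended per channel, and samples strictly
exceeding median + 5·IQR (per channel, full run) are replaced — together
with ±5 samples of padding — by monotone piecewise-cubic (PCHIP)
interpolation, with edge gaps held at the nearest valid value.  The
operation is idempotent on test fixtures.  The canonical 7-row feature stack
(raw + delta <4, theta 4–8, alpha 8–15, beta 15–30, low gamma 35–55, high
gamma 70–200 Hz) requires a native rate ≥ 400 Hz for the high-gamma band;
bands whose upper edge touches the Nyquist frequency are clipped just below
it with a warning, and fully infeasible bands raise.

## Cross-run conditional Granger causality

Per channel, with x = run-1 amplitude, y = run-2 amplitude, z = audio
envelope (all demeaned):

x_t = Σ_{k=1..p} A_xx,k x_{t−k} + Σ_k A_xy,k y_{t−k} + Σ_k A_xz,k z_{t−k} + e_t

fitted by OLS (lstsq), against the reduced model omitting the y block;
F_{y→x|z} = ln(σ̂′²/σ̂²) with σ̂² the maximum-likelihood residual variance.
The same order p serves both directions (both F values come from the same
trivariate system), so the first-order small-sample bias — E[F] ≈ p/n under
the null, which the tests verify — cancels in ΔF = F_{2→1|z} − F_{1→2|z};
no explicit bias correction is applied.  Swapping the runs negates ΔF
exactly.  Order selection minimizes AIC = n·ln det Σ_p + 2·d²·p over
p = 1…p_max on the joint trivariate process, computed with the Whittle/LWR
multivariate Levinson recursion on sample autocovariances (fast scan); the
final model is always refitted by OLS.  p_max defaults to 50 samples
(500 ms), comfortably covering the 130–350 ms range where the informative
structure lives; order is selected per recording (first channel) by default
and per channel on request.  Rank-deficient designs from duplicated
predictors (x ≡ y) are tolerated — minimum-norm OLS still yields the correct
ΔF = 0 — while zero-residual-variance designs raise with the channel id.

**Channel selection.**  A two-component 1-D Gaussian mixture (EM, 20
restarts, k-means init, seeded) is fitted to the ΔF distribution across
channels; the lower-mean component is the null.  A channel is selected when
the posterior ratio effect/null is ≥ 10 (in analogy to a Bayes factor of 10;
raising the threshold can only shrink the set, which is tested).  Group-level
inference uses sign-flip permutations of ΔF at channel or patient level;
with ≤ 12 patients all 2^k flips are enumerated exactly (9 patients → 512).
The patient-wise effect size is the mean of per-patient mean ΔF divided by
their SD (ddof 1).

## Recall time-course

Only the cross-run coefficient block is applied to the predictor run
(X̂′_t = Σ_k A_xy,k Y_{t−k}); the first p samples are undefined and dropped,
never zero-filled.  Each channel contributes X̂′·X − Ŷ′·Y (pointwise
products with the observed data); the channel mean is smoothed with a
centered 1 s moving average whose edge windows shrink rather than pad.  The
difference is smoothed, not the per-channel products (the choice was open;
difference-then-smooth keeps the per-channel components available for SEM).
Peak detection smooths with a Gaussian of nominal width w = 2 s implemented
as σ = w/6 truncated at ±3σ (support ±1 s — the stated "width" is read as
total support), thresholds at the 95th percentile, groups suprathreshold
samples into maximal contiguous clusters, and takes each cluster's maximum
(first sample on plateaus).  Peak output is invariant to positive affine
rescaling.

**Boundary-locked test.** The curve is averaged in windows around the
behavioral boundaries and compared per timepoint to 1000 averages over
equally many random positions (drawn uniformly, one half-window margin from
the edges); BH-FDR over the window.  **Word-locked correlation.** A
behavioral vector holds each word's prediction-probability change at the
samples where the word is heard; Pearson correlation with the neural curve
runs only over word samples (silences excluded) at each time shift, with a
null that reassigns the changes randomly to words, BH-FDR over lags.  The
permuted correlations are evaluated through per-word sufficient statistics
(counts, sums), making the 1000-permutation scan linear in the number of
words.

## Gaussian-copula mutual information

Each dimension is ranked (average ranks on ties), mapped to rank/(n+1), and
transformed by the inverse normal CDF; MI and conditional MI then follow
from Gaussian entropies via covariance Cholesky log-determinants with the
analytic expected-log-determinant bias correction (ψ terms).  The estimate
is a lower bound of the true MI, exactly invariant to strictly monotone
per-dimension transforms, and reported in nats.  A 1e-9 diagonal ridge keeps
the log-determinant finite when dimensions coincide exactly — precisely what
happens at lag 0, where the shifted target equals the zero-lag conditioner
and the conditional MI correctly collapses to ≈ 0.

**Lagged profiles and maps.** Samples are concatenated across 1 s windows;
at each lag (±1.5 s, 10 ms steps) the target feature stack is shifted
(positive lag = target lags behind the cortical pattern) and conditioned on
the unshifted target pattern to remove instantaneous shared signal.  Around
boundaries the profile is repeated at distances −3 s…+1 s from the marked
boundary (windows at adjacent distances overlap, as they must); the distance
step defaults to 10 ms with a coarse 50–100 ms mode used in tests.
Out-of-span windows are dropped with a warning.

**Cluster statistic.** Pointwise two-sample t (ROI > control) across
channels, thresholded at the one-tailed 95th-percentile t (directional
hypothesis), 4-connected clusters restricted to the plausible window
(distance −2 s…+0.5 s, lag ±1 s); the statistic is the summed ROI-mean MI in
the cluster (as stated; a t-mass variant would be conventional but is not
the default), compared to 1000 random channel swaps between the groups.
With no suprathreshold cluster the test is conservative (p = 1).

**Peak-locked contrasts.** Profiles over 1 s windows around recall peaks,
per run and channel group, with four BH-FDR-corrected contrasts: vs.
profiles at peaks of phase-shuffled recall curves (surrogates preserving the
amplitude spectrum, hence autocorrelation; shuffles yielding < 2 peaks are
redrawn), hippocampus vs. other channels (independent t), run 2 vs. run 1
(dependent t), and run difference vs. shuffled differences; conjunctions of
the masks are reported.

## Synthetic generator

The generator is the package's study-condition definition, not a tuning
knob.  The shared stimulus-driven latent is low-pass-filtered Gaussian noise
(8 Hz cutoff at 100 Hz) scaled to unit variance, split into an
envelope-visible component (softplus of it is the nonnegative "audio
envelope") and a story component invisible to the envelope — so conditioning
on Z does not absorb the cross-run effect.  Channels are snr·latent + unit
AR(2) noise; on effect channels the run-2 latent is advanced by an exact
integer-sample shift (truncation, no interpolation), making planted lags
exactly recoverable.  Hippocampal channels add a copy of the latent inside
coupling windows; windows designate *cortical* event times and the copy is
active lag samples later, with the lag defined against the run's own
cortical signal (in run 2 the copy advances with the effect channels) — both
conventions are required for a planted −700 ms lead to surface at −700 ms.
Press logs place hits at boundary ± Gaussian jitter (run 2 advanced by
`advance_ms`, optionally with its own jitter SD — tighter run-2 responses
are the generator's model of consensus learning), plus uniform Poisson false
presses.  Word tables draw naive probabilities and per-word learning
increments from user-specified distributions (pipeline default: Beta(2,6)
naive probabilities, N(0.2, 0.15) increments, two groups of 50).  All
randomness flows from a single seeded generator per call with spawned
sub-streams; outputs are bit-identical across calls at a fixed seed.

What the synthetic data do **not** emulate: raw 512 Hz broadband recordings,
epileptic spikes beyond simple amplitude outliers, line noise, reference
artifacts, volume conduction, inter-patient heterogeneity of effect size and
coverage, or any semantic structure linking the word table to the neural
latent.  Passing tests therefore establish the estimators' correctness,
calibration, and recovery power under the assumed signal model — not that
real recordings satisfy that model.

## Problem sizes and runtime

Tests and the acceptance script run at desk scale, chosen so the full suite
finishes in a few minutes on one CPU: recordings of 12–32 channels × 120 s
at 100 Hz (VAR fits are stable from ≈ 60 s), 20 seeds pooled for the ΔF
recovery AUROC, calibration checks with 400 replicates of 100–200-permutation
tests, behavioral cohorts of 8–200 raters on 60–120 s stories.  The
default pipeline configuration mirrors these sizes; every stage seed derives
from the single config seed.

## Known limitations

- One model order is shared across both directions and (by default) across
  channels of a recording; per-channel orders are available but slower.
- The GMM channel selection assumes a two-population structure of ΔF; with
  a tiny or absent effect population it degrades to near-arbitrary splits
  (the pipeline falls back to top-ΔF channels if the selected set is empty).
- The cluster statistic sums MI, so its power depends on the MI scale of the
  ROI; the conventional t-mass variant is available via the returned t-map.
- Phase-shuffled surrogates preserve only second-order structure; for
  strongly non-Gaussian recall curves the peak-count distribution of
  surrogates can differ from the original.
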