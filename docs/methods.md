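# Methods

`achda` re-implements, as a tested pipeline, the computational analyses used
to study striatal dopamine (DA) and acetylcholine (Ach) dynamics while mice
perform a probabilistic two-armed bandit task (2ABT).  In-vivo recordings of
this kind are not publicly archived, so every analysis is exercised
end-to-end on a synthetic-data generator whose statistical structure — and,
crucially, whose ground truth — is known.  This note describes the models,
the generator, the numerical choices, and what passing the validation
studies does and does not establish about real data.

## Task model

Mice self-initiate trials at a centre port and choose a left or right side
port.  One side is the high-reward-probability port (`p_high`, default
0.95); the other rewards at `1 - p_high`.  After 30 rewards the high side
reverses (a "block").  The simulator (`achda.task`) draws full event
streams: centre entry/exit, the centre-to-side transit, side occupancy,
licks and reward delivery (triggered by side entry on rewarded trials),
followed by a 1 s inter-trial interval plus exponential jitter.

Latency distributions are not published for this task, so the simulator
uses log-normal latencies for centre occupancy (median 0.15 s) and the
centre-to-side transit (median 0.5 s), outcome-dependent log-normal side
occupancy (median 1.5 s rewarded, 0.5 s unrewarded), a Poisson lick train
(8 Hz) during reward consumption and at most one lick on unrewarded trials.
Blocks advance on cumulative *rewards*, not trials; choice-window timeouts
are generated with probability zero (the schema supports an aborted flag).

## RFLR choice model

Choices are coded left = −1, right = +1.  The recursively formulated
logistic regression keeps a decaying evidence trace and a perseveration
term:

    phi_{t+1} = c_t r_t + exp(-1/tau) phi_t
    psi_t     = alpha c_{t-1} + beta phi_t,     P(c_t = +1) = logistic(psi_t)

`alpha` weighs repeating the last action, `beta` weighs accumulated
action–reward evidence, and `tau` (trials) sets how fast evidence decays.
Fitting profiles the Bernoulli log-likelihood over a log-spaced `tau` grid
(25 points in [0.25, 10]); at fixed `tau` the model is an ordinary logistic
regression in `[c_{t-1}, phi_t]` (statsmodels, no intercept — the model has
no side-bias term).  The grid optimum is refined by bounded 1-D
optimisation between its neighbours.  Trials without a predecessor are
excluded from the likelihood.  Degenerate sessions (one repeated choice)
return a non-converged fit rather than raising.

Validated by parameter recovery: an agent with (alpha, beta, tau) =
(1, 2, 1.5) over 10,000 trials is recovered within 10% on each parameter,
and a choice-randomised agent yields |z(beta)| < 2.

## Synthetic photometry generator

`achda.synth` builds each channel as a linear superposition of per-event
kernels plus structured noise:

* **Kernels** — difference-of-Gaussians per event on a lag axis (default
  support −0.5 to +2 s), amplitudes placed so z-scored traces span roughly
  [−3, +4].  Side-entry, reward and lick kernels are forced causal
  (responses follow, never precede, the event).
* **Amplitude rules** — per-(channel, event) gains keyed by reward outcome
  and by the eight (stay/switch × previous outcome × current outcome)
  history labels.  Defaults encode a reward-prediction-error-like ordering:
  unrewarded trials flip the DA side-entry transient into a dip and enlarge
  the Ach excursion; unexpected wins ("lose–win") boost both.
* **Trial-to-trial variability** — multiplicative amplitude jitter per
  event (sd 0.2) and a slow band-limited intrinsic fluctuation per channel
  (sd 0.3, < 2 Hz).  Without such variability in the *clean* DA signal,
  noise-correlation analyses would have nothing to recover: the coupling
  would only shift condition means.
* **Coupling** — Ach(t) −= g · DA_clean(t − delta), default g = 0.5,
  delta = 108 ms (two 54 ms bins; the physiological value is ~100 ms, which
  is not a multiple of the sample period and is snapped with a warning).
  The coupling acts on the noiseless DA signal so recovery is well-posed;
  options couple to the noisy trace or act divisively.  A gate can zero
  g(t) inside a per-trial epoch (e.g. 0–1 s after side entry), emulating
  the transient disappearance of the DA–Ach interaction at reward
  evaluation.
* **Drift and noise** — slow sinusoids (< 0.01 Hz) exercise the dF/F
  baseline logic; white observation noise (sd 0.05) is added last.
* **Carriers** — optionally the two envelopes are amplitude-modulated onto
  167 and 223 Hz sinusoids at 2 kHz with a positive offset, for testing the
  lock-in path.

The generator default sampling rate is two samples per 54 ms analysis bin,
so bin-mean alignment onto the analysis grid never leaves empty bins.  One
master seed spawns independent substreams per channel, for the observation
noise and for the drift.

## Preprocessing

* **Demodulation** — quadrature lock-in: multiply by sine and cosine
  references at the carrier, low-pass each (4th-order Butterworth at 15 Hz,
  forward–backward so zero phase), return `2*sqrt(I^2 + Q^2)` so a pure
  tone of amplitude A returns A.  Round trip on ≤ 10 Hz envelopes at the
  167/223 Hz pair recovers r > 0.999 with ~0.01% RMS crosstalk.
* **dF/F** — `(F − F0)/F0` with a 10th-percentile running baseline over a
  30 s window by default (robust to transients, window ≫ trial duration);
  non-positive baselines are an error naming the offending samples.
* **z-score** — per session.  Unit transitions (raw → dF/F → zscore) are
  recorded on the trace and invalid orderings refused.
* **Alignment** — bin-mean aggregation (no interpolation, preserving the
  noise statistics the covariance analyses use).  Epoching is index-based:
  the alignment timestamp is snapped to the nearest sample, so when the bin
  width is a whole number of sample periods every trial's bins aggregate
  identically-phased samples.  This matters: continuous-time bin anchoring
  lets the discretisation phase vary per trial and perturbs both channels
  coherently, which masquerades as cross-channel correlation.  Edge trials
  whose window leaves the session are dropped, never zero-padded.

## Trial metrics and LDA

Mean DA is the mean z-scored signal in a window relative to side entry;
delta-Ach is max − min in a window (the Ach transient is multiphasic, so an
excursion metric beats the mean).  Group comparisons collapse to per-mouse
condition means *first*, then run a paired two-sided t-test across mice, so
results are invariant to per-mouse trial counts.  LDA classifies trial type
from the binned waveform with stratified 5-fold CV, a shrinkage covariance
estimator when bins exceed one fifth of the trials, and an option to
balance classes by subsampling (used in the validation studies so chance
is 50%).  Significance of an accuracy is judged against a label-permutation
null.

In the dissociation study the analysis windows are chosen as whole numbers
of 54 ms bins on each side of side entry so that no bin straddles t = 0; a
straddling bin contains post-event samples and would leak outcome
information into the "pre" window.

## Encoding GLM

Binary event regressors on a 54 ms grid are expanded into T = 20 shifts
forward and backward (F(2T+1) columns; positive lag = the event influences
later signal).  Only bins from 1 s before centre entry to 1 s after side
exit are modelled ("shortly before/after" is not quantified in print; 1 s
is configurable).  Where consecutive trials' spans overlap, the overlapped
bins are included once in each trial; each copy keeps its own trial's group
key, so trial-grouped splits never divide a trial but duplicated bins can
appear in both halves — the overlap fraction is computed and logged per
run, as in the original protocol.

Cost functions: OLS `||y − Xb||²`; ridge adds `alpha ||b||²`; elastic net
`(1/2N)||y − Xb||² + alpha (lambda ||b||_1 + (1−lambda)/2 ||b||²)` with
lambda = 1 giving lasso.  The ridge and elastic-net alphas are on different
scales; `enet_to_ridge_alpha` converts (`alpha_ridge = N · alpha_enet` at
lambda = 0).  OLS/ridge solve penalised normal equations with an
unpenalised intercept (rank-deficient systems fall back to a least-squares
solve of the Gram system); lasso/elastic net use coordinate descent
(tol 1e−6, max 10,000 iterations).

Evaluation: per run, a 50/50 trial split; a 10-fold group shuffle split
(80–20) on the training half gives the validation MSE as the mean of the
concatenated squared residuals; the model is refit on the whole training
half and scored on the test half; Y runs with fresh splits.  Leave-out
analysis drops one feature's 2T+1 columns at a time on identical splits;
for OLS/ridge the per-fold Gram matrix is computed once on the full column
set and each leave-out solve reuses a column subset.  Kernels are the mean
(± sd) coefficients across runs; reconstructions report trial-averaged
predictions with a bootstrap-over-trials 95% CI.

Kernel-recovery validation uses generator kernels confined to the GLM's
±1.08 s lag window: a kernel extending past the window cannot be recovered
by any encoding model, so the comparison would otherwise measure window
truncation, not estimation quality.  With 300 trials and noise sd 0.1, OLS
recovers the kernels with RMSE ≈ 2% of the largest kernel amplitude.

## Covariance analyses

Sign convention, fixed once and asserted in tests: **positive lag means DA
(channel A) leads Ach (channel B)** — covariance at lag l pairs A(t) with
B(t + l), so a delayed negative DA→Ach interaction produces its most
negative covariance at l = +delta.  Raw mode centres each channel by its
session mean; noise mode subtracts condition-specific trial-averaged
waveforms.  Lagged values average over trials and the overlapping bins only
(no zero padding).  K(t1, t2) is the trial-averaged outer product of the
centred channels; its off-diagonal at offset delta is the band mean of
K(t1, t1 + delta ± w).  Covariance (not Pearson) is the default; the
circular-shift null re-draws an independent random shift per trial, the
session-swap null re-pairs channel B trials across sessions.

Null bands come in two flavours: pointwise per-lag 2.5/97.5 percentiles,
and a simultaneous (max-statistic) band — percentiles of the
per-permutation extremes across lags — which controls the family-wise rate
for "any lag outside" statements.  The validation studies use the
simultaneous band: with ~13 lags the pointwise band flags some lag in a
third of null datasets, which is the expected multiplicity, not a defect.

**Stationarity caveat.**  Cross-covariance analysis assumes the mean and
variance are stable across the window.  When event-locked transients carry
trial-to-trial variance (amplitude jitter, latency jitter, neighbouring
trials' kernels reaching into the window), the two channels are genuinely
correlated through shared behavioural events even with zero direct
coupling, and the circular-shift null — which destroys the event alignment
— becomes anti-conservative.  This is precisely the failure mode that
motivates the two-dimensional K(t1, t2) treatment.  The coupling-recovery
studies therefore run on a stationary generator configuration (no event
kernels; intrinsic fluctuations + coupling + noise); lag recovery is
additionally confirmed with side-entry-locked kernels present, where the
argmin is unchanged.  Passing these studies shows the estimators recover a
known lagged interaction under the analysis' stated assumptions; it does
not license the circular-shift null on strongly non-stationary real data.

## Validation study conditions

Defined in `achda.studies`, shared verbatim by the test suite, the
acceptance script and the analysis drivers: kernel recovery (300 trials,
noise sd 0.1, OLS, Y = 3); leave-out (250 trials, Y = 10; lick kernel
zeroed, side-entry kernel tripled); history GLM (300 trials, Y = 3;
side-entry history gains spanning 0.5–1.8×); coupling lag (500 trials,
g ∈ {0, 0.5}, delta ∈ {54, 108, 216} ms, 300 permutations); gated coupling
(gate = 0–1 s post side entry); RFLR recovery (10,000 trials);
block-transition dynamics (40,000 trials — about 1,000 transitions, enough
to resolve the P(switch) peak location against its shallow plateau);
demodulation (60 s at 2 kHz); metric dissociation (8 mice × 250 trials,
outcome gains confined to causal post-side-entry kernels with ≤ 0.8 s
support so post-trial tails decay before the next trial's pre-window).

## Known limitations

* The generator is linear; real sensor kinetics (dLight vs rDAh affinity
  and speed), photobleaching, motion and haemodynamic artefacts are out of
  scope, so passing studies do not certify robustness to those.
* The eight-way history modulation acts only on side-entry amplitudes;
  real history effects also move latencies and shapes.
* Per-session z-scoring and per-session RFLR fits are fixed choices; both
  are flagged for sensitivity analysis rather than explored here.
* The t-test "non-significant pre-window" checks assert a true null: under
  repeated seeds they fail at the nominal 5% rate by construction.
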