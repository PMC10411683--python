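# Methods

`thetaconflict` analyzes EEG recorded while people resolve motivational
conflicts — choices between two desirable options (approach–approach, AP-AP)
or two undesirable ones (avoidance–avoidance, AV-AV). This note documents the
models and procedures the package implements, the synthetic-data generator it
is tested against, and the numerical and design choices that were genuinely
open.

## Task model

Each valence has a set of personal-characteristic labels (seven by default).
Conflicts are all C(n, 2) unordered pairs within a valence: 21 AP-AP and 21
AV-AV conflicts at n = 7. A block presents every pair of both types once in
seeded-random order (42 trials), and the task runs seven blocks (294 trials).
Per trial: a 750 ms fixation, the two labels side by side (left/right by an
independent fair coin) until the response, then an inter-trial interval drawn
uniformly from {1500, 2000, 2500} ms. The labels themselves are configurable
strings, not shipped content.

Behavioral analysis: trials whose RT deviates more than 3 s.d. from the
participant's mean RT are excluded (a single pass per participant, using that
participant's all-trial mean and s.d.; the operation is not re-iterated, so
re-applying it with recomputed statistics may exclude further trials — by
design it is applied once). Condition means are compared with a one-sided
paired t-test, t = mean(d)/(sd(d)/sqrt(n)), df = n−1, with Cohen's d for
paired data defined as mean(d)/sd(d) (the classical d_z). The a-priori power
analysis inverts the noncentral-t power function of the paired test
(ncp = d·sqrt(n)); d = 1, alpha = .05, 80% power, two-sided gives n = 10.
Sidedness of that power analysis was an open choice; two-sided is the default
because it reproduces the canonical n = 10, and one-sided is a flag.

## Synthetic cohort

The generator produces, per participant, a continuous multichannel recording
(512 Hz native; 2048 Hz mode exists to exercise the downsampler) and a
behavioral table, plus the injected ground truth:

* **Background**: 1/f^k noise (k = 1 by default, 10 μV rms broadband) made by
  spectral shaping of white noise with seeded phases, independently per
  channel.
* **Theta bursts**: on every trial a 5.5 Hz tone under a raised-cosine
  envelope spanning 0–3000 ms post-stimulus is added at FCz, with random
  phase. The trial's theta level in dB is the condition mean plus a Gaussian
  trial deviation (sd 2 dB); burst amplitude is 10 μV · 10^(dB/20).
* **RT coupling**: RT = condition intercept + participant intercept
  (sd 1000 ms) ± half a participant-level condition-effect deviation
  (sd 800 ms) + slope·(theta − condition mean theta) + Gaussian noise
  (sd 1000 ms), floored at 200 ms. Condition intercepts default to
  5774 ms (AV-AV) and 4601 ms (AP-AP); slopes to −205 and −94 ms/dB. Because
  the slope acts on the *within-condition* theta deviation, the configured
  intercepts are the expected condition means.
* **ERP deflections**: Gaussian bumps (default: −2 μV at 300 ms on FCz,
  +2.5 μV at 700 ms on Pz), identical across conditions.
* **Artifacts**: square 200 μV transients of 150 ms on a seeded ~5% of
  trials, placed within the first second post-stimulus — the kind of
  transient that moving-window peak-to-peak rejection targets. Ocular/ICA
  artifacts are deliberately not modeled.

Stimulus onsets are laid out sequentially (fixation + RT + ITI), with the
onset-to-onset gap floored at 5200 ms by stretching the ITI so that every
trial supports the full −1000..4000 ms analysis epoch; configuring a floor
shorter than the epoch span is a configuration error.

Two free parameters are not constrained by any published quantity and were
fixed once: the background noise scale (10 μV rms, a realistic scalp-EEG
magnitude) and the condition gap in injected theta (4.0 dB). The gap is
calibrated — as the generator's declared purpose — so that the recovered
condition effect gives the n = 29 paired test high power and a positive
recovered difference in ≥90% of participants; at 1.5 dB the post-recovery
participant-level effect (attenuated by the noise floor) is only d ≈ 0.6.
This gap is a property of the synthetic cohort, not a claim about effect
sizes in recorded EEG.

**What the generator does not emulate**: volume conduction and realistic
topographies, eye movements and blinks, line noise and electrode drift,
non-Gaussian RT shapes, and condition differences in ERP components. Passing
recovery tests therefore demonstrates that the analysis chain is correct and
well calibrated under its assumed signal model, not that it would detect
effects of any particular size in recorded data.

## Preprocessing

Filters are zero-phase (forward–backward) Butterworth, order 2 per pass. A
digital Butterworth designed at cutoff f_c has amplitude 1/sqrt(2) there, so
the two passes land the half-amplitude (−6 dB) point exactly at f_c; the
requested 0.1 Hz (high-pass) and 30 Hz (ERP low-pass) cutoffs are honored
without pre-warping. Downsampling uses an anti-alias FIR and integer
decimation; event indices rescale by floor division. Average reference
subtracts the mean over all non-EOG channels.

Epoch windows are half-open [start, end) in ms with sample offsets
floor(ms·rate/1000) and 0-based indexing: −500..2000 ms at 512 Hz is exactly
1280 samples, −1000..4000 ms is 2560. Stimulus-locked ERP epochs are
baseline-corrected to −500..0 ms. Response-locked epochs for the CRN use
[−500, 500) ms (a window-size choice; only the −50..+50 ms measurement
interval is standard) and are baselined to their own full-window mean.

Artifact rejection flags a trial when max−min inside any 100 ms moving
window exceeds the participant's threshold on any monitored (non-EOG)
channel. The window step (50 ms default, half overlap), the monitored set,
and the thresholds themselves are not pinned down by convention, so all are
configuration values; a dense every-sample mode serves as the exact variant
and as the test oracle, and a calibration helper picks the threshold whose
realized rejection rate is closest to a target (default 15%). Participants
with strictly more than 25% rejected trials are excluded. Flags set on the
ERP epochs propagate by trial id to the long and response-locked epochs of
the same recording.

## Time–frequency decomposition

38 frequencies log-spaced 3→40 Hz; cycle counts log-spaced 3→8. Each complex
Morlet kernel has Gaussian s.d. σ_t = cycles/(2πf), is truncated at ±4σ_t,
and is normalized to unit energy (L2). Truncation and normalization are
choices: unit energy makes amplitudes comparable across frequencies, at the
cost of a slight (one-grid-bin) low-frequency bias of the raw power argmax —
irrelevant to the dB-normalized quantities the analysis uses. Power is
|signal ⊛ kernel|² at full time resolution; the FFT-based convolution is
checked against direct time-domain convolution to relative 1e-6. The long
epochs keep the 0–3000 ms analysis window more than 4σ_t from the epoch edge
even at 3 Hz.

Baseline normalization: dB(t) = 10·log10(power(t)/baseline), where the
baseline is, per frequency, the mean over all pre-stimulus timepoints
(−1000..0 ms) of the condition's trial-averaged power. Single-trial values
use the same condition-level baseline by default so they remain finite and
comparable; per-trial baselining is a flag. Theta is summarized over the 13
grid bins whose centers lie in [3.2, 7.7] Hz (inclusive) and timepoints in
[0, 3000) ms: the condition-level scalar is the *sum* of dB values over that
region (computed from the condition-averaged map), the single-trial
predictor for the RT model is the band–window *mean* in dB (same information
per trial, interpretable units of ms/dB downstream), and the band-averaged
dB time course per condition feeds the cluster test.

## ERP components

Averages are pointwise means over non-rejected trials of a condition (no
trial-count equalization), low-passed at 30 Hz after averaging. N2: minimum
in 250–350 ms at FCz, stimulus-locked. CRN: minimum in −50..+50 ms at FCz,
response-locked. LPC: mean amplitude over 650–750 ms at Pz. Peaks are plain
windowed extrema, ties broken earliest; an extremum on the window edge is
flagged rather than rejected. Conditions are compared with two-sided paired
t-tests on amplitude and (for peaks) latency.

## Inference

**Condition-level theta**: one-sided paired t (AV-AV > AP-AP) on the
participant × condition theta sums.

**Cluster-based permutation test** on the theta time course: pointwise
paired t across participants; contiguous runs with |t| above the two-sided
t-critical value at the cluster-forming alpha (default .05, df = n−1) form
clusters scored by summed t; the null distribution is the maximum |cluster
sum| under per-participant random sign flips of the condition difference
(the exchangeable transformation for paired data). Corrected p-values use
(1 + #{null ≥ observed})/(n_perm + 1); with `exact=True` all 2^n sign
patterns are enumerated (n ≤ 16) and p is the exact permutation proportion.
Forming threshold, permutation count (default 1000) and analysis window are
conventions, all configurable.

**Single-trial mixed model**: RT ~ theta + conflict + theta×conflict with a
Gaussian random intercept per participant, REML. Theta and RT are grand-mean
centered and conflict is coded ±0.5 (AV-AV = +0.5), so the theta coefficient
is the average within-condition slope and the interaction is the AV−AP slope
difference. Estimation profiles the variance ratio λ = σ_b²/σ_e²: for fixed
λ the GLS fixed effects and σ_e² are closed-form via the Woodbury identity
on the block-compound-symmetric covariance, leaving a 1-D REML criterion
minimized over log λ (grid bracket + bounded scalar search, with the λ = 0
boundary — plain OLS — checked explicitly and flagged when optimal). This
profiled estimator is the package's reference implementation; tests verify
it against a general-purpose REML estimator to 1e-4 on coefficients.
Fixed-effect p-values use a t distribution with n_obs − n_fixed degrees of
freedom — a deliberate, documented simplification relative to
Satterthwaite-style approximations; with thousands of trials per cohort the
difference is negligible. The CI for the random-intercept variance is Wald
on the log scale from a finite-difference Hessian of the REML criterion.

## Numerical conventions and degenerate inputs

Microvolts and milliseconds throughout; 0-based sample indexing; half-open
windows; band membership by bin center, inclusive. A paired test on
identical samples returns t = 0 (one-sided p = 0.5); a constant nonzero
paired difference raises a degenerate-input error. Zero or negative baseline
power raises an error naming the frequency. Rejection flags are monotone:
set, never cleared. All randomness flows from explicit seeds
(`numpy.random.Generator`; per-participant streams spawned from the cohort
seed), and the pipeline report is byte-identical across runs at a fixed
config + seed.

## Problem sizes in the shipped checks

The test suite and the acceptance script run reduced cohorts chosen as the
package's own verification sizes: null calibration uses 500 replicates of 12
participants × 40 trials (statistics computed on generator ground truth, no
EEG synthesis needed); the full-chain detection check uses 10 cohorts of 12
participants × 42 trials; mixed-model recovery uses 20 replicates of 29
participants × 200 trials with a generator matched to the model
(participant condition-effect spread set to 0 so the random-intercept
variance has a defined true value). The full 29 × 294 design runs through
the same code path via `examples/config.yaml`.

## Known limitations

Single-channel theta quantification (FCz) only; no topographic statistics,
phase measures, or source analysis. No ICA or channel interpolation. The LMM
supports a single random intercept — no random slopes or crossed effects.
The BDF writer emits plain 24-bit BDF without an embedded Status/trigger
channel; events travel as a BIDS-style TSV alongside. Recovered single-trial
theta is attenuated relative to injected dB by the noise floor, so slope
magnitudes estimated from recovered theta are biased toward zero
(measurement-error attenuation); recovery tests of coefficient values
therefore use ground-truth theta, while pipeline-level tests assert signs
and ordering.
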