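# Methods

This note records the model assumptions, parameter choices and known
limitations behind `roicsp`. It complements the README, which states
the method itself.

## Preprocessing

Continuous EEG is average-referenced, band-pass filtered to 7–15 Hz,
resampled to 100 Hz and epoched 0.5–3.5 s after the visual cue, in that
order. The band covers the mu rhythm and low beta, where event-related
desynchronization (ERD) lives. Choices the pipeline fixes:

- **FIR design.** Hamming windowed-sinc, transition width
  `min(3.5 Hz, low/2, (Nyquist − high)/2)`, tap count `⌈3.3·fs/Δf⌉`
  (odd), applied forward–backward for exactly zero phase. The tap count
  is capped at a third of the recording length (with a logged warning)
  so short recordings remain filterable. Passband ripple is well under
  1 dB; stopband attenuation exceeds 40 dB after the two passes.
- **Resampling.** Polyphase with the rational ratio
  `Fraction(fs_out/fs).limit_denominator(1000)`; output length is
  `⌊n·fs_out/fs⌋` and event indices are rescaled by rounding. No extra
  anti-alias filter is needed after the 7–15 Hz band-pass. A constant
  signal survives to within the resampler's passband ripple (~1e-4
  relative).
- **Epochs** are 0-based, half-open `[cue+offset, cue+offset+duration)`;
  any event whose window leaves the recording raises an error naming it.
- No automatic bad-channel or artifact handling; an exclusion list can
  be applied upstream.

## Head model and inverse

The inverse solver needs only a gain matrix and a noise covariance, so
both are pluggable. The bundled surrogate lead field is an analytic
dipole-like model, `gain ∝ (o_d · u_cd)/r²` with a conductivity-dependent
global scale — deliberately *not* a boundary-element solution, but it
preserves what the decoder relies on: linearity, distance falloff, fixed
perpendicular orientations, and distinct spatial signatures per source
patch. Conductivities default to 0.33/0.0042/0.33 S/m
(scalp/skull/brain).

- **Noise covariance**: sample covariance of the resting baseline plus
  diagonal loading of 5% of the mean diagonal (unit scale if the sample
  covariance is all-zero), guaranteeing positive definiteness. The
  loading fraction is exposed; published wMNE practice varies and the
  decoding results are insensitive to it in the tested range.
- **Regularization**: `λ² = 1/SNR²` with an assumed amplitude SNR of 3,
  the common convention when the true value is unknown. Exposed in
  `InverseConfig`.
- **Depth weighting**: exponent 0.5 by default (0 recovers plain MNE;
  1 fully normalizes lead-field columns). Minimum-norm solutions
  without depth weighting localize superficial sources preferentially;
  the localization test uses exponent 1 for exactly this reason.
- The whitened and unwhitened formulations are algebraically identical
  and agree to 1e−8 in tests; one inverse operator is computed per
  session from the resting baseline.

## CSP details

- Per-trial covariances are channel-mean-removed and trace-normalized
  (standard CSP practice; removes global amplitude drift across
  trials). Class covariances get a ridge of 1e−8 of the mean diagonal.
- The generalized eigenproblem is solved by whitening the composite
  covariance (eigh of `Σa+Σb`, then eigh of the whitened `Σa`), which
  avoids explicit inversion. Eigenvector signs are fixed by making the
  largest-magnitude component positive; filters are scaled so
  `w (Σa+Σb) wᵀ = 1`.
- The "rest" covariance in one-vs-rest is the unweighted mean of the
  other classes' mean covariances.
- **Tiny inputs.** When the input dimension `n` cannot support the
  `2K` stacked OVR filters, the stack is reduced to at most
  `n(n+1)/2` filters — the greedy choice keeps the most discriminative
  (largest `|λ−½|`) mutually non-collinear rows, with at least two rows
  always retained and a warning logged. Rationale: log-variance
  features of `k` directions in an `n`-dimensional space carry at most
  `n(n+1)/2` degrees of freedom (the trial covariance itself), so
  capping at `n` would discard usable covariance-shape information
  while anything beyond `n(n+1)/2` is redundant.
- Feature normalization follows the global-`L` reading of the
  log-normalized-variance definition: one normalization over all `L`
  filter outputs of the multiclass model, so `Σ_p exp(v_p) = 1`.

## LDA, ranking and the vote

- LDA uses class means, a pooled within-class covariance and empirical
  priors; optional shrinkage pulls the pooled covariance toward its own
  diagonal, `S(s) = (1−s)S + s·diag(S)`. The default is plain LDA
  (`s = 0`); desk-scale experiments on few-filter ROIs pass 0.05, which
  only matters when features are few or collinear.
- ROI ranking runs stratified 10-fold CV, re-randomized per repeat by
  reseeding the fold shuffler; CSP filters *and* LDA are refit inside
  every training fold, so held-out trials can never influence the
  fitted models (asserted bitwise in tests). Ties in the ranking keep
  catalogue order, making selection deterministic.
- Majority vote: modal class over the selected ROIs' predictions; ties
  go to the class with the largest summed LDA score over the tied
  classes across all voters, residual ties to the smallest class label.
- Alternative per-ROI classifiers (kNN with k=5, Gaussian naive Bayes,
  unlimited-depth decision tree) are available behind the same CV
  harness for the classifier-comparison experiment; defaults are
  ordinary library defaults.

## Synthetic sessions: what they emulate, and what not

Each cortical patch (ROI) carries one band-limited 8–13 Hz waveform —
white noise filtered by a 4th-order zero-phase Butterworth — shared
coherently by the patch's dipoles, plus independent per-dipole 1/f
background (amplitude 0.3 relative to the oscillation). In a class-`k`
trial the active patch's oscillation amplitude is scaled by
`1 + erd_depth` (default −0.5, i.e. ERD); sensors see `G D` plus white
noise at a per-channel power SNR (default 5). A resting baseline with
no modulation is emitted for covariance estimation. Everything is
deterministic per seed.

Patch coherence is the physiologically standard picture — EEG is
measurable at all because neighbouring pyramidal populations fire
synchronously — and it is also what makes band power *estimable*: a
3 s epoch of 5 Hz-wide noise provides only ~30 effective samples per
variance estimate, and with fully independent per-dipole oscillations
that estimation noise drowns the class signal at any geometry we
tested.

The default toy world (16 channels, 48 dipoles, 24 two-dipole patch
ROIs) exercises every code path cheaply. The **benchmark world** used
by the recovery experiments (`make_benchmark_session`) enlarges this to
120 dipoles — five per ROI, so each region supports the full 8-filter
OVR CSP — on a fixed "template anatomy" (world seed 1), mirroring how
the real method shares one template head model across subjects. The
four modulated regions (SMA_L, M1H_L, S1H_L, CMA_R — the sensorimotor
nodes decoding studies most consistently select) sit at moderate mutual
distances: close enough that each is visible to the others through
inverse leakage (every selected ROI then carries multi-class
information, which the majority vote needs), far enough that the
ranking can still tell them apart. Benchmark sessions use
`erd_depth = −0.8` and SNR 100: an intentionally separable instance,
so that recovery failures indicate pipeline defects rather than an
unlearnable task.

What the generator does **not** emulate: time-resolved ERD envelopes,
non-stationarity, artifacts (EOG/EMG), spatially structured sensor
noise, or realistic electrode montages. One consequence is worth
stating plainly: with a linear forward model and *white* sensor noise,
the sensor data is statistically sufficient for the source data, so the
sensor-space CSP baseline is never systematically worse than the source
pipeline on these simulations — both saturate on the benchmark. The
empirical source-over-sensor advantage reported on real recordings
stems from exactly the real-data properties this generator omits;
passing synthetic tests therefore validates correctness and parameter
recovery, not the real-data superiority claim. The corresponding test
asserts what does hold: the inverse step costs at most a few accuracy
points.

## Problem sizes

Desk-scale experiments use: benchmark sessions of 4 × 72 trials at
100 Hz × 3 s; 10-fold outer CV with the complete ensemble (ranking with
10-fold × 3 repeats, selection, refit) fit inside each training fold;
ROI recovery over 20 replicate sessions; solver oracles on 6 × 6
covariance pairs (100 000 random directions) and inverse systems up to
16 × 40. The full suite runs in ~2 minutes on one core, the acceptance
script in ~1 minute.

## Known limitations

- The surrogate lead field is not a BEM; absolute source amplitudes and
  inter-regional gain ratios are not physical.
- ROI catalogues ship as explicit vertex lists; no anatomical atlas
  integration.
- The published per-subject benchmark tables bundled under
  `roicsp/data/` are inputs for the comparison utilities' worked
  examples; reproducing them requires the external competition
  recordings, which this package treats as optional input
  (GDF ingestion via `mne`), not as a dependency.
- Single-session decoding only: no transfer learning, no online use.
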