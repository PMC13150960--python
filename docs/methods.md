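# Methods

This note records what the pipeline computes, the choices made where the
underlying methods literature leaves room, and what the synthetic benchmark
does and does not establish.

## Signal model and preprocessing

Recordings are 4-channel (EEG Ch1, EEG Ch2, EOG Ch1, EOG Ch2) time series in
µV, already referenced to a nose electrode, nominally 250 Hz. The QC chain
applies a 0.3–35 Hz band-pass and a 59–61 Hz band-stop, both 4th-order
Butterworth run forward-backward (zero phase, so effectively 8th order; the
filter family and order are this package's choice — standard sleep-EEG
practice with a testable frequency response). The notch runs before
downsampling, while the line frequency is still below Nyquist. Downsampling
to 100 Hz is polyphase (anti-aliased); detection and spectral analysis happen
at 100 Hz.

### Artifact detection

The recording is cut into non-overlapping 5-s windows; a trailing partial
window carries no flag and is excluded from analysis (a short window would
bias the variance estimate). Per window a single scalar is computed,
`m = log(ε + mean over channel pairs |cov|)` with ε = 10⁻¹², then z-scored
across all windows of the night; windows with |z| > 3 are excluded everywhere
downstream (detector inputs, PSD segments, density denominators). The log
makes the statistic scale-free (a global gain shift moves every `m` equally,
leaving z unchanged — asserted by test) and maps flatline windows to the far
negative tail. One scalar per window is a deliberate simplification of
"covariance metrics"; it is recorded here as this package's definition. With
all windows identical the z-scores are defined as 0 and nothing is flagged.

### Retention gate

A night is kept when it holds ≥5 h of recording, or is shorter while wrist
actigraphy concordantly reports <300 min of sleep (a short night, not a
device failure). The gate sees only duration and actigraphy; corrupted
long recordings are caught by the artifact mask and, in the cohort driver, by
staging misalignment.

## Event detectors (EEG Ch1 only)

### Slow oscillations

Signal: 0.5–1.5 Hz band-passed. Candidates are pairs of consecutive
down-going zero crossings enclosing a negative then a positive half-wave;
duration is the time between the bounding down-crossings, kept in [0.5, 2] s;
amplitude is trough-to-peak. A candidate becomes an event when its amplitude
exceeds the 75th percentile of the night's candidate pool (pooled per night
and channel within NREM; night-level pooling because detection runs per
recording). The full candidate pool is exposed for audit, and a test recomputes
the rule from it.

Consequence worth knowing: the percentile rule keeps the top quartile of
*whatever the pool is*. In 0.5–1.5 Hz-filtered background noise, zero-crossing
candidates in the accepted duration range occur at tens per minute, so the
detector's *total* density is dominated by this floor (~13/min on the default
synthetic background) regardless of how many true SOs were injected.
Recovery of injected events is therefore validated by matching detections to
ground truth: matched density tracks the injected rate times the fraction of
injected events whose amplitude clears the pool percentile. Group contrasts
in total SO density are only detectable when the groups differ in the
amplitude distribution, not just the rate — which is why the synthetic
cohort's SO-density row is null by construction.

### Spindles

Signal: 12–16 Hz band-passed. A 0.3-s RMS envelope is computed in 0.1-s
steps over the artifact-free epochs of one stage (N2 or N3); the threshold is
that stage's mean + 1.5·SD of the RMS series, recomputed per night (data-
derived, hence scale-invariant; events are included in the statistics — a
single pass, no iteration). An event is a maximal run of suprathreshold
windows whose *exceedance span* — the time between the first and last
suprathreshold window position, (k−1)·0.1 s — lies in [0.5, 2] s. Runs may
cross epoch boundaries of the same stage; a sub-threshold dip splits runs
(no merging).

The duration convention matters and is documented because the choice is a
knife-edge. Measured on 20-seed Monte-Carlo noise (both 1/f and white):

| convention | noise false positives | recall at 3× background |
|---|---|---|
| covered span ((k−1)·0.1 + 0.3 s) | ~8.6/min | 0.98 |
| exceedance span, inclusive bounds | ~0.55/min | 0.97 |
| exceedance span, strict lower bound | ~0.25/min | 0.88 |

The covered-span reading is scientifically unusable (the false-positive floor
would exceed typical true densities). The package uses the exceedance span
with inclusive bounds — the literal reading of "exceeded the threshold for
0.5–2 s" — accepting a noise floor of ~0.55/min: true 0.5-s bursts and the
longest noise runs coincide at span ≈ 0.5 s, so no convention removes the
floor without sacrificing short-burst recall. Spindle-density *contrasts*
between groups are unaffected (the floor is common), which the end-to-end
cohort benchmark confirms.

## Spectral summaries

Welch PSDs use 4-s Hann windows with 50% overlap (0.25-Hz resolution, enough
to resolve the 0.5-Hz delta edge); excluded spans contribute no segments
because callers pass stage-concatenated artifact-free samples of 0.5–45 Hz
band-passed signal. Relative power normalizes by the summed power over
δ/θ/α/β only. Composite NREM delta is the N2/N3 duration-weighted average.
The QC spectrogram is multitaper (DPSS): 6-s windows, 0.25-s step,
time-halfbandwidth 3, 5 tapers — configurable defaults in the usual range for
sleep spectrogram review. Delta SNR compares mean delta power over
artifact-free sleep epochs after onset (first non-wake epoch) against
pre-onset wake epochs, on EEG Ch1 (configurable; which channel the original
analyses used is not pinned down).

## Macro summaries and aggregation

TST = 0.5 min × sleep epochs (N1+N2+N3+REM); TIB = full recording duration
(patch-on to patch-off, the device-observable proxy — diary bed/wake times
are not modeled); SE = 100·TST/TIB. Stage percentages are shares of TST (the
published group means sum to ~100 under that convention). Per-participant
values are unweighted means over usable nights, skipping nights where a
metric is undefined (count recorded). The retention ledger splits
participants by whether they contributed any usable night: losses among
zero-usable participants are reported as integer percentages of their
scheduled nights; for the rest, usable nights are a share of nights with
device use (one decimal) and loss categories are shares of scheduled nights.
"Device use" counts every night except not-worn/not-connected ones.

## Statistics

U counts young-over-old pairs with ties half-counted (midranks); the reported
statistic is centered, U_c = U − n₁n₂/2, matching the published convention
(which takes negative and half-integer values). Exact two-sided p-values
(the U distribution under exchangeability) when there are no ties and both
n ≤ 25; otherwise a normal approximation with tie-corrected variance and no
continuity correction (the exact convention is not recoverable from 2-decimal
published p-values; this default is configurable in spirit but fixed here).
Effect size r = U_c/(n₁n₂/2); its 95% CI is Fisher-z with
SE = √((n₁+n₂+1)/(3n₁n₂)) — the classical large-sample SE of a rank
correlation, and the only standard interval that reproduces all ten published
CIs to 3 decimals. No multiple-testing correction across rows (none was
applied in the source analyses); the table footer says so.

## Synthetic cohort generator

The generator produces what the pipeline needs to see, not physiology:

- **Hypnogram**: wake latency, then NREM→REM cycles (N1, N2, N3, return-to-N2,
  REM, brief awakening), N3 dwell decaying and REM growing across cycles,
  truncated-normal dwell draws clipped to [0.5, 1.5]× the mean. Dwell means
  were calibrated by Monte-Carlo (100 seeds, 8-h nights) so group means track
  the published stage shares: young ≈ SE 82%, N1 3%, N2 59%, N3 18%, REM 20%;
  old ≈ SE 78%, N2 71%, N3 10%, REM 15% — old N3 about half of young.
- **Background**: per-channel independent 1/f Gaussian noise (frequency-domain
  synthesis, flat below 0.5 Hz), RMS scaled per epoch by stage (W 15, N1 12,
  N2 12, N3 20, REM 10 µV). Real EEG channels are correlated; independence is
  a simplification noted below.
- **Events**: N3 slow oscillations as one 0.75-Hz sine period starting at the
  down-phase (negative-then-positive by construction, satisfying the
  detector's zero-crossing rules), peak-to-peak 150 µV ± 20% jitter, 5/min;
  N2 spindles as Tukey-windowed 12–15 Hz bursts, durations U[0.5, 1.5] s,
  envelope peak 10 µV, 3/min young vs 1/min old (about one third, mirroring
  the published ratio); REM as opposite-polarity EOG deflections; wake as
  10-Hz alpha plus occasional common-mode movement bursts (which the
  covariance mask should catch). Events on one channel never overlap (≥1-s
  gap) so ground-truth matching is unambiguous.
- **Between-participant heterogeneity**: multiplicative LogNormal(σ=0.15)
  factors on dwell means and event rates, chosen once; the generator exists
  to give recovery tests a detectable effect, not to model population
  variance.
- **Data loss**: `not_worn` yields no recording; `bluetooth` truncates below
  the 5-h gate; `poor_reference_adhesion` corrupts spans (flatline and
  broadband noise on all channels — the reference is common to all) and ends
  the record under 5 h, so the gate rejects it.

Nights are generated independently (no first-night effect, no night-to-night
correlation), channels carry no ECG/respiration, and the spectral shape is a
bare 1/f — so passing tests demonstrate that the *pipeline* recovers what was
injected under realistic SNR, not that the detectors are validated against
human-scored recordings.

## Problem sizes used in tests and walk-throughs

Tests run nights of 1–2 h at 100 Hz and the cohort walk-through uses 4-h
nights, 12 participants per group, 3 nights each — sizes chosen so the whole
suite completes in a few minutes while keeping every statistic comfortably
away from small-sample degeneracy. Two visible artifacts of the scaling:
half-length nights over-represent early-night N3 (the walk-through's N3%
means sit above the 8-h calibration targets), and every scaled night passes
the 5-h gate only through the actigraphy-concordance branch. Neither affects
the group contrasts.

## Known limitations

- The trained sleep-staging classifier is not re-implemented; the naive
  stager keys N2 on spindle bursts and therefore under-calls N2 in
  low-spindle (e.g. older) sleep. On default young synthetic nights it agrees
  with the true hypnogram at ~75%; treat it strictly as a test double.
- The SO 75th-percentile rule's candidate-pool floor (above) makes absolute
  SO densities generator-dependent.
- The spindle detector's ~0.55/min noise floor is inherent to a single-pass
  amplitude-only threshold at mean + 1.5 SD with 0.5-s minimum duration.
- EDF support is plain EDF (16-bit, 1-s records, one sampling rate);
  EDF+ annotations are out of scope. The patch CSV dialect (header `# fs=`,
  `sample_index` + channel columns, suffix-ordered rotation files, NaN-filled
  gap sentinels with spans recorded in metadata) is this package's own
  definition — the deployed app's schema is unpublished.
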