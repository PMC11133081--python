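# Methods

This note documents the models, procedures, parameter choices, and known
limitations of `vocscram`. It states only what the package computes and what
its test suite verifies.

## Problem setting

Studies of vocal affect need control stimuli that remove emotional meaning
from a recording while keeping selected low-level acoustic properties
intact. `vocscram` implements three families of such *scrambling*
manipulations (one of them at two time scales, giving four conditions), a
pitch estimator used to parameterize one of them, and a nonparametric
equivalence analysis for deciding whether scrambled stimuli are rated as
neutrally as genuinely neutral originals.

## Audio representation and preprocessing

Audio is a frozen `AudioSignal(samples, sample_rate)` with float64 samples.

- **Peak normalization** rescales to a maximum absolute amplitude of 0.99
  (not 1.0, leaving headroom against clipping after 16-bit quantization).
  Every scrambler normalizes its input first and, by default, its output,
  so loudness is equated across conditions.
- **WAV I/O** uses 16-bit PCM by default. Integer samples are mapped to
  float via division by 2^15; writing rounds `samples * 2^15` and clips to
  the int16 range, so a round trip is exact to within one quantization step
  (1/2^15). Multi-channel files are averaged to mono.
- **Amplitude envelope**: magnitude of the analytic signal (Hilbert
  transform) smoothed by a zero-phase 4th-order Butterworth low-pass at
  50 Hz (`sosfiltfilt`). 50 Hz keeps syllable-rate modulation while
  removing carrier ripple; zero-phase filtering avoids envelope lag.
- **Power spectral density**: Welch's method, Hann window, default segment
  length 1024 samples, `detrend=False`.

## Pitch estimation

Frame-wise normalized autocorrelation:

- Frames of 40 ms with a 10 ms hop (long enough to hold ≥ 3 periods of a
  75 Hz voice; hop standard for prosody tracking). Search range 75–2000 Hz.
- The autocorrelation is computed by FFT and normalized as
  r(τ) = acf(τ) / sqrt(E_head(τ) · E_tail(τ)), which keeps r in [−1, 1]
  regardless of amplitude decay within the frame.
- A frame is **voiced** when its best peak exceeds 0.45 and its RMS exceeds
  1% of the loudest frame's RMS (silence gate). 0.45 separates harmonic
  from noise-like frames on the synthetic material with margin; the gate
  prevents pitch readings from near-silent pauses.
- **Octave guard**: among candidate peaks, the shortest lag whose height is
  at least 0.95 × the global best is chosen, preventing halving errors.
  The lag is refined by parabolic interpolation over three points, then the
  frequency is clipped to the search range.
- `median_pitch` is the median F0 over voiced frames and raises with a
  request for an explicit threshold if no frame is voiced.

On synthetic harmonic bursts spanning 90–400 Hz the estimator recovers the
generating F0 to well within 2% (observed max error < 0.01%).

## Scrambling methods

All methods consume a seeded `ScrambleParams`; the same seed always yields
the same output. `scramble()` returns the output plus a `Provenance` record
(method, parameters, seed, and — for phase scrambling — the pitch threshold
used), which the CLI writes as a JSON sidecar.

### Frequency scrambling

Destroys spectral structure per short-time window while keeping each
window's magnitude multiset and energy.

1. Normalize; trim the signal to a whole number of hop steps; zero-pad one
   hop at each end.
2. Slide a 1024-sample periodic Hann window with a 512-sample hop
   (50% overlap — the constant-overlap-add condition: the shifted windows
   sum to 1 over the retained region). At 44.1 kHz this is a ~23 ms window,
   fine enough to keep the broadband envelope.
3. In each window, take the rFFT and randomly permute the *positions* of
   the positive-frequency coefficients (bins 1 … N/2−1). DC and Nyquist are
   never moved so the inverse transform stays real. The rebuilt window is
   rescaled to the original tapered window's RMS.
4. Overlap-add without any window-sum division (COLA makes it exact), crop
   the padding, and rescale once globally to the trimmed input's energy.

The zero-pad + global-rescale design avoids the edge instability of
dividing by the pointwise window sum, which is near zero at the edges while
scrambled content is not. With the identity permutation the pipeline
reproduces the normalized input to < 1e-6.

### Phase scrambling

Destroys temporal structure above the voice's pitch while exactly keeping
the magnitude spectrum (hence total energy).

- One rFFT over the whole signal. The threshold defaults to the signal's
  `median_pitch`; bins at or below it (plus DC and Nyquist) are untouched,
  so the fundamental's phase relations survive. Phases of all bins above
  the threshold are permuted among those bins; magnitudes stay in place.
- Because only phases move, the sorted magnitude spectrum is preserved to
  machine precision.

### Time scrambling

Destroys temporal order at a chosen granularity while conserving duration
exactly.

- The signal is cut into windows of 6 ms or 12 ms (two standard
  granularities; a trailing remainder shorter than the window is kept as
  its own window). Windows are shuffled with the seeded generator.
- Each window gets 1 ms linear on/off ramps (clipped to half the window if
  the window is very short) to suppress concatenation clicks, then the
  windows are concatenated. Output length equals input length for any
  input; the ramps strictly reduce energy before renormalization.

## Equivalence analysis

The question is whether valence ratings of a scrambled condition are
*equivalent* to ratings of original neutral stimuli, not merely
non-different — so two one-sided tests (TOST) are used.

- **Unit of analysis**: per-participant condition means
  (`participant_condition_means`), one value per participant ×
  manipulation × valence category.
- **Margin δ**: by default the sample standard deviation (ddof = 1) of the
  reference condition's per-participant means — a data-driven margin of
  "one between-participant SD". Callers may pass a fixed δ.
- **Test**: for paired differences d (condition minus reference, matched by
  participant), Wilcoxon signed-rank on d − δ with alternative "less" and
  on d + δ with alternative "greater". Equivalence is declared iff both
  p < α (default 0.05). An all-zero difference vector is a degenerate case
  and returns p = 1 with a warning. A parametric paired-t TOST is provided
  as a cross-check.
- **Interval**: percentile bootstrap CI of the mean paired difference,
  default 10 000 resamples, seeded.
- **Table**: `equivalence_table` runs the 12 comparisons (4 scrambled
  manipulations × 3 valence categories) against the original-neutral
  reference, in a fixed order. Participants missing either member of a
  pair are dropped from that comparison and counted in `n_missing`.
  No multiple-testing correction is applied by default — TOST is already
  conservative and the comparisons are reported jointly; a Bonferroni
  option (`bonferroni=True`) divides α by the number of comparisons.

Calibration verified by simulation: with the true mean exactly at the
margin, the one-sided rank test rejects at ~5% (nominal level); the 95%
bootstrap CI covers the true mean ~94–95% of the time.

## Ratings pipeline

Trial records carry participant, stimulus, valence category, manipulation,
apparency (1–4), gender response, integer valence rating (0–100), rating
type and listen count. Loading validates every row and returns violations
(with CSV line numbers) separately rather than failing. Branching logic is
enforced: apparency 1–2 implies a "reaction" rating and no gender response;
apparency 3–4 implies an "expression" rating and a gender response in
{female, male, not_identifiable}.

**Participant exclusion**: a participant is excluded when the range of
their per-valence-category mean ratings of *original* stimuli is below 10
points — i.e. they do not differentiate clearly positive from clearly
negative originals on the 0–100 scale, so their ratings carry no valence
signal. Participants with no original trials are kept with a warning.

Summaries (`valence_summary`, `gender_accuracy`) emit empty design cells
explicitly with n = 0 instead of silently dropping them.

## Synthetic data

The generator exists to exercise the pipeline end to end with known ground
truth; it does **not** aim at perceptually realistic affect bursts.

- **Stimuli**: 10 speakers (5 female, 5 male) × 3 valence categories;
  durations drawn from 0.24–2.61 s; F0 from 170–280 Hz (female) or
  95–160 Hz (male); 44.1 kHz. Each burst is a harmonic complex of up to 8
  harmonics with 1/k amplitude rolloff.
- **Archetypes** capture coarse acoustic signatures only: *neutral* — flat
  F0, smooth attack/release; *happiness* — 4–6 voiced segments separated by
  ≥ 30 ms pauses with F0 rising across segments (so the median pitch of a
  happy burst sits above its base F0); *anger* — 1.5% random-walk F0
  jitter, 12% broadband noise, 5 ms attack, exponential decay.
- **Ratings**: `make_ratings` crosses participants × stimuli × 5
  manipulations and draws ratings around configurable cell means
  (`RatingEffectSpec`, rating SD 18 — wide enough that equivalence is a
  statistical question, not a foregone conclusion), with branching-valid
  apparency and gender responses and Poisson listen counts.
  `default_effect_spec` plants a pattern in which only the phase-scrambled
  neutral cell is equivalent to original neutral.

What it does not emulate: formant structure, microprosody, recording-chain
noise, speaker idiosyncrasies, or any perceptual validity of the planted
rating effects.

## Numerical choices

- float64 throughout; FFT sizes follow signal/window lengths (no implicit
  padding beyond the documented one-hop zero-pad).
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  nothing reads global RNG state.
- Energy and magnitude invariants hold to ~1e-13 relative or better;
  identity-permutation limits to < 1e-6 absolute (dominated by the peak
  renormalization, not the transforms).

## Limitations

- The pitch estimator targets clean, quasi-harmonic signals; breathy or
  creaky voice and strong noise may misclassify frames.
- Frequency scrambling discards up to one hop of trailing samples
  (< 12 ms at 44.1 kHz); time scrambling's ramps slightly attenuate window
  edges.
- δ-from-reference makes the equivalence margin sample-dependent; studies
  wanting a pre-registered margin should pass δ explicitly.
- The synthetic generator supports methodological validation only; no
  claims about human listeners follow from it.
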