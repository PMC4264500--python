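# Methods

`erdsbci` implements the signal-processing and statistics chain of a
cue-based EEG paradigm for detecting mental imagery and attempted
movements — the kind of protocol used to probe command following in
patients with disorders of consciousness — together with a synthetic EEG
generator that reproduces the paradigm's structure with known ground
truth. This note describes the models, the defaults and why they were
chosen, and what the synthetic validation does and does not establish.

## The paradigm

A session consists of runs of 15 cue-based trials of 12 s. A beep marks
trial start (t = 0); a verbal task cue arrives at t = 2 s; the 1–2 s
period (one second before the cue) is the reference interval. Trials are
separated by random pauses of 4–6 s. Three runs yield the canonical 45
trials per task. EEG is modelled after a 32-electrode montage over
frontal, central and parietal cortex sampled at 512 Hz (0.5 Hz high-pass,
100 Hz low-pass, 50 Hz notch in the acquisition metadata).

## Synthetic EEG generator

The generator is first-class, tested code: every downstream stage is
validated against the ground truth it emits.

* **Background**: Gaussian noise with power spectral density ∝ 1/f^γ
  (default γ = 1), synthesised in the frequency domain (random-phase
  spectrum shaped by f^(−γ/2), inverse FFT) for exact spectral control,
  scaled to 10 µV total RMS per channel.
* **Rhythms**: band-limited oscillations are band-passed white noise
  (4th-order Butterworth, 2 Hz bandwidth), not sinusoids, so band power
  fluctuates from trial to trial the way real sensorimotor rhythms do —
  this variance is what the bootstrap and the cross-validation are
  exercised against. Default baseline amplitude is 10 µV RMS, a clearly
  present idle rhythm over a 10 µV broadband background (≈ 4% of the
  power in a 2-Hz band at 10 Hz comes from the background).
* **ERD/ERS**: during each trial's modulation window (default: cue onset
  → trial end) the rhythm's amplitude is scaled by an activity factor
  with 0.25-s raised-cosine ramps against spectral splatter. A pure
  amplitude scaling by a factor a changes band power by a², so the
  implanted ERD/ERS percentage is (a² − 1)·100: factor 0.5 implants −75%
  ERD, √2 implants +100% ERS. The ground truth records these values.
* **Artifacts**: muscle-like transients are Hann-windowed 45-Hz tone
  bursts (default 0.2 s) with peak amplitude `amplitude_factor` × channel
  RMS, injected additively at annotated positions. The high-frequency
  morphology matters: a whitening filter calibrated on 1/f EEG amplifies
  high-frequency transients and suppresses smooth low-frequency bumps.
* **Resting state**: same background and rhythms at baseline amplitude,
  no modulation, no artifacts — the stationary process the AR detector is
  calibrated on. Idle rhythms are present at rest, as in real EEG.

Identical configuration and seed give bit-identical output; all
randomness flows through one `numpy` generator seeded from the config.

What the generator does **not** emulate: auditory evoked potentials of
the cue, volume conduction (channels have independent noise, so the
Laplacian derivation removes less common-mode activity than on real EEG
and slightly *increases* independent noise), realistic EOG/EMG spectra,
non-stationary vigilance drifts, and electrode artifacts other than
transients. Passing tests therefore demonstrate correctness of the
estimators under the stated signal model, not clinical performance.

## Spatial filtering and artifact rejection

**Laplacian derivation.** Orthogonal (Hjorth-style) Laplacian: each
center electrode minus the mean of its up/down/left/right neighbors on
the 10-10 grid. Edge channels keep whatever orthogonal neighbors exist;
centers with fewer than two neighbors are excluded from derivation and
passed through unfiltered. The operation is linear and purely spatial.

**AR inverse filter.** Per monitored Laplacian channel, an
autoregressive model (default order 10, Burg's method — stable on short
segments; the order and the monitored channel set are configurable) is
fitted on a resting segment of at least 10 s (default 90 s). The
whitening ("inverse") filter's prediction error on the resting segment
defines the residual RMS, and the detection threshold is exactly 5 ×
that RMS. A trial is rejected when the absolute prediction error exceeds
the threshold at any single sample on any monitored channel (strictest
reading; a minimum run-length is available for robustness studies). The
first `order` samples of each trial are excluded as filter transient.
Decisions use only the trial's own samples and the fixed calibration.

## ERD/ERS maps

Band power per trial is band-pass filter → square → 0.25-s moving
average. Offline maps use zero-phase (forward–backward) 4th-order
Butterworth filters so ERD latencies are not smeared; the online path
uses the causal variant. The default grid is 35 overlapping 2-Hz bands
with 1-Hz steps starting at 6–8 Hz, and the map is sampled every 0.25 s.

For each (channel, band, time) pixel,

    ERDS% = (Ā − R̄) / R̄ × 100,

with Ā the trial-averaged power at the pixel and R̄ the trial-averaged
power over the reference window. Pixels within 0.5 s of the trial edges
are excluded (filter settling).

**Significance** uses a studentized (t-percentile) bootstrap over trials
at α = 0.05, B = 1000 by default: trials are resampled with replacement,
the ratio statistic x̄/r̄ − 1 is studentized with a delta-method standard
error recomputed in each resample, and a pixel is significant iff the
(1 − α) interval excludes zero. Zero-variance pixels fall back to exact
comparison of the point estimate with zero. The mask is deterministic
under a fixed seed. No multiple-comparison correction is applied across
pixels — the conventional pixel-wise display for these maps — so ~5% of
null pixels are marked by construction; the type-I calibration test
checks exactly this rate.

## Features and classification

Features are log band powers in five canonical bands (θ 4–7, α 7–13,
β_L 13–19, β_M 19–25, β_H 25–30 Hz): causal band-pass, squaring, 1-s
trailing moving average computed sample by sample, log. Each 12-s trial
is tiled into twelve 1-s periods and one value is read at each period's
midpoint sample, so the feature at a midpoint depends only on samples up
to that point (tested causality). The 1–2 s period is the reference
class; each post-cue period is a candidate activity period, classified
against the reference separately (the per-segment framing of "accuracy
over different time periods relative to the reference").

**LDA** is Fisher's linear discriminant with pooled covariance,
w ∝ Σ⁻¹(μ₁ − μ₀), boundary at the pooled midpoint. The covariance is
shrunk toward a scaled identity (γ = 0.1) only when ill-conditioned or
when n < 2·dims; the production classification problems are
one-dimensional, where shrinkage is moot and the fit reduces to means
and a sign.

**Nested cross-validation.** Blocks are the runs of 15 trials. The
outer loop leaves one block out; the inner loop runs 10 repetitions of
10-fold CV on the training blocks, separately per (Laplacian channel,
band, segment), with the randomized fold assignments held constant
across all candidates so their inner accuracies are comparable. The
candidate with the best inner accuracy (ties: earlier segment, then
lower band, then channel order — deterministic, favouring earlier
detection) is trained on all training blocks and evaluated on the
held-out block; outer confusion matrices are summed (micro-averaged)
before computing the session accuracy. "10 × 10" is read as
10-times-repeated 10-fold CV. Initial single runs use leave-one-trial-out
outer folds instead. The headline (channel, band, segment) triple is the
inner selection re-run on all blocks (the usual final-model convention);
per-fold selections are retained so disagreement is visible.

**Significance of accuracy** is a one-sided exact binomial test of the
micro-averaged correct count against chance 0.5, reported with the
conventional 0.05 / 0.01 tags. It is uncorrected for the search over
channels × bands × segments; the nested outer loop keeps the accuracy
estimate itself unbiased, but a session-level permutation test (per-trial
class-role flips, available as `flip_mask`) is the appropriate corrected
check, and the chance-level control test uses exactly that machinery.

## Online feedback loop

The online path is strictly causal: causal IIR band-pass and trailing
1-s average on the selected Laplacian channel/band, per-sample LDA
prediction over the imagery period (default cue → trial end; the true
span patients sustained is unknown, so it is configurable). A trial is
answered "correct" iff the prediction is correct for strictly more than
50% of the imagery period and no artifact was detected; artifact-flagged
trials always get "pause". Per-sample predictions are not smoothed (the
rule taken literally; smoothing is exposed as configuration). Because
only successes are announced, the feedback is biased; each outcome
records the true correct fraction so the bias is quantifiable.

After each run the classifier is recalculated from the up-to-three most
recent runs (leave-one-trial-out when only one exists, nested block-wise
otherwise). The session controller continues iff the latest
cross-validated p-value is at or below the threshold (default 0.05);
clinical contingencies (fatigue, vigilance) are reduced to a manual
override hook.

## Numerical choices and problem sizes

* EDF I/O: plain EDF, 1-s records, 16-bit samples, ±200 µV physical
  range (quantization ≈ 0.006 µV); events travel in a sidecar CSV; the
  final partial record is zero-padded. Sample indexing is 0-based and
  windows are half-open, so a 12-s trial at 512 Hz is exactly 6144
  samples and tiles into twelve 512-sample segments.
* Log features are floored at 1e-30 before the logarithm (unreachable
  for non-degenerate signals).
* Validation runs use compact sub-montages centred on Cz (6 channels for
  map-level checks, 9 for classification) and 45-trial sessions — large
  enough for every statistical check while keeping the whole validation
  suite fast on a single CPU. Monte-Carlo checks use 20 seeds or 20
  permutations; bootstrap B = 1000.

## Known limitations

* The bootstrap is calibrated per pixel; neighbouring pixels share data
  through overlapping bands and smoothing, so significant pixels come in
  clumps, as on real maps.
* With independent per-channel noise the Laplacian derivation cannot
  demonstrate its real-world common-mode rejection benefit; it is tested
  for algebraic correctness, not for SNR gain.
* The binomial session p-value treats the two samples a trial
  contributes (reference + activity) as independent; on strongly
  autocorrelated real EEG this is optimistic, which is why the
  permutation control is provided.
* The ICA-based offline cleaning of the original protocol requires human
  visual component inspection and is out of scope; the algorithmic AR
  detector is used for both branches here.
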