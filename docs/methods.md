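# Methods

This note documents the models, conventions and design choices behind
`vds`, in the order data flows through the pipeline. Time is measured in
seconds from recording start, samples are 0-based, epoch *k* covers the
half-open interval [4k, 4(k+1)) s, and all signal amplitudes are in µV.

## Acquisition preprocessing (`vds.io`)

Raw signals are zero-phase band-pass filtered (Chebyshev Type II,
applied forward–backward with `sosfiltfilt`, so the effective response
is the squared magnitude with no phase distortion) and resampled to
256 Hz by rational polyphase resampling. Passbands are 0.5–120 Hz for
EEG/LFP and 10–45 Hz for EMG. Only the passband edges are fixed by the
acquisition convention; the transition bands are our choice: stopband
edges at half the lower passband edge and ~1.15–1.5× the upper edge
(capped just below Nyquist), minimum filter order for 40 dB stopband
attenuation and at most 3 dB passband deviation. Chebyshev II has a
flat, monotonic passband, which makes preprocessing near-idempotent:
re-filtering an already preprocessed 256 Hz signal changes its RMS by
less than 1%.

EDF files are 16-bit with one 1-s data record per second. The writer
sets each channel's physical range to its data range padded by 5% (to
maximise 16-bit resolution), rounds those limits to the 8-character EDF
header fields, and digitises against the *rounded* values, so the
round-trip error is bounded by one quantization step,
(phys_max − phys_min)/65535. Reading goes through `mne`, which gives an
independent decoding path for the round-trip check. When a two-arm
study is written, both arms share a per-channel physical range (the
union of both arms' data) so that their identical pre-injection samples
remain identical after quantization.

Pose CSVs use the three-header-row layout of pose-estimation exports
(scorer / bodyparts / coords) with x, y, likelihood columns for the
four cardinal pupil points. Readers reject rather than coerce: unknown
state tokens, missing bodyparts and non-numeric values raise with the
offending token and file row.

## Vigilance-state scoring (`vds.scoring`)

Scoring operationalises the standard visual criteria for rodent sleep
on 4-s epochs:

- **wake** — high EMG tone;
- **NREM** — low EMG with high-amplitude frontal slow activity
  (0.5–4 Hz);
- **REM** — low EMG with occipital theta (7–12.5 Hz) dominating delta;
- **micro-arousal** — a 1–4-epoch waking intrusion flanked by
  (NREM, NREM) or (REM, NREM); runs of ≥ 5 epochs remain wake.

Features per epoch: EMG RMS; frontal SWA envelope (mean magnitude of
the analytic signal of the 0.5–4 Hz filtered trace); occipital theta and
delta band power (zero-phase third-order Butterworth band-passes); and a
saturation indicator (≥ 3 consecutive samples pinned at the recording
extreme). The decision rules are total and deterministic, with wake
(EMG) checked first — so drug-window epochs that carry sleep-like slow
waves but waking muscle tone score as wake — and the REM check preceding
the NREM check; any remaining non-wake epoch defaults to NREM. The
theta-dominance threshold is 1.5 (ratio of occipital theta to delta
power).

**EMG threshold calibration.** Epoch EMG RMS is strongly bimodal
(sleep vs waking tone). The wake threshold `emg_hi` is the geometric
midpoint of the two clusters found by a deterministic 2-means split of
log EMG RMS; `emg_lo` is 0.8 × `emg_hi`, so both thresholds sit inside
the sleep–wake gap. We initially used fixed percentiles of the RMS
distribution, but a fixed percentile encodes an assumed time-in-state
mixture and lands inside a state cluster whenever the recording's
actual mixture deviates (short recordings, drug conditions), costing
10–15 percentage points of accuracy; the cluster split is invariant to
the mixture. A 60th-percentile fallback covers degenerate
(near-constant) EMG.

Micro-arousal refinement re-evaluates joint wake/micro-arousal runs and
is iterated to fixpoint (reached in ≤ n passes; in practice one), so an
epoch mistakenly relabelled on an earlier pass is corrected. Refinement
conserves epoch count and only ever exchanges wake and micro-arousal.

Artefact flags are per epoch and per derivation: saturation, or a
robust z-score of the epoch's peak amplitude above 6 (median/MAD
scaling). Flags exclude epochs from spectral analyses but never change
the state label.

## Spectra, aperiodic slope, phase–amplitude coupling (`vds.spectral`)

Per-epoch spectra are Hanning-windowed periodograms of 1024-sample
(4-s) epochs at 256 Hz: exactly 0.25 Hz bins, exported 0–120 Hz
(481 bins). Density scaling with the window-power correction makes
band-summed power equal signal variance (Parseval) for noise and, to
within 1%, for sinusoids. Band edges are inclusive on both sides (0.5
and 4.0 Hz both belong to SWA). Two theta conventions exist in the
sleep literature (7–12.5 Hz for state scoring, 6–9 Hz in aperiodic
work); the package default is 7–12.5 Hz, configurable per call.

The aperiodic "spectral slope" is an ordinary least-squares straight
line through log₁₀(power) against frequency *in Hz* over 20–120 Hz —
linear–log space, taken literally. Note this slope (log₁₀-power per Hz)
is *not* the 1/f power-law exponent χ, which is the slope in log–log
space; `estimate_background_exponent` performs the log–log fit over the
same range and is the function to use when the quantity of interest is
χ itself. Both fits use the centred OLS form, so a constant spectrum
yields a slope of exactly zero. Non-positive power inside the fit range
is an error, not silently masked.

The modulation index follows the entropy-based convention: zero-phase
third-order Butterworth band-passes for the phase and amplitude bands,
instantaneous phase and amplitude envelope from the analytic signal,
mean envelope in N = 18 phase bins normalised to a distribution P, and
MI = (log N − H(P)) / log N ∈ [0, 1]. The comodulogram evaluates MI on
a grid covering phase frequencies 1.5–10.5 Hz (1 Hz steps, ±0.5 Hz
bands) × amplitude frequencies 0.25–100.5 Hz (5 Hz steps, ±5 Hz bands);
steps and bandwidths are configuration values. MI is amplitude-scale
invariant, near zero (< 0.01 at 60 s) without coupling, and exactly 1
when all amplitude mass falls in a single phase bin.

## Slow waves and OFF periods (`vds.waves`)

The slow-wave filter is a zero-phase Chebyshev II band-pass with
passband 0.5–4 Hz and stopband edges 0.2/8 Hz (40 dB). A wave is a
maximal run of strictly positive samples of the filtered LFP, bounded
by zero crossings, accepted only when the immediately preceding and
following excursions both contain strictly negative samples. Onset and
offset are the (linearly interpolated) bounding zero crossings of the
positive excursion — the flanking sub-zero requirement is a gate, not
part of the span — amplitude is the positive peak of the filtered
signal, and duration is offset − onset. Whether "amplitude" should be
peak-to-trough and "duration" trough-to-trough is genuinely ambiguous
in the field; the half-wave definitions used here are the simplest
consistent reading and are what the tests freeze. Detection is
amplitude-scale equivariant, and a brute-force sample-by-sample scan
over sign changes is kept in the package as an independent oracle; the
two must agree event-for-event.

All detected waves feed the amplitude/duration distributions; only
waves whose peak strictly exceeds the mean + 2 SD (population SD) of
all detected amplitudes enter the multi-unit analysis. With equal
amplitudes the SD is zero and the strict inequality selects nothing —
intended. Waves are attributed to the vigilance state of the epoch
containing their peak.

The peri-event MUA profile counts spikes in 5-ms lag bins over ±500 ms
around each selected wave peak, averaged over events and converted to
Hz. The trough rate is the minimum-rate bin. For the trough *centre*
and *width* we use the contiguous region around the minimum where the
rate stays below half the outer-lag (|lag| > 300 ms) baseline: the
centre is the deficit-weighted centroid of that region and the width
its span. The naive alternatives (centre of the zero-count run, total
count of below-half bins anywhere) are dominated by single-spike
Poisson noise at the region edges and mis-estimate by 10–15 ms / tens
of percent at realistic event counts; the contiguous-region estimators
measure the same quantity with stable statistics.

## Pupillometry (`vds.pupil`)

Diameter per frame is (‖N−S‖ + ‖E−W‖)/2 over the four cardinal points,
and is missing unless **all four** likelihoods are ≥ 0.99 (the
strictest reading of a per-point confidence cutoff; anything less
distorts the geometry). Missing stays missing — no blink interpolation
by default; an optional linear interpolation across gaps ≤ 1 s is
provided but off. Units are pixels unless a calibration is applied;
all reported dynamics are percent of a baseline-window mean, hence
unit-free. Frame timestamps come from the nominal frame rate
(the hardware varies 45–55 fps; a constant nominal rate with an
optional offset is the documented approximation). The
pupil–EEG relation is an ordinary least-squares regression with
Pearson r² and a two-sided p-value; pairs with a missing member are
dropped, and fewer than 3 pairs or zero variance is an error.

## Endpoints (`vds.endpoints`)

Time-in-state tables count epochs × 4 s per interval, with
micro-arousal as its own category; a trailing partial interval is
included so the accounting conserves total recording duration. REM
latency is the time from injection to the start of the first REM epoch
at or after it, missing if none. Cumulative state curves are running
minutes sampled at interval ends (non-decreasing, final value = total).
A NREM *episode* — undefined quantitatively in the sleep literature we
follow — defaults to ≥ 15 consecutive NREM epochs (1 min) tolerating at
most one interrupting epoch; SWA dynamics are reported per NREM epoch
from the first qualifying post-injection episode onset, as percent of a
caller-supplied reference (typically the subject's baseline-day NREM
SWA mean).

Condition contrasts take per-subject mean power per 0.25 Hz bin, paired
across conditions, and run an uncorrected two-sided paired t-test per
bin, reporting maximal contiguous significant runs — the per-frequency
post-hoc convention behind "significance line" spectra panels. A
sign-flip permutation alternative is provided. Full mixed-effects
modelling is deliberately out of scope. Under the null (identical
conditions, normal noise) the per-bin false-positive rate matches the
nominal α to binomial accuracy; this calibration is exercised over 200
simulated cohorts of 8 paired subjects.

## The synthetic-study generator (`vds.synth`)

The generator produces the statistical structure the analyses assume,
plus its ground truth. All randomness flows from named substreams of a
single seed: identical configurations give byte-identical studies, and
two label sequences that share a prefix produce identical samples on
that prefix (per-epoch draws are generated for all epochs up front).

- **Hypnogram** — a semi-Markov chain over wake/NREM/REM with geometric
  bout lengths (means 120/120/60 s) and embedded transitions
  wake→NREM; NREM→wake 0.65, →REM 0.35; REM→wake 0.9, →NREM 0.1, so REM
  is entered only from NREM. These give long-run fractions of roughly
  45% wake, 47% NREM, 8% REM — realistic for a mouse over 24 h.
  Micro-arousals are inserted as brief high-EMG epochs inside NREM
  bouts (6/h); they are a scoring construct, so ground truth labels
  them MA and accuracy is measured excluding them.
- **Signals** — 1/f^χ background (χ = 2) made by frequency-domain
  amplitude shaping of white noise, flat below 0.5 Hz so the variance
  is not dominated by unobservable drift; EEG background 15 µV RMS, LFP
  10 µV. State-gated oscillations: 60 µV 1.8 Hz delta on frontal (×0.7
  occipital) in NREM; 30 µV (REM) and 20 µV (wake) 8 Hz theta on
  occipital. EMG is white noise with per-state RMS 40/15/6 µV
  (wake/NREM/REM; 45 µV in micro-arousals). Magnitudes are free
  parameters — per-state absolute magnitudes are not published for this
  preparation — chosen once to be plausible for mouse epidural EEG.
- **Slow waves / OFF periods** — NREM epochs are divided into 2-s
  slots; each slot hosts at most one biphasic wave template (0.5-s
  positive lobe between 0.35-s negative flanks, band-limited to the SWA
  filter, exactly time-symmetric about its renormalised peak so that
  detection-side refiltering does not bias the peak time) at a rate of
  20/min, with gamma-distributed amplitudes (mean 160 µV, shape 4).
  Each wave carries an OFF period: spikes of the homogeneous 30 Hz
  Poisson MUA train are deleted in an interval centred on the wave peak
  with duration N(150, 30) ms (configurable; truncated at 30 ms).
- **Drug window** — default 600–3300 s (injection at 10 min, 45-min
  effect). In the drug arm, window epochs are forced to wake
  (behavioural wakefulness with initial NREM/REM suppression — which
  also produces the increased-REM-latency endpoint); wake epochs fully
  inside the window receive added waves with coupled OFF periods on LFP
  (×0.8 frontal, ×0.5 occipital) at a rate proportional to
  `drug_swa_gain − 1`, so a gain of 1 is the identity, and the
  occipital theta-band component of those epochs is scaled by
  `drug_theta_gain` (default 0.4). A 1-s margin keeps the template
  support inside the window, so samples outside it are bit-identical.
  Because the added waves have NREM-like amplitudes against a weak wake
  delta background, wake SWA rises far more than 2× at the default
  gain — deliberately so: the emulated state shows wake slow waves of
  NREM amplitude, and `drug_swa_gain` is a rate dial, not a calibrated
  multiplicative factor on band power.
- **Pupil** — four points on a circle of the true diameter (40 px
  baseline, 2% slow physiological noise, 0.5 px coordinate jitter);
  5% of frames get one point with likelihood below 0.99. The drug arm
  adds a raised-cosine dilation transient starting at the injection,
  peak fraction 0.75, duration 720 s.

What the generator does **not** emulate: spindles and sharp-wave
ripples, transition epochs of mixed character, real artefact morphology
(chewing, electrostatic noise), scorer disagreement, non-stationary 1/f
exponents, correlated pupil–EEG dynamics, eyelid occlusion geometry,
or circadian structure. Passing tests therefore demonstrate the
*correctness of the computations* under the stated generative
assumptions, not scoring or detection performance on real recordings,
where class boundaries are less separable.

## Problem sizes and runtime choices

The validation suite exercises: detector–oracle equivalence on 1,000
random 60-s filtered signals; detection accuracy on a 30-min NREM-only
study (~600 injected waves); scoring on a full 24-h study (21,600
epochs); OFF-period geometry at configured durations 100/150/200 ms;
MI monotonicity over 100 seeded runs at four coupling depths; and
contrast calibration over 200 cohorts (96,200 paired tests). These
sizes give stable statistics while keeping the whole suite around a
minute of CPU; all of them scale up by changing one argument.

## Known limitations

- The scoring thresholds assume bimodal EMG; preparations with poor
  EMG separation (or pure-LFP studies) need explicit thresholds.
- The linear–log aperiodic slope is fit exactly as stated; if the
  intended convention was log–log, use the exponent estimator instead.
- EDF writing requires integer samples per second per channel and pads
  the trailing partial record with zeros.
- `spectra_contrast` treats subjects as exchangeable pairs and applies
  no multiple-comparison correction by design; interpret significance
  runs accordingly, or use the permutation option.
- The pupil transient and the EEG drug window have independent
  dynamics in the generator, so cross-correlating them on synthetic
  data is uninformative (near-zero r² by construction).
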