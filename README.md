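# vds — dissociated vigilance-state analysis

`vds` is an analysis pipeline for characterising *dissociated* brain states in
rodent electrophysiology: episodes in which sleep-like cortical slow waves and
neuronal silence coexist with behavioural wakefulness, muscle tone and pupil
dilation, as induced acutely by the short-acting psychedelic 5-MeO-DMT. It is
aimed at sleep/electrophysiology researchers who record frontal and occipital
EEG, nuchal EMG, cortical LFP with multi-unit activity (MUA), and eye-camera
pupillometry in freely moving mice.

The package covers the full desk-side workflow:

- **I/O and preprocessing** — EDF signals, plain-text spike lists,
  pose-estimation CSVs (DeepLabCut dialect); zero-phase Chebyshev Type II
  band-pass (0.5–120 Hz EEG/LFP, 10–45 Hz EMG) and polyphase resampling to
  256 Hz.
- **Vigilance-state scoring** — deterministic rule-based classification of 4-s
  epochs into wake / NREM / REM / micro-arousal from EMG tone, frontal
  slow-wave activity (SWA, 0.5–4 Hz) and occipital theta (7–12.5 Hz)
  dominance, with per-derivation artefact flags.
- **Spectral analysis** — Hanning-windowed per-epoch spectra at 0.25 Hz
  resolution (0–120 Hz), band-power time courses, the aperiodic spectral slope
  (straight line through log₁₀ P(f) vs f over 20–120 Hz), and the
  entropy-based phase–amplitude modulation index
  MI = (log N − H(P)) / log N over 18 phase bins.
- **Slow waves and OFF periods** — detection of LFP slow waves as positive
  deflections of the 0.5–4 Hz filtered signal between two flanking sub-zero
  deflections; selection of waves above the mean + 2 SD amplitude criterion;
  peri-wave MUA profiles quantifying the ~100–200 ms population OFF period
  centred on the wave peak.
- **Pupillometry** — pupil diameter as the mean of the north–south and
  east–west cardinal-point distances, keeping only frames where all four
  points have tracking likelihood ≥ 0.99; baseline-normalised time courses
  and pupil–EEG regression (Pearson r²).
- **Endpoints** — time-in-state accounting, REM latency, cumulative state
  curves, SWA dynamics from the first post-injection NREM episode, and
  per-frequency-bin paired condition contrasts with significance runs.
- **Synthetic studies** — a fully seeded generator that emulates the
  recordings (1/f^χ background, state-gated oscillations, graded EMG tone,
  injected slow waves with spike-silent OFF periods, a post-injection drug
  window with wake slow waves, theta suppression and a pupil transient),
  together with the ground truth every stage is validated against.

## Worked example

```python
import numpy as np
from vds import synth, scoring, spectral, waves, pupil, io as vio

cfg = synth.SynthConfig(seed=1, duration_h=1.0)       # injection at t=600 s
labels = synth.generate_hypnogram(cfg)
starts = np.arange(len(labels)) * cfg.epoch_s
in_win = (starts >= 600) & (starts + 4 <= 3300)
labels_drug = labels.copy(); labels_drug[in_win] = "WAKE"
rec, gt = synth.synthesize_signals(labels_drug, cfg)
rec = synth.apply_drug_effects(rec, labels_drug, cfg, ground_truth=gt)

hyp = scoring.score_recording(vio.preprocess(rec))
print(f"agreement with ground truth: {100*scoring.agreement(hyp.labels, gt.labels):.1f}%")

lfp = rec.channels["lfp"]
events = waves.detect_waves(waves.filter_swa(lfp.data, lfp.fs), lfp.fs, hyp)
big = waves.select_high_amplitude(events)
prof = waves.peri_event_mua(big, rec.spike_times)
print(f"slow waves: {len(events)} detected, {len(big)} above mean+2SD; "
      f"OFF trough {prof.trough_lag_ms:+.1f} ms, {prof.trough_rate_hz:.1f} Hz "
      f"vs baseline {prof.baseline_rate():.1f} Hz")

sp = spectral.epoch_spectra(rec, "frontal")
slope = spectral.fit_spectral_slope(sp.freqs, sp.power.mean(axis=0))
print(f"aperiodic slope (20-120 Hz): {slope.slope:.4f} log10-power/Hz")

trace, _, _ = synth.synthesize_pupil(cfg, drug=True)
trace = pupil.compute_diameter(trace)
_, pct = pupil.bin_timecourse(trace, 60.0, (0.0, 600.0))
print(f"pupil peak: {np.nanmax(pct):.0f}% of baseline (+{np.nanmax(pct)-100:.0f}%)")
```

prints

```
agreement with ground truth: 100.0%
slow waves: 4062 detected, 253 above mean+2SD; OFF trough +1.0 ms, 0.0 Hz vs baseline 29.5 Hz
aperiodic slope (20-120 Hz): -0.0141 log10-power/Hz
pupil peak: 175% of baseline (+75%)
```

The scoring recovers the generated hypnogram; multi-unit firing collapses to
zero at the peak of high-amplitude slow waves (the OFF period); and the pupil
dilates by the configured +75% at the peak of the drug transient.

The same pipeline is available from the shell:

```bash
vds simulate --seed 1 --out study/           # drug + vehicle arms (EDF, spikes, pose CSV)
vds score    --edf study/vehicle/recording.edf --out hyp.tsv
vds waves    --edf study/drug/recording.edf --spikes study/drug/spikes.txt --out events.csv
vds pupil    --pose study/drug/pupil.csv --out pupil.csv
vds report   --bundle study/ --out report/   # endpoint tables per arm
```

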