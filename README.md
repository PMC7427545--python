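# dualeeg

Tools for validating a consumer EEG headset against a research-grade
amplifier when both record the *same* brain activity simultaneously.

Low-cost, saline-electrode EEG systems are attractive for classrooms,
field work, and clinical screening, but their lower bit depth (14 vs 24
bits), slower and slightly drifting sampling rate (a nominal 128 Hz that
measures at 129.05 Hz), and hardware filtering raise the question of
whether they capture the same evoked and oscillatory signals as a
laboratory amplifier. `dualeeg` implements the full analysis loop used to
answer that question — and, because no raw dual recordings are needed, a
synthetic two-device acquisition model with known ground truth against
which every stage can be verified.

## What it does

- **Paradigm generation** — pseudo-random auditory oddball sequences
  (666 tones, 85%/15% standard/deviant, 10 blocks, ≥ 3 leading standards
  per block, 5–35 standards between deviants, SOA jittered uniformly on
  900–1,100 ms), a 300-trial upright/inverted face–watch task, a 14.36 Hz
  flicker schedule, and eyes-open/eyes-closed resting blocks.
- **Synthesis + acquisition** — ground-truth scalp signals (ERP templates,
  condition-gated oscillations, 1/f + white noise, Poisson blinks) recorded
  through two parametric virtual devices (rate, bit depth, input range,
  hardware band, marker jitter, sensor noise).
- **Preprocessing** — empirical rate estimation (samples/elapsed s),
  zero-phase 0.1–30 Hz Butterworth bandpass, polyphase resampling onto the
  slower device's *measured* rate, common-average re-referencing, and
  blink removal (windowed regression by default, FastICA optional).
- **ERP quantification** — −100…700 ms epochs with −100…0 ms baseline,
  the ±150 µV rejection rule harmonized across systems (a trial rejected
  in either recording is dropped from both), condition averages and
  difference waves, mean amplitude / extremum latency in pre-registered
  windows (MMN 100–200 ms at Fz, P300 280–380 ms at Pz, N170 120–220 ms at
  P7/P8), the post-hoc rule that centres a 100 ms window on the
  grand-average extremum, and ERP SNR = RMS(signal window) / SD(baseline).
- **Spectral analysis** — 5 s non-overlapping Hanning-taper FFT spectra in
  0.2 Hz steps, the neighbor-bin SSVEP SNR (each bin against the mean of
  the 20 surrounding bins, 10 per side, skipping the immediately adjacent
  bin) with z-scores thresholded at 1.96, and occipital alpha band power.
- **Agreement statistics** — waveform intraclass correlations, ICC(A,1)
  with McGraw–Wong 95% CIs; the default JZS Bayes-factor t-test (Cauchy
  prior, r = √2/2) evaluated by quadrature; a sequential stopping rule
  (BF checked from n = 20, stop below 0.33 or above 3.00); a contrast-based
  Bayesian 2×2 (system × condition) analysis; tie-corrected Wilcoxon
  signed-rank with exact enumeration at small n; Pearson topography
  correlations.

## Worked example

Simulate one dual-device passive-oddball session, preprocess both
streams, and compare the mismatch-negativity waveforms:

```python
import numpy as np
from dualeeg import paradigms, simulate, preprocess, erp, stats
from dualeeg.types import ParadigmSpec

spec = ParadigmSpec(paradigm_kind="oddball_passive")
schedule = paradigms.generate_oddball_sequence(spec, seed=7)
source = simulate.default_source_model("oddball_passive")
master = simulate.synthesize_scalp_signal(schedule, source,
                                          master_rate_hz=1024.0, seed=7)
rec_a = simulate.acquire(master, simulate.research_device(), seed=8)
rec_b = simulate.acquire(master, simulate.consumer_device(), seed=9)

rate = preprocess.estimate_sampling_rate(rec_b.n_samples, master.duration_s)
waves = {}
for name, rec in (("research", rec_a), ("consumer", rec_b)):
    proc = preprocess.preprocess_recording(
        rec, target_rate_hz=rate.estimated_rate_hz, seed=1)
    ep = erp.epoch_and_baseline(proc, ["standard", "deviant"])
    mask = erp.rejection_mask(ep)
    waves[name] = erp.difference_wave(erp.average_erp(ep, mask, "deviant"),
                                      erp.average_erp(ep, mask, "standard"))

m = erp.component_measure(waves["consumer"], "Fz", (100, 200), "negative")
icc = stats.waveform_icc(waves["research"], waves["consumer"], "Fz")
print(f"consumer MMN mean amplitude: {m.mean_amplitude_uV:.2f} uV")
print(f"between-system waveform ICC at Fz: {icc.estimate:.3f} "
      f"(95% CI {icc.ci95[0]:.3f}-{icc.ci95[1]:.3f})")
```

Output:

```
consumer MMN mean amplitude: -0.47 uV
between-system waveform ICC at Fz: 0.945 (95% CI 0.857-0.973)
```

The consumer device's difference wave carries the injected mismatch
negativity (a frontocentral negativity of order −1 µV after
common-average referencing), and the two systems' waveforms agree
point-for-point (ICC near 1 with a CI excluding zero) even though one was
quantized at 0.5 µV/bit and recorded at 129.05 Hz.

A full multi-participant study — five paradigms, two devices, agreement
statistics and stopping traces — runs from one seed:

```
dualeeg run-study --demo --seed 1 --participants 8 --out report.json
```

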