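# Full-scale study configuration: the complete validation design.
# Running this end to end simulates 20 participants x 5 paradigms at the
# full paradigm durations; use demo_study_config() for quick runs.
paradigms: [oddball_passive, oddball_active, n170, ssvep, resting]
n_participants: 20
seed: 0
master_rate_hz: 8192.0
band_hz: [0.1, 30.0]
ocular: regression
ssvep_duration_s: 120.0
stopping_min_n: 20
stopping_bounds: [0.33, 3.00]
paradigm_specs:
  oddball_passive:
    paradigm_kind: oddball_passive
    n_tones: 666
    deviant_fraction: 0.15
    n_blocks: 10
    min_leading_standards: 3
    min_gap: 5
    max_gap: 35
    soa_range_ms: [900.0, 1100.0]
    tone_freqs_hz: [1000.0, 1500.0]
    tone_duration_ms: 175.0
  oddball_active:
    paradigm_kind: oddball_active
    n_tones: 666
    deviant_fraction: 0.15
    n_blocks: 10
  n170:
    paradigm_kind: n170
    n_face_images: 75
    n_watch_images: 75
  ssvep:
    paradigm_kind: ssvep
    flicker_hz: 14.36
  resting:
    paradigm_kind: resting
    condition_durations_s: [180.0, 180.0]
devices:
  - name: research-1000
    nominal_rate_hz: 1000.0
    true_rate_hz: 1000.0
    bit_depth: 24
    input_range_uV: [-200000.0, 200000.0]
    hardware_band_hz: [0.01, 400.0]
    marker_jitter_ms: 0.1
    sensor_noise_uV: 0.2
  - name: consumer-129
    nominal_rate_hz: 128.0
    true_rate_hz: 129.05
    bit_depth: 14
    input_range_uV: [-4096.0, 4096.0]
    hardware_band_hz: [0.2, 45.0]
    marker_jitter_ms: 1.0
    sensor_noise_uV: 1.0
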