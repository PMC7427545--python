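"""Ground-truth scalp signal synthesis and two-device acquisition.

The source model is deliberately abstract: no head geometry, just
per-channel weight maps for each ERP component and oscillation, pink + white
background noise, and Poisson-scheduled frontal blinks.  Weight maps are
centred to zero mean across the montage so that common-average
re-referencing downstream is truth-preserving; blink maps are left
uncentred because ocular artifacts genuinely violate the zero-mean
assumption.

Acquisition applies, in order: the device's hardware band, polyphase
resampling to the device's *true* rate, mid-tread quantization over the
input range, additive sensor noise, and Gaussian marker jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .types import MONTAGE_16, DeviceModel, Event, EventSchedule, Recording

#: Default master simulation rate (Hz); both device rates resample cleanly.
MASTER_RATE_HZ = 8192.0


@dataclass
class ERPComponent:
    """Gaussian-envelope event-locked potential."""

    name: str
    event_labels: tuple[str, ...]
    latency_ms: float
    width_ms: float          # FWHM of the Gaussian envelope
    amplitude_uV: float
    polarity: int            # +1 or -1
    channel_weights: dict[str, float]

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("component width must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class Oscillation:
    freq_hz: float
    amplitude_uV: float
    channel_weights: dict[str, float]
    condition_gate: str | None = None   # gate by schedule interval label


@dataclass
class BlinkModel:
    rate_per_min: float = 12.0
    amplitude_uV: float = 120.0   # positive at the frontal pole
    duration_ms: float = 400.0
    frontal_weights: dict[str, float] = field(default_factory=lambda: {
        "Fp1": 1.0, "Fp2": 1.0, "F3": 0.45, "F4": 0.45, "Fz": 0.5,
        "FT7": 0.3, "FT8": 0.3, "Cz": 0.2, "CP3": 0.1, "CP4": 0.1,
        "P7": 0.05, "P8": 0.05, "Pz": 0.05, "O1": 0.02, "O2": 0.02,
        "Oz": 0.02,
    })


@dataclass
class SourceModel:
    erp_templates: list[ERPComponent] = field(default_factory=list)
    oscillations: list[Oscillation] = field(default_factory=list)
    pink_scale_uV: float = 4.0
    white_scale_uV: float = 1.0
    blinks: BlinkModel | None = field(default_factory=BlinkModel)


def _weight_vector(weights: dict[str, float], labels: tuple[str, ...],
                   center: bool = True) -> np.ndarray:
    w = np.array([weights.get(lab, 0.0) for lab in labels], dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("channel weights must be finite")
    if center:
        w = w - w.mean()
    return w


def _frontocentral() -> dict[str, float]:
    return {"Fz": 1.0, "F3": 0.8, "F4": 0.8, "Cz": 0.7, "Fp1": 0.5,
            "Fp2": 0.5, "FT7": 0.4, "FT8": 0.4, "CP3": 0.3, "CP4": 0.3,
            "Pz": 0.2}


def _parietal() -> dict[str, float]:
    return {"Pz": 1.0, "CP3": 0.8, "CP4": 0.8, "Cz": 0.7, "P7": 0.5,
            "P8": 0.5, "O1": 0.3, "Oz": 0.35, "O2": 0.3, "Fz": 0.2}


def _occipitotemporal(right_bias: float = 1.2) -> dict[str, float]:
    return {"P8": right_bias, "P7": 1.0, "O2": 0.6 * right_bias, "O1": 0.6,
            "Oz": 0.5, "CP3": 0.2, "CP4": 0.2}


def _occipital() -> dict[str, float]:
    return {"O1": 1.0, "Oz": 1.1, "O2": 1.0, "P7": 0.5, "P8": 0.5, "Pz": 0.4}


def default_source_model(paradigm_kind: str) -> SourceModel:
    """Study-condition source model for one paradigm.

    Amplitudes are typical adult scalp values: an obligatory auditory
    N1/P2 complex to every tone, a -2 uV mismatch negativity at ~150 ms for
    deviants, a +5 uV parietal P300 for attended deviants, a -4 uV N170 to
    faces (inverted faces delayed 7 ms and enlarged 20%), a 1 uV 14.36 Hz
    flicker response, and occipital alpha that grows from 1.5 to 5 uV when
    the eyes close.
    """
    model = SourceModel()
    k = paradigm_kind
    if k in ("oddball_passive", "oddball_active"):
        for labels in (("standard", "deviant"),):
            model.erp_templates += [
                ERPComponent("auditory_N1", labels, 100.0, 60.0, 1.5, -1,
                             _frontocentral()),
                ERPComponent("auditory_P2", labels, 200.0, 80.0, 1.8, +1,
                             _frontocentral()),
            ]
        model.erp_templates.append(
            ERPComponent("mmn", ("deviant",), 150.0, 80.0, 2.0, -1,
                         _frontocentral()))
        if k == "oddball_active":
            model.erp_templates.append(
                ERPComponent("p300", ("deviant",), 330.0, 150.0, 5.0, +1,
                             _parietal()))
    elif k == "n170":
        for ori, cat, lat, amp in (
                ("upright", "face", 170.0, 4.0),
                ("inverted", "face", 177.0, 4.8),
                ("upright", "watch", 170.0, 1.5),
                ("inverted", "watch", 172.0, 1.6)):
            model.erp_templates.append(
                ERPComponent(f"n170_{ori}_{cat}", (f"{ori}_{cat}",),
                             lat, 50.0, amp, -1, _occipitotemporal()))
        model.erp_templates.append(
            ERPComponent("visual_P1",
                         tuple(f"{o}_{c}" for o in ("upright", "inverted")
                               for c in ("face", "watch")),
                         100.0, 60.0, 2.0, +1, _occipital()))
    elif k == "ssvep":
        model.oscillations.append(
            Oscillation(14.36, 1.0, _occipital(), condition_gate=None))
    elif k == "resting":
        model.oscillations += [
            Oscillation(10.0, 1.5, _occipital(), condition_gate="eyes_open"),
            Oscillation(10.0, 5.0, _occipital(), condition_gate="eyes_closed"),
        ]
    else:
        raise ValueError(f"unknown paradigm kind {k!r}")
    return model


def _gaussian_template(comp: ERPComponent, rate_hz: float,
                       tmax_ms: float = 700.0) -> np.ndarray:
    """Component time course from stimulus onset to ``tmax_ms`` (1-D)."""
    t_ms = np.arange(int(round(tmax_ms / 1000.0 * rate_hz)) + 1) / rate_hz * 1000.0
    sigma = comp.width_ms / 2.3548200450309493  # FWHM -> SD
    return (comp.polarity * comp.amplitude_uV
            * np.exp(-0.5 * ((t_ms - comp.latency_ms) / sigma) ** 2))


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise per channel via spectral shaping."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * shape, n=n, axis=1)
    rms = pink.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return pink / rms


def _condition_intervals(schedule: EventSchedule, label: str,
                         duration: float) -> list[tuple[float, float]]:
    """Intervals [onset, next-event-onset) for boundary events named label."""
    out = []
    onsets = schedule.onsets
    for i, ev in enumerate(schedule.events):
        if ev.label == label:
            end = onsets[i + 1] if i + 1 < len(onsets) else duration
            out.append((ev.onset_s, float(end)))
    return out


def synthesize_scalp_signal(schedule: EventSchedule, source: SourceModel,
                            master_rate_hz: float = MASTER_RATE_HZ,
                            seed: int = 0, pad_s: float = 1.0) -> Recording:
    """Render the ground-truth 16-channel scalp signal for one schedule.

    The output is the superposition of event-locked component templates,
    condition-gated sinusoids, pink + white noise, and Poisson blinks.
    ``pad_s`` of silence is added before the first event and after the
    last so epochs around edge events never underrun the recording.
    Exact injected templates (post weight-centering) are stored in
    ``Recording.meta['ground_truth']`` so recovery can be scored.
    """
    max_osc = max((o.freq_hz for o in source.oscillations), default=0.0)
    if max_osc and master_rate_hz < 4.0 * max_osc:
        raise ValueError(
            f"master rate {master_rate_hz} Hz risks aliasing the "
            f"{max_osc} Hz oscillation (need >= 4x)")

    labels = MONTAGE_16
    n_ch = len(labels)
    n = int(round((schedule.duration_s + 2 * pad_s) * master_rate_hz))
    data = np.zeros((n_ch, n))
    # Independent sub-streams so each additive stage is reproducible alone.
    ss = np.random.SeedSequence(seed)
    rng_noise, rng_blink = (np.random.default_rng(s) for s in ss.spawn(2))

    truth_templates: dict[str, np.ndarray] = {}
    template_rate = master_rate_hz
    event_samples = np.round(
        (schedule.onsets + pad_s) * master_rate_hz).astype(int)

    for comp in source.erp_templates:
        w = _weight_vector(comp.channel_weights, labels)
        course = _gaussian_template(comp, master_rate_hz)
        patch = np.outer(w, course)
        for lab in comp.event_labels:
            truth_templates.setdefault(
                lab, np.zeros((n_ch, course.size)))
            truth_templates[lab] += patch
        for ev, s0 in zip(schedule.events, event_samples):
            if ev.label in comp.event_labels:
                s1 = min(s0 + course.size, n)
                data[:, s0:s1] += patch[:, : s1 - s0]

    t = np.arange(n) / master_rate_hz
    for osc in source.oscillations:
        w = _weight_vector(osc.channel_weights, labels)
        wave = osc.amplitude_uV * np.sin(2 * np.pi * osc.freq_hz * t)
        if osc.condition_gate is None:
            gate = np.ones(n, dtype=bool)
        else:
            gate = np.zeros(n, dtype=bool)
            for lo, hi in _condition_intervals(schedule, osc.condition_gate,
                                               schedule.duration_s):
                gate[int((lo + pad_s) * master_rate_hz):
                     int((hi + pad_s) * master_rate_hz)] = True
        data += np.outer(w, wave * gate)

    if source.pink_scale_uV > 0:
        data += source.pink_scale_uV * _pink_noise(rng_noise, n_ch, n)
    if source.white_scale_uV > 0:
        data += source.white_scale_uV * rng_noise.standard_normal((n_ch, n))

    blink_times: list[float] = []
    if source.blinks is not None and source.blinks.rate_per_min > 0:
        bl = source.blinks
        n_blinks = rng_blink.poisson(bl.rate_per_min * (n / master_rate_hz) / 60.0)
        w = _weight_vector(bl.frontal_weights, labels, center=False)
        width = int(round(bl.duration_ms / 1000.0 * master_rate_hz))
        bump = bl.amplitude_uV * 0.5 * (1 - np.cos(
            2 * np.pi * np.arange(width) / width))
        for t0 in np.sort(rng_blink.uniform(0, n / master_rate_hz - bl.duration_ms / 1000.0,
                                            size=n_blinks)):
            s0 = int(round(t0 * master_rate_hz))
            data[:, s0:s0 + width] += np.outer(w, bump)[:, : n - s0]
            blink_times.append(float(t0))

    events = [(int(s), ev.label) for s, ev in zip(event_samples, schedule.events)
              if s < n]
    meta = {
        "ground_truth": {
            "templates": truth_templates,
            "template_rate_hz": template_rate,
            "oscillations": source.oscillations,
            "blink_times_s": blink_times,
            "source": source,
            "schedule": schedule,
        }
    }
    return Recording(data=data, rate_hz=master_rate_hz, channel_labels=list(labels),
                     events=events, meta=meta)


# ---------------------------------------------------------------------------
# Device presets and acquisition


def research_device() -> DeviceModel:
    """Research-grade amplifier: 24-bit, wide input range, 1,000 Hz."""
    return DeviceModel(
        name="research-1000", nominal_rate_hz=1000.0, true_rate_hz=1000.0,
        bit_depth=24, input_range_uV=(-200_000.0, 200_000.0),
        hardware_band_hz=(0.01, 400.0), marker_jitter_ms=0.1,
        sensor_noise_uV=0.2)


def consumer_device() -> DeviceModel:
    """Consumer headset: 14-bit, 0.2-45 Hz hardware band, nominal 128 Hz
    but a measured true rate of 129.05 Hz."""
    return DeviceModel(
        name="consumer-129", nominal_rate_hz=128.0, true_rate_hz=129.05,
        bit_depth=14, input_range_uV=(-4096.0, 4096.0),
        hardware_band_hz=(0.2, 45.0), marker_jitter_ms=1.0,
        sensor_noise_uV=1.0)


def _hardware_filter(data: np.ndarray, device: DeviceModel,
                     rate_hz: float) -> np.ndarray:
    hp, lp = device.hardware_band_hz
    nyq = rate_hz / 2.0
    out = data
    if hp > 0.0:
        sos = sps.butter(4, hp / nyq, btype="highpass", output="sos")
        out = sps.sosfiltfilt(sos, out, axis=-1)
    if lp < nyq * 0.99:
        sos = sps.butter(4, lp / nyq, btype="lowpass", output="sos")
        out = sps.sosfiltfilt(sos, out, axis=-1)
    return np.ascontiguousarray(out)


def _rational_ratio(target: float, current: float) -> Fraction:
    return Fraction(target / current).limit_denominator(10_000)


def quantize(data: np.ndarray, device: DeviceModel) -> np.ndarray:
    """Uniform mid-tread quantization with saturation clipping."""
    step = device.quantization_step_uV
    lo, hi = device.input_range_uV
    return np.clip(step * np.round(data / step), lo, hi)


def acquire(master: Recording, device: DeviceModel, seed: int = 0) -> Recording:
    """Record the master scalp signal through one virtual device.

    Stages: hardware band -> polyphase resample to ``true_rate_hz`` ->
    mid-tread quantization -> additive Gaussian sensor noise -> event
    markers re-indexed with Gaussian timing jitter.
    """
    if device.true_rate_hz > master.rate_hz + 1e-9:
        raise ValueError(
            f"device rate {device.true_rate_hz} Hz exceeds master rate "
            f"{master.rate_hz} Hz")
    rng = np.random.default_rng(seed)

    data = _hardware_filter(master.data, device, master.rate_hz)

    frac = _rational_ratio(device.true_rate_hz, master.rate_hz)
    if frac != 1:
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    out_rate = device.true_rate_hz

    data = quantize(data, device)
    if device.sensor_noise_uV > 0:
        data = data + rng.normal(0.0, device.sensor_noise_uV, size=data.shape)

    n_out = data.shape[1]
    events: list[tuple[int, str]] = []
    for s, lab in master.events:
        t = s / master.rate_hz
        if device.marker_jitter_ms > 0:
            t += rng.normal(0.0, device.marker_jitter_ms / 1000.0)
        idx = int(np.clip(round(t * out_rate), 0, n_out - 1))
        events.append((idx, lab))

    meta = dict(master.meta)
    meta["device"] = device
    return Recording(data=data, rate_hz=out_rate,
                     channel_labels=list(master.channel_labels),
                     events=events, t0=master.t0, meta=meta)
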