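"""Epoching, artifact rejection with cross-system harmonization, ERP
averaging, and component quantification.

Windows are closed intervals evaluated on the nearest-sample time grid;
extremum ties resolve to the earliest latency.  The rejection rule is the
classic +-150 uV absolute-amplitude criterion, applied per system and then
harmonized so a trial rejected by either simultaneous recording is dropped
from both.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .types import ComponentMeasure, Epochs, ERPWaveform, Recording

REJECTION_THRESHOLD_UV = 150.0
#: Fraction of rejected epochs above which a participant is excluded.
EXCLUSION_FRACTION = 0.5


def epoch_and_baseline(rec: Recording,
                       event_labels: Sequence[str] | None = None,
                       tmin_ms: float = -100.0, tmax_ms: float = 700.0,
                       baseline_ms: tuple[float, float] = (-100.0, 0.0)
                       ) -> Epochs:
    """Cut fixed-length epochs around events and baseline-correct them.

    Events whose epoch would run past either end of the recording are
    dropped with a warning.  Baseline correction subtracts, per epoch and
    channel, the mean over the baseline window.
    """
    rate = rec.rate_hz
    # floor keeps time_ms[0] <= tmin_ms so the baseline window is always
    # inside the epoch, whatever the (possibly non-integer) rate
    offset_lo = int(np.floor(tmin_ms / 1000.0 * rate))
    n_t = int(round((tmax_ms - tmin_ms) / 1000.0 * rate)) + 1
    time_ms = (np.arange(n_t) + offset_lo) / rate * 1000.0

    wanted = [(s, lab) for s, lab in rec.events
              if event_labels is None or lab in event_labels]
    keep, labels = [], []
    n_dropped = 0
    for s, lab in wanted:
        i0 = s + offset_lo
        if i0 < 0 or i0 + n_t > rec.n_samples:
            n_dropped += 1
            continue
        keep.append(rec.data[:, i0:i0 + n_t])
        labels.append(lab)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} edge events outside recording",
                      stacklevel=2)
    if not keep:
        raise ValueError("no events yielded complete epochs")
    data = np.stack(keep)

    bl = (time_ms >= baseline_ms[0] - 1e-9) & (time_ms <= baseline_ms[1] + 1e-9)
    data = data - data[:, :, bl].mean(axis=2, keepdims=True)
    return Epochs(data=data, time_ms=time_ms, baseline_ms=baseline_ms,
                  condition_labels=np.array(labels),
                  channel_labels=list(rec.channel_labels))


def rejection_mask(epochs: Epochs,
                   threshold_uV: float = REJECTION_THRESHOLD_UV) -> np.ndarray:
    """Per-trial accept mask: reject when any sample exceeds |threshold|.

    The bound is inclusive-exclusive: exactly ``threshold`` is retained.
    """
    peak = np.abs(epochs.data).max(axis=(1, 2))
    return peak <= threshold_uV


def reject_and_harmonize(epochs_a: Epochs, epochs_b: Epochs,
                         threshold_uV: float = REJECTION_THRESHOLD_UV
                         ) -> tuple[np.ndarray, bool]:
    """Joint accept mask for two simultaneous recordings of the same trials.

    A trial rejected in either system is rejected in both.  Returns the
    joint mask and an exclusion flag that is true when more than half the
    trials were rejected in either single system (the participant-level
    exclusion rule).

    Raises
    ------
    ValueError
        On trial-count or label mismatch, which signals an event-marking
        fault (missing/extra events in one system's file).
    """
    if epochs_a.n_trials != epochs_b.n_trials:
        raise ValueError(
            f"trial count mismatch between systems "
            f"({epochs_a.n_trials} vs {epochs_b.n_trials}); "
            "check event markers")
    if not np.array_equal(epochs_a.condition_labels, epochs_b.condition_labels):
        raise ValueError("condition labels differ between systems")
    mask_a = rejection_mask(epochs_a, threshold_uV)
    mask_b = rejection_mask(epochs_b, threshold_uV)
    joint = mask_a & mask_b
    n = epochs_a.n_trials
    excluded = ((n - mask_a.sum()) > EXCLUSION_FRACTION * n
                or (n - mask_b.sum()) > EXCLUSION_FRACTION * n)
    return joint, bool(excluded)


def average_erp(epochs: Epochs, mask: np.ndarray | None = None,
                condition: str | None = None) -> ERPWaveform:
    """Arithmetic mean over accepted trials of one condition."""
    sel = np.ones(epochs.n_trials, dtype=bool) if mask is None else np.asarray(mask, bool)
    if condition is not None:
        sel = sel & (epochs.condition_labels == condition)
    n = int(sel.sum())
    if n < 1:
        raise ValueError(f"no accepted epochs for condition {condition!r}")
    return ERPWaveform(data=epochs.data[sel].mean(axis=0),
                       time_ms=epochs.time_ms.copy(),
                       condition=condition or "all", n_epochs=n,
                       channel_labels=list(epochs.channel_labels))


def difference_wave(a: ERPWaveform, b: ERPWaveform) -> ERPWaveform:
    """Pointwise a - b (e.g. deviant minus standard)."""
    if a.data.shape != b.data.shape or not np.allclose(a.time_ms, b.time_ms):
        raise ValueError("waveforms must share channels and time axis")
    return ERPWaveform(data=a.data - b.data, time_ms=a.time_ms.copy(),
                       condition=f"{a.condition}-{b.condition}",
                       n_epochs=min(a.n_epochs, b.n_epochs),
                       channel_labels=list(a.channel_labels))


def _window_indices(time_ms: np.ndarray,
                    window_ms: tuple[float, float]) -> np.ndarray:
    lo, hi = window_ms
    idx = np.where((time_ms >= lo - 1e-9) & (time_ms <= hi + 1e-9))[0]
    if idx.size == 0:
        raise ValueError(f"window {window_ms} contains no samples")
    return idx


def component_measure(erp: ERPWaveform, channel: str,
                      window_ms: tuple[float, float],
                      polarity: str) -> ComponentMeasure:
    """Mean amplitude and extremum latency in a closed window.

    ``polarity`` 'negative' takes the minimum, 'positive' the maximum;
    tied extrema resolve to the earliest sample.
    """
    if polarity not in ("negative", "positive"):
        raise ValueError("polarity must be 'negative' or 'positive'")
    idx = _window_indices(erp.time_ms, window_ms)
    wave = erp.get_channel(channel)[idx]
    ext = int(np.argmin(wave)) if polarity == "negative" else int(np.argmax(wave))
    return ComponentMeasure(
        mean_amplitude_uV=float(wave.mean()),
        extremum_latency_ms=float(erp.time_ms[idx[ext]]),
        window_ms=window_ms, channel=channel, polarity=polarity)


def posthoc_window(grand_avg: ERPWaveform, channel: str,
                   search_ms: tuple[float, float], polarity: str,
                   width_ms: float = 100.0) -> tuple[float, float]:
    """Center a fixed-width window on the grand-average extremum.

    A grand-average minimum at 116 ms inside a 0-200 ms search range with
    the default 100 ms width returns (66.0, 166.0).
    """
    m = component_measure(grand_avg, channel, search_ms, polarity)
    t_star = m.extremum_latency_ms
    return (t_star - width_ms / 2.0, t_star + width_ms / 2.0)


def erp_snr(erp: ERPWaveform, channels: Sequence[str],
            signal_window_ms: tuple[float, float],
            baseline_window_ms: tuple[float, float] = (-100.0, 0.0)) -> float:
    """Signal-to-noise ratio of an averaged ERP.

    Per channel: RMS of the samples in the signal window divided by the
    (n-1) standard deviation of the baseline samples; the returned value
    is the mean of the per-channel ratios.
    """
    sig_idx = _window_indices(erp.time_ms, signal_window_ms)
    base_idx = _window_indices(erp.time_ms, baseline_window_ms)
    ratios = []
    for ch in channels:
        wave = erp.get_channel(ch)
        rms = float(np.sqrt(np.mean(wave[sig_idx] ** 2)))
        sd = float(np.std(wave[base_idx], ddof=1))
        if sd == 0:
            raise ValueError(f"zero baseline SD at {ch}; degenerate input")
        ratios.append(rms / sd)
    return float(np.mean(ratios))
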