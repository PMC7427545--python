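"""Offline preprocessing: rate estimation, filtering, resampling,
common-average re-referencing, and ocular-artifact removal.

The canonical stage order — bandpass filter, resample to the measured
common rate, common-average re-reference, ocular removal — is enforced by
:func:`preprocess_recording`; the individual stages are exposed for
testing and custom pipelines.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .types import FilterSpec, RateEstimate, Recording


def estimate_sampling_rate(n_samples: int, elapsed_s: float,
                           sample_indices: Sequence[int] | None = None
                           ) -> RateEstimate:
    """Empirical sampling rate: samples collected / elapsed seconds.

    Consumer devices drift from their nominal rate, so downstream stages
    should consume this estimate rather than the advertised figure.  If the
    device's running sample counter is supplied, gaps in it are counted as
    dropped samples.
    """
    if elapsed_s <= 0:
        raise ValueError("elapsed time must be positive")
    n_dropped = 0
    if sample_indices is not None and len(sample_indices) > 1:
        gaps = np.diff(np.asarray(sample_indices, dtype=np.int64))
        if np.any(gaps <= 0):
            raise ValueError("sample indices must be strictly increasing")
        n_dropped = int(np.sum(gaps - 1))
    return RateEstimate(estimated_rate_hz=n_samples / elapsed_s,
                        n_samples=n_samples, elapsed_s=elapsed_s,
                        n_dropped=n_dropped)


def bandpass_filter(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth bandpass (default 0.1-30 Hz)."""
    lo, hi = spec.band_hz
    nyq = rec.rate_hz / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz not below Nyquist {nyq} Hz")
    if spec.family != "butter":
        raise ValueError("only Butterworth filters are implemented")
    if lo > 0:
        sos = sps.butter(spec.order, [lo / nyq, hi / nyq], btype="bandpass",
                         output="sos")
    else:
        sos = sps.butter(spec.order, hi / nyq, btype="lowpass", output="sos")
    if spec.zero_phase:
        filtered = sps.sosfiltfilt(sos, rec.data, axis=-1)
    else:
        filtered = sps.sosfilt(sos, rec.data, axis=-1)
    out = rec.copy()
    out.data = np.ascontiguousarray(filtered)
    return out


def resample(rec: Recording, target_rate_hz: float,
             allow_upsample: bool = False) -> Recording:
    """Polyphase rational resampling with anti-alias filtering.

    Events are re-indexed to the nearest new sample, so an event's onset
    moves by at most half an output sampling period.
    """
    if target_rate_hz <= 0:
        raise ValueError("target rate must be positive")
    if target_rate_hz > rec.rate_hz and not allow_upsample:
        raise ValueError("upsampling requires allow_upsample=True")
    frac = Fraction(target_rate_hz / rec.rate_hz).limit_denominator(10_000)
    out = rec.copy()
    if frac == 1:
        out.rate_hz = target_rate_hz
        return out
    out.data = sps.resample_poly(rec.data, frac.numerator, frac.denominator,
                                 axis=-1)
    out.rate_hz = target_rate_hz
    scale = target_rate_hz / rec.rate_hz
    n_out = out.data.shape[1]
    out.events = [(int(np.clip(round(s * scale), 0, n_out - 1)), lab)
                  for s, lab in rec.events]
    return out


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over all scalp channels."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs >= 2 channels")
    out = rec.copy()
    out.data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return out


def _blink_reference(rec: Recording, frontal: Sequence[str]) -> np.ndarray:
    """Blink-band (0.5-8 Hz) mean of the frontal channels."""
    idx = [rec.channel_index(ch) for ch in frontal]
    ref = rec.data[idx].mean(axis=0)
    nyq = rec.rate_hz / 2.0
    sos = sps.butter(4, [0.5 / nyq, min(8.0, nyq * 0.9) / nyq],
                     btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, ref)


def remove_ocular_artifacts(rec: Recording,
                            frontal_channels: Sequence[str] = ("Fp1", "Fp2"),
                            method: str = "regression",
                            seed: int = 0,
                            detect_z: float = 4.0,
                            dilate_ms: float = 150.0) -> Recording:
    """Suppress eye-blink artifacts.

    ``regression`` (default, deterministic): a blink-band frontal reference
    is thresholded with a robust z-score to find blink intervals; within
    those intervals only, each channel's least-squares projection onto the
    reference is subtracted.  Data away from detected blinks is untouched,
    so blink-free recordings pass through essentially unchanged.

    ``ica``: FastICA decomposition (fixed seed); components whose time
    courses correlate with a frontal channel at |r| > 0.8 are zeroed.
    """
    for ch in frontal_channels:
        rec.channel_index(ch)  # raises KeyError if missing
    if method == "regression":
        return _remove_blinks_regression(rec, frontal_channels, detect_z,
                                         dilate_ms)
    if method == "ica":
        return _remove_blinks_ica(rec, frontal_channels, seed)
    raise ValueError(f"unknown ocular-removal method {method!r}")


def _remove_blinks_regression(rec: Recording, frontal: Sequence[str],
                              detect_z: float, dilate_ms: float) -> Recording:
    ref = _blink_reference(rec, frontal)
    med = np.median(ref)
    mad = np.median(np.abs(ref - med))
    out = rec.copy()
    if mad == 0:
        return out
    z = (ref - med) / (1.4826 * mad)
    mask = np.abs(z) > detect_z
    if not mask.any():
        return out
    width = int(round(dilate_ms / 1000.0 * rec.rate_hz))
    if width > 0:
        kernel = np.ones(2 * width + 1, dtype=bool)
        mask = np.convolve(mask, kernel, mode="same") > 0
    ref_masked = np.where(mask, ref, 0.0)
    denom = float(ref_masked @ ref_masked)
    if denom == 0:
        return out
    beta = (rec.data @ ref_masked) / denom
    out.data = rec.data - np.outer(beta, ref_masked)
    return out


def _remove_blinks_ica(rec: Recording, frontal: Sequence[str],
                       seed: int) -> Recording:
    from sklearn.decomposition import FastICA

    x = rec.data.T  # samples x channels
    ica = FastICA(n_components=rec.n_channels, random_state=seed,
                  whiten="unit-variance", max_iter=1000, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sources = ica.fit_transform(x)
    frontal_sig = np.stack([rec.get_channel(ch) for ch in frontal])
    bad = []
    for k in range(sources.shape[1]):
        r = max(abs(np.corrcoef(sources[:, k], f)[0, 1]) for f in frontal_sig)
        if r > 0.8:
            bad.append(k)
    sources[:, bad] = 0.0
    cleaned = ica.inverse_transform(sources)
    out = rec.copy()
    out.data = cleaned.T
    return out


def preprocess_recording(rec: Recording,
                         band_hz: tuple[float, float] = (0.1, 30.0),
                         target_rate_hz: float | None = None,
                         ocular: str | None = "regression",
                         frontal_channels: Sequence[str] = ("Fp1", "Fp2"),
                         seed: int = 0) -> Recording:
    """Full preprocessing chain in the canonical order.

    filter -> resample -> common-average re-reference -> ocular removal.
    ``target_rate_hz`` should be the *measured* rate of the slower device
    so both systems end on an identical time base.
    """
    out = bandpass_filter(rec, FilterSpec(band_hz=band_hz))
    if target_rate_hz is not None and abs(target_rate_hz - rec.rate_hz) > 1e-9:
        # the measured common rate may sit a hair above the slower stream's
        # nominal rate, so a tiny upsample is legitimate here
        out = resample(out, target_rate_hz, allow_upsample=True)
    out = rereference_common_average(out)
    if ocular is not None:
        out = remove_ocular_artifacts(out, frontal_channels, method=ocular,
                                      seed=seed)
    out.meta.setdefault("preprocessing", {}).update({
        "band_hz": tuple(band_hz),
        "target_rate_hz": target_rate_hz or rec.rate_hz,
        "reference": "common_average",
        "ocular": ocular,
        "order": ["bandpass_filter", "resample",
                  "rereference_common_average", "remove_ocular_artifacts"],
    })
    return out
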