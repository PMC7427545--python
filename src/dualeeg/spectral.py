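"""Single-taper spectral estimation, neighbor-bin SNR, and band power.

Spectra are computed on non-overlapping Hanning-tapered segments (default
5 s) and averaged across segments.  Bin steps finer than the segment's
natural resolution are reached by zero-padding (interpolation of the same
information, not new information); coarser steps aggregate natural bins.
Two unit conventions are carried explicitly: ``amplitude`` spectra are
corrected for the taper's coherent gain so a pure tone of amplitude A
reads A at its bin, while ``power`` spectra use energy normalization so
the bins sum to the time-domain variance (Parseval) and the same tone
carries total band power A^2/2.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import Recording, SNRSpectrum, SpectralEstimate


def amplitude_spectrum(rec: Recording, window_s: float = 5.0,
                       bin_step_hz: float = 0.2,
                       unit: str = "amplitude") -> SpectralEstimate:
    """Segment-averaged single-taper FFT spectrum.

    Partial trailing segments are discarded; a 120 s recording analysed
    with 5 s windows averages 24 segments.
    """
    if unit not in ("amplitude", "power"):
        raise ValueError("unit must be 'amplitude' or 'power'")
    nper = int(round(window_s * rec.rate_hz))
    if rec.n_samples < nper:
        raise ValueError("recording shorter than one analysis window")
    n_seg = rec.n_samples // nper
    taper = np.hanning(nper)
    coh_gain = taper.sum()            # coherent gain (tone amplitude)
    energy = float(np.sum(taper ** 2))  # energy normalization (Parseval)

    natural_df = rec.rate_hz / nper
    if bin_step_hz <= natural_df * (1 + 1e-9):
        nfft = int(round(rec.rate_hz / bin_step_hz))
        aggregate = False
    else:
        nfft = nper
        aggregate = True

    acc = None
    for k in range(n_seg):
        seg = rec.data[:, k * nper:(k + 1) * nper] * taper
        mag = np.abs(np.fft.rfft(seg, n=nfft, axis=-1))
        if unit == "amplitude":
            val = 2.0 * mag / coh_gain
            val[:, 0] /= 2.0  # DC is not doubled
        else:
            val = 2.0 * mag ** 2 / (nfft * energy)
            val[:, 0] /= 2.0
            if nfft % 2 == 0:
                val[:, -1] /= 2.0  # Nyquist bin is also unpaired
        acc = val if acc is None else acc + val
    values = acc / n_seg
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rec.rate_hz)

    if aggregate:
        centers = np.arange(0.0, freqs[-1] + bin_step_hz / 2, bin_step_hz)
        agg = np.empty((values.shape[0], centers.size))
        for i, f0 in enumerate(centers):
            sel = (freqs >= f0 - bin_step_hz / 2) & (freqs < f0 + bin_step_hz / 2)
            # amplitude bins average; power bins accumulate (band integral)
            if unit == "amplitude":
                agg[:, i] = values[:, sel].mean(axis=1)
            else:
                agg[:, i] = values[:, sel].sum(axis=1)
        freqs, values = centers, agg
        step = bin_step_hz
    else:
        step = float(freqs[1] - freqs[0])

    return SpectralEstimate(freqs_hz=freqs, values=values, unit=unit,
                            window_s=window_s, bin_step_hz=step,
                            channel_labels=list(rec.channel_labels),
                            n_segments=n_seg)


def _select_channels(spec: SpectralEstimate,
                     channels: Sequence[str] | None) -> np.ndarray:
    if channels is None:
        return spec.values.mean(axis=0)
    idx = [spec.channel_index(ch) for ch in channels]
    return spec.values[idx].mean(axis=0)


def neighbor_snr(spec: SpectralEstimate, channels: Sequence[str] | None = None,
                 n_side: int = 10, gap: int = 1) -> SNRSpectrum:
    """Local SNR: each bin against the mean of its 2*n_side neighbors.

    The neighborhood of bin f is {f +- (gap+1) ... f +- (gap+n_side)} bin
    steps — the immediately adjacent ``gap`` bins are excluded so spectral
    leakage from the bin under test does not contaminate its own baseline.
    z-scores use the neighborhood's (n-1) standard deviation.  Bins whose
    neighborhood would run off either spectrum edge are returned as NaN.
    """
    v = _select_channels(spec, channels)
    nf = v.size
    snr = np.full(nf, np.nan)
    z = np.full(nf, np.nan)
    reach = gap + n_side
    offsets = np.concatenate([np.arange(-reach, -gap), np.arange(gap + 1, reach + 1)])
    for i in range(reach, nf - reach):
        nb = v[i + offsets]
        mu = nb.mean()
        sd = nb.std(ddof=1)
        if mu > 0:
            snr[i] = v[i] / mu
        if sd > 0:
            z[i] = (v[i] - mu) / sd
    return SNRSpectrum(freqs_hz=spec.freqs_hz.copy(), snr=snr, z=z,
                       n_neighbors=2 * n_side, gap=gap)


def band_power(spec: SpectralEstimate, band_hz: tuple[float, float] = (8.0, 12.0),
               channels: Sequence[str] | None = None) -> float:
    """Integrated power over a closed band, averaged over channels.

    Requires a power-unit spectrum (Parseval-normalized bins), so a pure
    tone of amplitude A inside the band contributes A^2/2 regardless of
    bin step or zero-padding.
    """
    if spec.unit != "power":
        raise ValueError("band_power requires a power-unit spectrum")
    lo, hi = band_hz
    if lo < spec.freqs_hz[0] - 1e-9 or hi > spec.freqs_hz[-1] + 1e-9:
        raise ValueError("band outside spectrum")
    v = _select_channels(spec, channels)
    sel = (spec.freqs_hz >= lo - 1e-9) & (spec.freqs_hz <= hi + 1e-9)
    return float(v[sel].sum())
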