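"""Core containers shared by every stage of the dual-system EEG pipeline.

Conventions: amplitudes in microvolts, times in seconds unless a field name
says ``_ms``, channel data as ``(n_channels, n_samples)`` float arrays.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

#: 16-channel scalp montage used throughout (consumer-cap layout).
MONTAGE_16: tuple[str, ...] = (
    "Fp1", "F3", "FT7", "CP3", "P7", "O1", "O2", "P8",
    "CP4", "FT8", "F4", "Fp2", "Fz", "Cz", "Pz", "Oz",
)

OCCIPITAL = ("O1", "Oz", "O2")


@dataclass(frozen=True)
class Event:
    onset_s: float
    label: str
    block: int = 0


@dataclass
class EventSchedule:
    """Ordered stimulus/boundary events for one paradigm run."""

    events: list[Event]
    duration_s: float

    def __post_init__(self) -> None:
        onsets = self.onsets
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def onsets(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.events]

    @property
    def blocks(self) -> np.ndarray:
        return np.array([e.block for e in self.events], dtype=int)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ParadigmSpec:
    """Parameters of one stimulation paradigm.

    Defaults encode the validation study's design: a 666-tone auditory
    oddball (85% standards at 1,000 Hz, 15% deviants at 1,500 Hz) in 10
    blocks, 75 face + 75 watch images each shown upright and inverted,
    a 14.36 Hz flickering screen, and 3-minute eyes-open/eyes-closed
    resting conditions.
    """

    paradigm_kind: str = "oddball_passive"
    n_tones: int = 666
    deviant_fraction: float = 0.15
    n_blocks: int = 10
    min_leading_standards: int = 3
    min_gap: int = 5
    max_gap: int = 35
    soa_range_ms: tuple[float, float] = (900.0, 1100.0)
    tone_freqs_hz: tuple[float, float] = (1000.0, 1500.0)
    tone_duration_ms: float = 175.0
    n_face_images: int = 75
    n_watch_images: int = 75
    flicker_hz: float = 14.36
    condition_durations_s: tuple[float, ...] = (180.0, 180.0)

    _KINDS = ("oddball_passive", "oddball_active", "n170", "ssvep", "resting")

    def __post_init__(self) -> None:
        if self.paradigm_kind not in self._KINDS:
            raise ValueError(f"unknown paradigm_kind {self.paradigm_kind!r}")
        if not (0.0 <= self.deviant_fraction < 1.0):
            raise ValueError("deviant_fraction must lie in [0, 1)")
        if self.min_gap > self.max_gap:
            raise ValueError("min_gap must not exceed max_gap")
        if self.soa_range_ms[0] > self.soa_range_ms[1]:
            raise ValueError("SOA low bound exceeds high bound")
        for name in ("n_tones", "n_blocks", "min_leading_standards", "min_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_tones <= 0 or self.n_blocks <= 0:
            raise ValueError("counts must be positive")
        if any(d <= 0 for d in self.condition_durations_s):
            raise ValueError("condition durations must be positive")


@dataclass
class DeviceModel:
    """Parametric acquisition device: rate, resolution, analog front end.

    ``true_rate_hz`` may differ from ``nominal_rate_hz`` (consumer hardware
    commonly drifts; e.g. a nominal 128 Hz device measured at 129.05 Hz).
    """

    name: str
    nominal_rate_hz: float
    true_rate_hz: float
    bit_depth: int
    input_range_uV: tuple[float, float]
    hardware_band_hz: tuple[float, float]
    marker_jitter_ms: float = 0.0
    sensor_noise_uV: float = 0.0

    def __post_init__(self) -> None:
        if self.true_rate_hz <= 0:
            raise ValueError("true_rate_hz must be positive")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")
        lo, hi = self.input_range_uV
        if lo >= hi:
            raise ValueError("input range must be (min, max) with min < max")
        hp, lp = self.hardware_band_hz
        if hp >= lp:
            raise ValueError("hardware band requires hp < lp")

    @property
    def quantization_step_uV(self) -> float:
        lo, hi = self.input_range_uV
        return (hi - lo) / 2 ** self.bit_depth


@dataclass
class Recording:
    """Multichannel time series with event markers.

    data: (n_channels, n_samples) in microvolts.
    events: list of (sample_index, label) pairs, indices within bounds.
    meta: free-form provenance (ground truth for synthetic recordings).
    """

    data: np.ndarray
    rate_hz: float
    channel_labels: Sequence[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    t0: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data rows")
        for idx, _ in self.events:
            if not (0 <= idx < self.n_samples):
                raise ValueError(f"event sample {idx} outside recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channel_labels).index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            rate_hz=self.rate_hz,
            channel_labels=list(self.channel_labels),
            events=list(self.events),
            t0=self.t0,
            meta=_copy.deepcopy(self.meta),
        )


@dataclass
class FilterSpec:
    band_hz: tuple[float, float] = (0.1, 30.0)
    family: str = "butter"
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0.0 <= lo < hi):
            raise ValueError("band must satisfy 0 <= low < high")


@dataclass
class RateEstimate:
    estimated_rate_hz: float
    n_samples: int
    elapsed_s: float
    n_dropped: int = 0


@dataclass
class Epochs:
    """Trials x channels x time, with a per-trial accept mask."""

    data: np.ndarray
    time_ms: np.ndarray
    baseline_ms: tuple[float, float]
    condition_labels: np.ndarray
    channel_labels: Sequence[str]
    accept_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.condition_labels = np.asarray(self.condition_labels)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time vector inconsistent with data")
        if self.data.shape[0] != self.condition_labels.size:
            raise ValueError("one condition label per trial required")
        lo, hi = self.baseline_ms
        if lo < self.time_ms[0] - 1e-9 or hi > self.time_ms[-1] + 1e-9:
            raise ValueError("baseline window outside epoch")
        if self.accept_mask is None:
            self.accept_mask = np.ones(self.data.shape[0], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, label: str) -> int:
        return list(self.channel_labels).index(label)


@dataclass
class ERPWaveform:
    """Condition-average waveform (channels x time)."""

    data: np.ndarray
    time_ms: np.ndarray
    condition: str
    n_epochs: int
    channel_labels: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.n_epochs < 1:
            raise ValueError("an ERP requires at least one epoch")
        if self.data.shape != (len(self.channel_labels), self.time_ms.size):
            raise ValueError("data shape inconsistent with labels/time")

    def channel_index(self, label: str) -> int:
        return list(self.channel_labels).index(label)

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


@dataclass
class ComponentMeasure:
    mean_amplitude_uV: float
    extremum_latency_ms: float
    window_ms: tuple[float, float]
    channel: str
    polarity: str


@dataclass
class SpectralEstimate:
    """Segment-averaged single-taper spectrum (amplitude or power)."""

    freqs_hz: np.ndarray
    values: np.ndarray
    unit: str
    window_s: float
    bin_step_hz: float
    channel_labels: Sequence[str]
    n_segments: int = 1

    def channel_index(self, label: str) -> int:
        return list(self.channel_labels).index(label)


@dataclass
class SNRSpectrum:
    freqs_hz: np.ndarray
    snr: np.ndarray
    z: np.ndarray
    n_neighbors: int
    gap: int


@dataclass
class ICCResult:
    estimate: float
    ci95: tuple[float, float]
    n_points: int
    model: str

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0.0 or hi < 0.0


@dataclass
class BayesFactorResult:
    bf10: float
    prior_scale: float
    n: int
    t_stat: float
    integration_error: float


@dataclass
class StoppingTrace:
    per_n: list[tuple[int, float]]
    decision: str
    n_final: int
    bounds: tuple[float, float]
    min_n: int
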