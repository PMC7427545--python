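"""Stimulus schedule generators for the five validation paradigms.

Each generator returns an :class:`~dualeeg.types.EventSchedule` whose onset
times are in seconds from recording start.  The auditory oddball honours the
classic pseudo-random constraints used in mismatch-negativity work: every
block starts with a run of standards, deviants are evenly allocated to
blocks, and the number of standards between successive deviants is bounded
on both sides.
"""

from __future__ import annotations

import math

import numpy as np

from .types import Event, EventSchedule, ParadigmSpec


class InfeasibleParadigmError(ValueError):
    """Raised when a paradigm spec cannot satisfy its own constraints."""


def _deviant_counts(spec: ParadigmSpec) -> tuple[int, int]:
    n_dev = int(round(spec.n_tones * spec.deviant_fraction))
    return n_dev, spec.n_tones - n_dev


def _allocate_extras(rng: np.random.Generator, total: int, caps: np.ndarray) -> np.ndarray:
    """Spread ``total`` surplus standards over gap slots, respecting caps.

    Multinomial draw followed by cap repair: surplus above a cap is pushed
    to randomly chosen slots with remaining room.  ``caps`` entries may be
    -1 for unbounded slots.
    """
    k = caps.size
    extras = rng.multinomial(total, np.full(k, 1.0 / k))
    unbounded = caps < 0
    for _ in range(10_000):
        over = np.where(~unbounded & (extras > caps))[0]
        if over.size == 0:
            return extras
        room = np.where(unbounded | (extras < caps))[0]
        if room.size == 0:
            raise InfeasibleParadigmError("gap caps too tight for standard count")
        for i in over:
            surplus = extras[i] - caps[i]
            extras[i] = caps[i]
            dest = rng.choice(room, size=surplus)
            np.add.at(extras, dest, 1)
    raise InfeasibleParadigmError("could not repair gap allocation")


def generate_oddball_sequence(spec: ParadigmSpec, seed: int) -> EventSchedule:
    """Generate a pseudo-random standard/deviant tone sequence.

    Constraints enforced: deviants split equally across ``n_blocks``; each
    block begins with at least ``min_leading_standards`` standards; between
    consecutive deviants there are between ``min_gap`` and ``max_gap``
    standards (block boundaries do not relax the gap rule).  Onsets are
    spaced by i.i.d. uniform SOAs drawn from ``soa_range_ms``.

    Raises
    ------
    InfeasibleParadigmError
        If the standard budget cannot satisfy the gap/leading constraints,
        or deviants do not divide evenly across blocks.
    """
    rng = np.random.default_rng(seed)
    n_dev, n_std = _deviant_counts(spec)

    soa_lo, soa_hi = (s / 1000.0 for s in spec.soa_range_ms)
    soas = rng.uniform(soa_lo, soa_hi, size=spec.n_tones)
    duration = float(np.sum(soas))
    onsets = np.concatenate([[0.0], np.cumsum(soas[:-1])])

    if n_dev == 0:
        events = [Event(float(t), "standard", _block_of(i, spec.n_tones, spec.n_blocks))
                  for i, t in enumerate(onsets)]
        return EventSchedule(events, duration)

    if n_dev % spec.n_blocks != 0:
        raise InfeasibleParadigmError(
            f"{n_dev} deviants do not divide evenly over {spec.n_blocks} blocks")
    per_block = n_dev // spec.n_blocks

    # Gap slots: leading run, n_dev - 1 inter-deviant runs, trailing run.
    # Cross-block inter-deviant runs must leave room for the next block's
    # leading standards.
    n_inter = n_dev - 1
    cross = np.zeros(n_inter, dtype=bool)
    for b in range(1, spec.n_blocks):
        cross[b * per_block - 1] = True
    inter_min = np.where(cross,
                         max(spec.min_gap, spec.min_leading_standards),
                         spec.min_gap)
    minima = np.concatenate([[spec.min_leading_standards], inter_min, [0]])
    caps = np.concatenate([[-1], spec.max_gap - inter_min, [-1]])
    surplus = n_std - int(minima.sum())
    if surplus < 0:
        raise InfeasibleParadigmError(
            f"need at least {int(minima.sum())} standards, have {n_std}")
    gaps = minima + _allocate_extras(rng, surplus, caps)

    labels: list[str] = []
    for i in range(n_dev):
        labels.extend(["standard"] * int(gaps[i]))
        labels.append("deviant")
    labels.extend(["standard"] * int(gaps[-1]))
    assert len(labels) == spec.n_tones

    # Block boundaries: block b+1 starts so that at least
    # min_leading_standards of the cross-block run fall at its head.
    blocks = np.zeros(spec.n_tones, dtype=int)
    dev_pos = [i for i, lab in enumerate(labels) if lab == "deviant"]
    for b in range(1, spec.n_blocks):
        prev_dev = dev_pos[b * per_block - 1]
        next_dev = dev_pos[b * per_block]
        run = next_dev - prev_dev - 1  # standards in between
        latest = next_dev - spec.min_leading_standards
        earliest = prev_dev + 1
        start = int(rng.integers(earliest, latest + 1)) if latest >= earliest else earliest
        blocks[start:] = b

    events = [Event(float(t), lab, int(b))
              for t, lab, b in zip(onsets, labels, blocks)]
    return EventSchedule(events, duration)


def _block_of(i: int, n: int, n_blocks: int) -> int:
    return min(i * n_blocks // n, n_blocks - 1)


# Per-trial timeline of the face/watch discrimination task (ms).
N170_FIXATION_MS = 500.0
N170_STIMULUS_MS = 200.0
N170_RESPONSE_MS = (500.0, 1000.0)  # self-paced; simulated uniform
N170_BLINK_MS = 1500.0
N170_BLANK_MS = 500.0


def generate_n170_trials(spec: ParadigmSpec, seed: int) -> EventSchedule:
    """Randomized upright/inverted face-and-watch presentation order.

    Each unique image appears exactly once upright and once inverted, so a
    spec with 75 faces and 75 watches yields 300 trials in two equal blocks.
    Event onsets mark stimulus appearance (after the 500 ms fixation); the
    simulated response interval is uniform on ``N170_RESPONSE_MS``.
    """
    if spec.n_face_images < 0 or spec.n_watch_images < 0:
        raise ValueError("image counts must be non-negative")
    if spec.n_face_images + spec.n_watch_images == 0:
        raise ValueError("at least one image required")
    rng = np.random.default_rng(seed)

    trials = [(cat, idx, ori)
              for cat, count in (("face", spec.n_face_images),
                                 ("watch", spec.n_watch_images))
              for idx in range(count)
              for ori in ("upright", "inverted")]
    order = rng.permutation(len(trials))
    n_trials = len(trials)
    half = n_trials // 2

    events = []
    t = 0.0
    for pos, j in enumerate(order):
        cat, idx, ori = trials[j]
        t += N170_FIXATION_MS / 1000.0
        events.append(Event(t, f"{ori}_{cat}", 0 if pos < half else 1))
        resp = rng.uniform(*N170_RESPONSE_MS)
        t += (N170_STIMULUS_MS + resp + N170_BLINK_MS + N170_BLANK_MS) / 1000.0
    return EventSchedule(events, t)


def generate_ssvep_schedule(duration_s: float, flicker_hz: float) -> EventSchedule:
    """Flicker-cycle onsets at exact multiples of the stimulation period.

    Only cycles that fit entirely inside ``duration_s`` are emitted, so
    120 s at 14.36 Hz gives floor(120 x 14.36) = 1,723 cycles.
    """
    if duration_s <= 0 or flicker_hz <= 0:
        raise ValueError("duration and frequency must be positive")
    n_cycles = math.floor(duration_s * flicker_hz * (1 + 1e-12))
    events = [Event(k / flicker_hz, "cycle", 0) for k in range(n_cycles)]
    return EventSchedule(events, duration_s)


def generate_resting_schedule(spec: ParadigmSpec) -> EventSchedule:
    """Contiguous eyes-open then eyes-closed intervals with boundary events."""
    durations = spec.condition_durations_s
    labels = ("eyes_open", "eyes_closed")
    if len(durations) != 2:
        raise ValueError("resting paradigm expects two condition durations")
    events = []
    t = 0.0
    for lab, d in zip(labels, durations):
        events.append(Event(t, lab, 0))
        t += float(d)
    events.append(Event(t, "end", 0))
    return EventSchedule(events, t)
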