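"""End-to-end study orchestration: simulate two devices recording the same
brain, preprocess both streams identically, quantify ERPs/spectra, and
compute the between-system agreement statistics.

Every number in the report is reproducible from (config, seed): random
streams are derived per paradigm / participant / stage from a single root
seed, splitmix-style, via :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import erp as erp_mod
from . import paradigms, preprocess, simulate, spectral, stats
from .types import DeviceModel, ParadigmSpec, Recording

#: Pre-registered measurement windows: paradigm -> (channel, window, polarity)
PREREGISTERED_WINDOWS = {
    "oddball_passive": ("Fz", (100.0, 200.0), "negative"),
    "oddball_active": ("Pz", (280.0, 380.0), "positive"),
    "n170": ("P8", (120.0, 220.0), "negative"),
}
POSTHOC_SEARCH = {
    "oddball_passive": ((0.0, 200.0), "negative"),
    "oddball_active": ((200.0, 400.0), "positive"),
}


@dataclass
class StudyConfig:
    """Study-level parameters; defaults mirror the full validation design."""

    paradigms: tuple[str, ...] = ("oddball_passive", "oddball_active",
                                  "n170", "ssvep", "resting")
    n_participants: int = 20
    seed: int = 0
    master_rate_hz: float = simulate.MASTER_RATE_HZ
    band_hz: tuple[float, float] = (0.1, 30.0)
    ocular: str | None = "regression"
    ssvep_duration_s: float = 120.0
    stopping_min_n: int = 20
    stopping_bounds: tuple[float, float] = (0.33, 3.00)
    paradigm_specs: dict[str, ParadigmSpec] = field(default_factory=dict)
    devices: tuple[DeviceModel, DeviceModel] = field(
        default_factory=lambda: (simulate.research_device(),
                                 simulate.consumer_device()))
    pink_scale_uV: float | None = None   # None -> source-model default
    white_scale_uV: float | None = None
    blink_rate_per_min: float | None = None

    def __post_init__(self) -> None:
        if len(self.devices) != 2:
            raise ValueError("exactly two devices required")

    def spec_for(self, kind: str) -> ParadigmSpec:
        if kind in self.paradigm_specs:
            return self.paradigm_specs[kind]
        return ParadigmSpec(paradigm_kind=kind)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        specs = {k: ParadigmSpec(**v)
                 for k, v in raw.pop("paradigm_specs", {}).items()}
        devices = raw.pop("devices", None)
        kwargs: dict[str, Any] = dict(raw)
        if specs:
            kwargs["paradigm_specs"] = specs
        if devices is not None:
            kwargs["devices"] = tuple(DeviceModel(**d) for d in devices)
        for key in ("paradigms", "band_hz", "stopping_bounds"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def demo_study_config(seed: int = 0, n_participants: int = 8) -> StudyConfig:
    """Scaled-down configuration for fast, fully in-memory study runs.

    Shorter paradigms (132-tone oddball in 2 blocks, 10+10 images, 60 s
    flicker, 30 s resting conditions) and a 1,024 Hz master grid keep a
    complete multi-participant study in the seconds-to-minutes range while
    exercising every stage at the study's noise and effect sizes.
    """
    specs = {
        "oddball_passive": ParadigmSpec(paradigm_kind="oddball_passive",
                                        n_tones=132, n_blocks=2),
        "oddball_active": ParadigmSpec(paradigm_kind="oddball_active",
                                       n_tones=132, n_blocks=2),
        "n170": ParadigmSpec(paradigm_kind="n170", n_face_images=10,
                             n_watch_images=10),
        "resting": ParadigmSpec(paradigm_kind="resting",
                                condition_durations_s=(30.0, 30.0)),
    }
    return StudyConfig(seed=seed, n_participants=n_participants,
                       master_rate_hz=1024.0, ssvep_duration_s=60.0,
                       paradigm_specs=specs)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


def _build_source(kind: str, config: StudyConfig) -> simulate.SourceModel:
    src = simulate.default_source_model(kind)
    if config.pink_scale_uV is not None:
        src.pink_scale_uV = config.pink_scale_uV
    if config.white_scale_uV is not None:
        src.white_scale_uV = config.white_scale_uV
    if config.blink_rate_per_min is not None:
        if src.blinks is not None:
            src.blinks.rate_per_min = config.blink_rate_per_min
    return src


def _make_schedule(kind: str, spec: ParadigmSpec, config: StudyConfig,
                   seed: int):
    if kind in ("oddball_passive", "oddball_active"):
        return paradigms.generate_oddball_sequence(spec, seed)
    if kind == "n170":
        return paradigms.generate_n170_trials(spec, seed)
    if kind == "ssvep":
        return paradigms.generate_ssvep_schedule(config.ssvep_duration_s,
                                                 spec.flicker_hz)
    if kind == "resting":
        return paradigms.generate_resting_schedule(spec)
    raise ValueError(f"unknown paradigm {kind!r}")


def simulate_participant(kind: str, config: StudyConfig,
                         ss: np.random.SeedSequence
                         ) -> tuple[Recording, Recording, Recording]:
    """One participant's simultaneous two-device session for one paradigm.

    Returns (master, preprocessed device A, preprocessed device B); both
    device streams are preprocessed onto the *measured* rate of the slower
    device, mirroring how a real dual recording is harmonized.
    """
    s_sched, s_master, s_a, s_b, s_pre = (
        _child_seed(c) for c in ss.spawn(5))
    spec = config.spec_for(kind)
    schedule = _make_schedule(kind, spec, config, s_sched)
    source = _build_source(kind, config)
    master = simulate.synthesize_scalp_signal(
        schedule, source, master_rate_hz=config.master_rate_hz, seed=s_master)
    dev_a, dev_b = config.devices
    rec_a = simulate.acquire(master, dev_a, seed=s_a)
    rec_b = simulate.acquire(master, dev_b, seed=s_b)
    # consume the empirical rate of the slower stream, not its nominal rate
    slower = rec_b if rec_b.rate_hz <= rec_a.rate_hz else rec_a
    est = preprocess.estimate_sampling_rate(slower.n_samples,
                                            master.duration_s)
    target = est.estimated_rate_hz
    pre_a = preprocess.preprocess_recording(
        rec_a, band_hz=config.band_hz, target_rate_hz=target,
        ocular=config.ocular, seed=s_pre)
    pre_b = preprocess.preprocess_recording(
        rec_b, band_hz=config.band_hz, target_rate_hz=target,
        ocular=config.ocular, seed=s_pre)
    return master, pre_a, pre_b


def _erp_conditions(kind: str) -> list[str]:
    if kind in ("oddball_passive", "oddball_active"):
        return ["standard", "deviant"]
    return ["upright_face", "inverted_face", "upright_watch", "inverted_watch"]


def _measurement_wave(kind: str, waves: dict[str, erp_mod.ERPWaveform]
                      ) -> erp_mod.ERPWaveform:
    if kind == "oddball_passive":
        return erp_mod.difference_wave(waves["deviant"], waves["standard"])
    if kind == "oddball_active":
        return waves["deviant"]
    return waves["upright_face"]


def run_erp_paradigm(kind: str, config: StudyConfig,
                     ss: np.random.SeedSequence) -> dict[str, Any]:
    channel, window, polarity = PREREGISTERED_WINDOWS[kind]
    conditions = _erp_conditions(kind)
    participants = ss.spawn(config.n_participants)

    per_sys: dict[str, dict[str, list]] = {
        "A": {"measure": [], "snr": [], "rejected": []},
        "B": {"measure": [], "snr": [], "rejected": []},
    }
    grand: dict[str, dict[str, list]] = {"A": {}, "B": {}}
    meas_waves: dict[str, list] = {"A": [], "B": []}
    excluded = 0

    for p_ss in participants:
        _, pre_a, pre_b = simulate_participant(kind, config, p_ss)
        ep_a = erp_mod.epoch_and_baseline(pre_a, conditions)
        ep_b = erp_mod.epoch_and_baseline(pre_b, conditions)
        mask, flag = erp_mod.reject_and_harmonize(ep_a, ep_b)
        if flag:
            excluded += 1
            continue
        for name, ep in (("A", ep_a), ("B", ep_b)):
            waves = {c: erp_mod.average_erp(ep, mask, c) for c in conditions}
            mwave = _measurement_wave(kind, waves)
            meas = erp_mod.component_measure(mwave, channel, window, polarity)
            per_sys[name]["measure"].append(meas.mean_amplitude_uV)
            per_sys[name]["snr"].append(
                erp_mod.erp_snr(mwave, list(ep.channel_labels), window))
            per_sys[name]["rejected"].append(
                int(ep.n_trials - erp_mod.rejection_mask(ep).sum()))
            for c, w in waves.items():
                grand[name].setdefault(c, []).append(w)
            meas_waves[name].append(mwave)

    if not per_sys["A"]["measure"]:
        return {"excluded_participants": excluded, "error": "all excluded"}

    def _grand(wlist):
        out = wlist[0]
        data = np.mean([w.data for w in wlist], axis=0)
        return erp_mod.ERPWaveform(data=data, time_ms=out.time_ms,
                                   condition=out.condition,
                                   n_epochs=sum(w.n_epochs for w in wlist),
                                   channel_labels=out.channel_labels)

    grand_meas = {s: _grand(meas_waves[s]) for s in ("A", "B")}
    icc = stats.waveform_icc(grand_meas["A"], grand_meas["B"], channel)
    diffs = np.array(per_sys["A"]["measure"]) - np.array(per_sys["B"]["measure"])
    degenerate = diffs.size < 2 or float(np.std(diffs, ddof=1)) == 0.0
    bf10 = None if degenerate else stats.jzs_bf_ttest(diffs).bf10
    trace = None
    if not degenerate and diffs.size >= config.stopping_min_n:
        trace = stats.sequential_stop(diffs, config.stopping_min_n,
                                      *config.stopping_bounds)
    try:
        wz, wp = stats.wilcoxon_signed_rank(per_sys["A"]["rejected"],
                                            per_sys["B"]["rejected"])
        wilcoxon = {"z": wz, "p": wp}
    except stats.AllZeroDifferencesError:
        wilcoxon = {"z": None, "p": None, "note": "all differences zero"}

    topo = {}
    for s in ("A", "B"):
        gm = grand_meas[s]
        topo[s] = [float(np.mean(gm.data[i][erp_mod._window_indices(
            gm.time_ms, window)])) for i in range(gm.data.shape[0])]
    topo_r = stats.topography_correlation(topo["A"], topo["B"])

    result: dict[str, Any] = {
        "channel": channel, "window_ms": list(window), "polarity": polarity,
        "excluded_participants": excluded,
        "n_analyzed": int(diffs.size),
        "per_system": {
            s: {
                "mean_measure_uV": float(np.mean(per_sys[s]["measure"])),
                "mean_snr": float(np.mean(per_sys[s]["snr"])),
                "rejected_epochs": per_sys[s]["rejected"],
            } for s in ("A", "B")
        },
        "icc": {"estimate": icc.estimate, "ci95": list(icc.ci95),
                "model": icc.model, "significant": icc.significant},
        "bf10_measure": bf10,
        "wilcoxon_rejected": wilcoxon,
        "topography_r": topo_r,
    }
    if kind in POSTHOC_SEARCH:
        search, pol = POSTHOC_SEARCH[kind]
        overall = erp_mod.ERPWaveform(
            data=(grand_meas["A"].data + grand_meas["B"].data) / 2.0,
            time_ms=grand_meas["A"].time_ms, condition="overall",
            n_epochs=grand_meas["A"].n_epochs + grand_meas["B"].n_epochs,
            channel_labels=grand_meas["A"].channel_labels)
        result["posthoc_window_ms"] = list(
            erp_mod.posthoc_window(overall, channel, search, pol))
    if trace is not None:
        result["stopping"] = {
            "decision": trace.decision, "n_final": trace.n_final,
            "per_n": [[n, float(b)] for n, b in trace.per_n],
        }
    return result


def run_ssvep_paradigm(config: StudyConfig,
                       ss: np.random.SeedSequence) -> dict[str, Any]:
    flicker = config.spec_for("ssvep").flicker_hz
    out: dict[str, dict[str, list]] = {"A": {"snr": [], "z": []},
                                       "B": {"snr": [], "z": []}}
    for p_ss in ss.spawn(config.n_participants):
        _, pre_a, pre_b = simulate_participant("ssvep", config, p_ss)
        for name, rec in (("A", pre_a), ("B", pre_b)):
            spec = spectral.amplitude_spectrum(rec)
            snr = spectral.neighbor_snr(spec, channels=list(spectral_occipital()))
            k = int(np.argmin(np.abs(snr.freqs_hz - flicker)))
            out[name]["snr"].append(float(snr.snr[k]))
            out[name]["z"].append(float(snr.z[k]))
    diffs = np.array(out["A"]["snr"]) - np.array(out["B"]["snr"])
    bf = stats.jzs_bf_ttest(diffs) if diffs.size >= 2 else None
    return {
        "flicker_hz": flicker,
        "per_system": {s: {"mean_snr": float(np.mean(out[s]["snr"])),
                           "mean_z": float(np.mean(out[s]["z"])),
                           "frac_z_significant":
                               float(np.mean(np.array(out[s]["z"]) > 1.96))}
                       for s in ("A", "B")},
        "bf10_snr": bf.bf10 if bf else None,
    }


def spectral_occipital() -> tuple[str, str, str]:
    return ("O1", "Oz", "O2")


def _trim_condition(rec: Recording, label: str) -> Recording:
    starts = [s for s, lab in rec.events if lab == label]
    if not starts:
        raise ValueError(f"no {label!r} boundary event")
    s0 = starts[0]
    later = sorted(s for s, _ in rec.events if s > s0)
    s1 = later[0] if later else rec.n_samples
    out = rec.copy()
    out.data = rec.data[:, s0:s1]
    out.events = []
    return out


def run_resting_paradigm(config: StudyConfig,
                         ss: np.random.SeedSequence) -> dict[str, Any]:
    table = []
    for p_ss in ss.spawn(config.n_participants):
        _, pre_a, pre_b = simulate_participant("resting", config, p_ss)
        row = np.empty((2, 2))
        for i, rec in enumerate((pre_a, pre_b)):
            for j, cond in enumerate(("eyes_open", "eyes_closed")):
                seg = _trim_condition(rec, cond)
                spec = spectral.amplitude_spectrum(seg, unit="power")
                row[i, j] = spectral.band_power(
                    spec, (8.0, 12.0), channels=list(spectral_occipital()))
        table.append(row)
    table = np.array(table)
    bfs = stats.bayes_2x2(table, factors=("system", "condition"))
    return {
        "alpha_power": {
            "A_open": float(table[:, 0, 0].mean()),
            "A_closed": float(table[:, 0, 1].mean()),
            "B_open": float(table[:, 1, 0].mean()),
            "B_closed": float(table[:, 1, 1].mean()),
        },
        "bf10": {k: v.bf10 for k, v in bfs.items()},
        "closed_gt_open_all": bool(
            np.all(table[:, :, 1].mean(axis=1) > table[:, :, 0].mean(axis=1))),
    }


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Execute every configured paradigm and assemble the validation report."""
    root = np.random.SeedSequence(config.seed)
    children = dict(zip(config.paradigms, root.spawn(len(config.paradigms))))
    report: dict[str, Any] = {
        "provenance": {
            "seed": config.seed,
            "n_participants": config.n_participants,
            "master_rate_hz": config.master_rate_hz,
            "devices": [dataclasses.asdict(d) for d in config.devices],
        },
        "paradigms": {},
    }
    for kind in config.paradigms:
        ss = children[kind]
        if kind in PREREGISTERED_WINDOWS:
            report["paradigms"][kind] = run_erp_paradigm(kind, config, ss)
        elif kind == "ssvep":
            report["paradigms"][kind] = run_ssvep_paradigm(config, ss)
        elif kind == "resting":
            report["paradigms"][kind] = run_resting_paradigm(config, ss)
        else:
            raise ValueError(f"unknown paradigm {kind!r}")
    return report
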