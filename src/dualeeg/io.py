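"""Readers and writers for recordings, event tables, and configs.

Native on-disk format is plain text: a TSV sample matrix (one column per
channel), a JSON sidecar carrying the rate and labels, and a TSV event
table (onset_s, sample, label, block).  EDF files are read through MNE
when available; writing stays textual.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import Recording


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path,
                    events_path: str | Path | None = None,
                    fmt: str = "%.6f") -> None:
    """Write a recording as TSV matrix + JSON sidecar (+ events TSV)."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, sep="\t", index=False, float_format=fmt)
    sidecar = {
        "rate_hz": rec.rate_hz,
        "channel_labels": list(rec.channel_labels),
        "t0": rec.t0,
        "n_samples": rec.n_samples,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    if events_path is not None:
        write_events(rec, events_path)


def write_events(rec: Recording, path: str | Path) -> None:
    rows = [{"onset_s": s / rec.rate_hz + rec.t0, "sample": s, "label": lab}
            for s, lab in rec.events]
    pd.DataFrame(rows, columns=["onset_s", "sample", "label"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_events(path: str | Path, n_samples: int) -> list[tuple[int, str]]:
    tbl = pd.read_csv(path, sep="\t")
    if len(tbl) == 0:
        return []
    events = []
    last = -1
    for i, row in tbl.iterrows():
        s = int(row["sample"])
        if s < 0 or s >= n_samples:
            raise ValueError(
                f"{path}, line {i + 2}: event sample {s} outside recording")
        if s <= last:
            raise ValueError(f"{path}, line {i + 2}: events not sorted")
        last = s
        events.append((s, str(row["label"])))
    return events


def read_recording(path: str | Path,
                   events_path: str | Path | None = None) -> Recording:
    """Read a recording from native TSV+JSON or from an EDF file."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        sidecar = json.loads(_sidecar_path(path).read_text())
        df = pd.read_csv(path, sep="\t")
        if list(df.columns) != list(sidecar["channel_labels"]):
            raise ValueError("channel labels in TSV header do not match sidecar")
        rec = Recording(data=df.to_numpy().T, rate_hz=float(sidecar["rate_hz"]),
                        channel_labels=list(sidecar["channel_labels"]),
                        t0=float(sidecar.get("t0", 0.0)))
    if events_path is not None:
        rec.events = read_events(events_path, rec.n_samples)
    return rec


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires mne") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(data=raw.get_data() * 1e6, rate_hz=float(raw.info["sfreq"]),
                     channel_labels=list(raw.ch_names))


class _NumpyJSON(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True,
                                     cls=_NumpyJSON))
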