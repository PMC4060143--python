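"""Minimal EDF (European Data Format) writing and reading.

Sessions are written as one EDF file per subject and condition (EEG plus
the respiration belt channel) with a JSON sidecar holding the generating
configuration. Reading goes through :mod:`mne`, so files written here are
interoperable with standard tooling; the writer exists because only an EDF
*reader* dependency is available.

EDF stores 16-bit integers against a per-channel physical range, so a
write/read round trip is exact only up to that quantization step.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .core import CHANNELS, REGION_MAP, Recording

_HDR = 256


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, recordings: list[Recording], record_duration: float = 1.0):
    """Write one or more same-rate recordings into a single EDF file.

    Channels are stacked in the given order. The signal is truncated to a
    whole number of data records.
    """
    path = Path(path)
    fs = recordings[0].fs
    for rec in recordings:
        if rec.fs != fs:
            raise ValueError("all recordings must share one sampling rate")
    data = np.vstack([rec.samples for rec in recordings])
    labels = [c for rec in recordings for c in rec.channel_labels]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels across recordings")

    spr = fs * record_duration
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("fs * record_duration must be an integer")
    spr = int(round(spr))
    n_records = data.shape[1] // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    data = data[:, : n_records * spr]

    ns = data.shape[0]
    phys_min, phys_max, digital = [], [], []
    for row in data:
        lo, hi = float(row.min()), float(row.max())
        if hi - lo < 1e-6:
            lo, hi = lo - 1.0, hi + 1.0
        # pad the range so rounding never clips
        span = hi - lo
        lo -= 0.001 * span
        hi += 0.001 * span
        phys_min.append(lo)
        phys_max.append(hi)
        scaled = (row - lo) / (hi - lo) * 65535.0 - 32768.0
        digital.append(np.clip(np.round(scaled), -32768, 32767).astype("<i2"))
    digital = np.array(digital)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate X X X X", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(_HDR * (1 + ns)), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field(f"{record_duration:g}", 8))
        fh.write(_field(str(ns), 4))

        def col(fmt, width):
            for i in range(ns):
                fh.write(_field(fmt(i), width))

        col(lambda i: labels[i], 16)
        col(lambda i: "", 80)  # transducer
        col(lambda i: "uV", 8)
        col(lambda i: f"{phys_min[i]:.8g}"[:8], 8)
        col(lambda i: f"{phys_max[i]:.8g}"[:8], 8)
        col(lambda i: "-32768", 8)
        col(lambda i: "32767", 8)
        col(lambda i: "", 80)  # prefiltering
        col(lambda i: str(spr), 8)
        col(lambda i: "", 32)

        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf(path) -> Recording:
    """Read an EDF/BDF file into a :class:`Recording` (amplitudes in uV).

    Channel labels found in the standard montage get region assignments;
    unknown labels are kept but unmapped.
    """
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for uV-dimensioned data
    labels = tuple(raw.ch_names)
    region_map = {c: REGION_MAP[c] for c in labels if c in REGION_MAP}
    return Recording(
        samples=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        region_map=region_map,
    )


def write_session(
    out_dir,
    eeg: Recording,
    resp: Recording,
    config=None,
) -> Path:
    """Write one session (EEG + respiration) plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{eeg.subject_id or 'subject'}_{eeg.condition or 'unlabelled'}"
    edf_path = out_dir / f"{stem}.edf"
    write_edf(edf_path, [eeg, resp])
    sidecar = {
        "subject_id": eeg.subject_id,
        "condition": eeg.condition,
        "fs": eeg.fs,
        "eeg_channels": list(eeg.channel_labels),
        "respiration_channels": list(resp.channel_labels),
    }
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return edf_path


def split_session(rec: Recording, resp_label: str = "Resp"):
    """Split a combined recording into (eeg, respiration) parts."""
    eeg_idx = [i for i, c in enumerate(rec.channel_labels) if c != resp_label]
    resp_idx = [i for i, c in enumerate(rec.channel_labels) if c == resp_label]
    if not resp_idx:
        raise ValueError(f"no channel labelled {resp_label!r}")
    labels = tuple(rec.channel_labels[i] for i in eeg_idx)
    eeg = Recording(
        samples=rec.samples[eeg_idx],
        fs=rec.fs,
        channel_labels=labels,
        region_map={c: REGION_MAP[c] for c in labels if c in REGION_MAP},
        condition=rec.condition,
        subject_id=rec.subject_id,
    )
    resp = Recording(
        samples=rec.samples[resp_idx],
        fs=rec.fs,
        channel_labels=(resp_label,),
        condition=rec.condition,
        subject_id=rec.subject_id,
    )
    return eeg, resp
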