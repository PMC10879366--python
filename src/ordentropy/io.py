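"""Readers and writers: recordings (EDF, CSV), events, score tables.

CSV dialect throughout: comma-separated, header row, "." decimal, UTF-8,
times in seconds as floats.

EDF support: reading goes through ``mne.io.read_raw_edf``.  Writing uses a
minimal EDF+-compatible writer implemented here (fixed-width ASCII header
plus little-endian int16 data records, one record per second), sufficient
for continuous multichannel signals with a single physical range; samples
are stored in microvolts.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DataError, EegRecording, EventAnnotations
from .entropy import SCORE_NAMES, EntropyScoreSeries

# ---------------------------------------------------------------- recordings


def read_recording(path, fmt: str | None = None) -> EegRecording:
    """Read a recording from EDF or CSV (format inferred from the suffix).

    The four required channels Fp1/Fp2/P3/P4 must be present
    (case-insensitive label match); other channels are kept as-is.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "edf":
        rec = _read_edf(path)
    elif fmt == "csv":
        rec = _read_csv(path)
    else:
        raise DataError(f"unsupported recording format {fmt!r} (use edf or csv)")
    rec.require_channels()
    return rec


def _read_csv(path: Path) -> EegRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise DataError(f"{path}: CSV recording needs a time_s column")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise DataError(f"{path}: need at least 2 samples to infer the rate")
    steps = np.diff(t)
    if steps.min() <= 0 or (np.abs(steps - steps.mean()) > 1e-6 * steps.mean()).any():
        raise DataError(f"{path}: nonuniform time step; cannot infer sampling rate")
    labels = [c for c in df.columns if c != "time_s"]
    return EegRecording(
        channel_labels=labels, fs=1.0 / float(steps.mean()),
        samples=df[labels].to_numpy(dtype=float).T, start_time_s=float(t[0]),
    )


def _read_edf(path: Path) -> EegRecording:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    # EDF convention prefixes labels with the signal type ("EEG Fp1")
    labels = [ch.removeprefix("EEG ").strip() for ch in raw.ch_names]
    return EegRecording(
        channel_labels=labels, fs=float(raw.info["sfreq"]),
        samples=raw.get_data() * 1e6,  # mne loads EEG in volts
    )


def write_recording_csv(rec: EegRecording, path) -> None:
    t = rec.start_time_s + np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t})
    for lab, row in zip(rec.channel_labels, rec.samples):
        df[lab] = row
    df.to_csv(path, index=False)


def write_recording_edf(rec: EegRecording, path) -> None:
    """Write a continuous EDF file (16-bit, physical dimension uV).

    One data record per second; the recording is truncated to a whole
    number of seconds, and the sampling rate must be an integer.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise DataError(f"EDF writer needs an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise DataError("recording shorter than one EDF data record (1 s)")
    data = rec.samples[:, : n_rec * spr]
    n_ch = len(rec.channel_labels)

    phys_max = float(np.max(np.abs(data)))
    phys_max = max(phys_max, 1.0) * 1.01
    dig_min, dig_max = -32768, 32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")

    def f(value, width) -> bytes:
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    hdr = _io.BytesIO()
    hdr.write(f("0", 8))                          # version
    hdr.write(f("X X X X", 80))                   # patient id (anonymous)
    hdr.write(f("Startdate X X X X", 80))         # recording id
    hdr.write(f("01.01.00", 8))                   # start date
    hdr.write(f("00.00.00", 8))                   # start time
    hdr.write(f(256 + 256 * n_ch, 8))             # header bytes
    hdr.write(f("", 44))                          # reserved
    hdr.write(f(n_rec, 8))                        # number of records
    hdr.write(f("1", 8))                          # record duration, s
    hdr.write(f(n_ch, 4))                         # number of signals
    for lab in rec.channel_labels:
        hdr.write(f(f"EEG {lab}", 16))            # label
    for _ in range(n_ch):
        hdr.write(f("", 80))                      # transducer
    for _ in range(n_ch):
        hdr.write(f("uV", 8))                     # physical dimension
    for _ in range(n_ch):
        hdr.write(f(f"{-phys_max:.6g}", 8))       # physical minimum
    for _ in range(n_ch):
        hdr.write(f(f"{phys_max:.6g}", 8))        # physical maximum
    for _ in range(n_ch):
        hdr.write(f(dig_min, 8))                  # digital minimum
    for _ in range(n_ch):
        hdr.write(f(dig_max, 8))                  # digital maximum
    for _ in range(n_ch):
        hdr.write(f("", 80))                      # prefiltering
    for _ in range(n_ch):
        hdr.write(f(spr, 8))                      # samples per record
    for _ in range(n_ch):
        hdr.write(f("", 32))                      # reserved

    with open(path, "wb") as fh:
        fh.write(hdr.getvalue())
        # records: for each second, each channel's samples contiguously
        rec3d = digital.reshape(n_ch, n_rec, spr)
        for r in range(n_rec):
            fh.write(rec3d[:, r, :].tobytes())


# -------------------------------------------------------------------- events


def read_events(path) -> list[EventAnnotations]:
    """Read the events CSV (header: patient_id, lor_s, ror_s)."""
    df = pd.read_csv(path)
    needed = ["patient_id", "lor_s", "ror_s"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"{path}: events file missing column(s) {missing}")
    dup = df["patient_id"][df["patient_id"].duplicated()]
    if len(dup):
        raise DataError(f"{path}: duplicate patient_id {sorted(set(dup))}")
    return [
        EventAnnotations(patient_id=str(row.patient_id),
                         lor_s=float(row.lor_s), ror_s=float(row.ror_s))
        for row in df.itertuples()
    ]


def write_events(events: list[EventAnnotations], path) -> None:
    pd.DataFrame(
        [{"patient_id": e.patient_id, "lor_s": e.lor_s, "ror_s": e.ror_s}
         for e in events]
    ).to_csv(path, index=False)


# -------------------------------------------------------------- score tables


def write_scores(series: dict[str, EntropyScoreSeries], path) -> None:
    """Per-patient score table: columns time_s, PE, STE_FP, STE_PF, STE_UND,
    STE_MEAN on the common 1 s grid."""
    ref = series[SCORE_NAMES[0]]
    df = pd.DataFrame({"time_s": ref.timestamps_s})
    for name in SCORE_NAMES:
        s = series[name]
        if not np.array_equal(s.timestamps_s, ref.timestamps_s):
            raise DataError(f"score series {name} not on the common time grid")
        df[name] = s.values
    df.to_csv(path, index=False)


def read_scores(path, patient_id: str = "") -> dict[str, EntropyScoreSeries]:
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", *SCORE_NAMES) if c not in df.columns]
    if missing:
        raise DataError(f"{path}: score table missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    return {
        name: EntropyScoreSeries(
            patient_id=patient_id, score_name=name, timestamps_s=t,
            values=df[name].to_numpy(dtype=float),
        )
        for name in SCORE_NAMES
    }
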