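"""Recording container I/O: EDF signals plus a JSON sidecar.

The signal data is stored as plain 16-bit EDF.  No EDF *writer* library is
part of this package's dependency set, so the writer here is a compact,
self-contained implementation of the format (256-byte fixed header, 256 bytes
per signal, int16 little-endian data records); files it produces are read
back through :mod:`mne`, which serves as an independent implementation of the
reader side.  Trial schedule, blink ground truth and montage extras that EDF
cannot carry go into a ``.json`` sidecar next to the signal file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .synth import BlinkTruth, MontageSpec, Recording, TrialSchedule

_DIG_MIN, _DIG_MAX = -32768, 32767


class RecordingIOError(ValueError):
    """Malformed or inconsistent recording container."""


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise RecordingIOError(f"field {s!r} exceeds EDF width {width}")
    return s.ljust(width).encode("ascii")


def quantization_step(physical_min: float, physical_max: float) -> float:
    """Physical resolution of one digital unit in the EDF container."""
    return (physical_max - physical_min) / (_DIG_MAX - _DIG_MIN)


def write_recording(rec: Recording, path) -> Path:
    """Write ``rec`` to ``path`` (EDF) with a JSON sidecar; returns EDF path."""
    path = Path(path).with_suffix(".edf")
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise RecordingIOError("EDF container requires an integer sampling rate")
    fs = int(round(fs))
    n_ch, n_samples = rec.data.shape
    n_records = int(np.ceil(n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samples] = rec.data

    # symmetric physical range per channel, with headroom against clipping
    absmax = np.maximum(np.abs(padded).max(axis=1) * 1.01, 1.0)
    pmin, pmax = -absmax, absmax

    header = b"".join([
        _ascii(0, 8), _ascii("X X X X", 80), _ascii("Startdate X X X X", 80),
        _ascii("01.01.00", 8), _ascii("00.00.00", 8),
        _ascii(256 * (1 + n_ch), 8), _ascii("", 44),
        _ascii(n_records, 8), _ascii(1, 8), _ascii(n_ch, 4),
    ])
    labels = list(rec.montage.ch_names)
    sig = b"".join([
        b"".join(_ascii(l, 16) for l in labels),
        b"".join(_ascii("", 80) for _ in labels),
        b"".join(_ascii("uV", 8) for _ in labels),
        b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in pmin),
        b"".join(_ascii(f"{v:.6g}"[:8], 8) for v in pmax),
        b"".join(_ascii(_DIG_MIN, 8) for _ in labels),
        b"".join(_ascii(_DIG_MAX, 8) for _ in labels),
        b"".join(_ascii("", 80) for _ in labels),
        b"".join(_ascii(fs, 8) for _ in labels),
        b"".join(_ascii("", 32) for _ in labels),
    ])
    # re-read the truncated physical ranges actually written to the header, so
    # quantization uses exactly what a reader will see
    pmin_w = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_w = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    scale = (pmax_w - pmin_w) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((padded - pmin_w[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig)
        # records: per record, channel-by-channel contiguous
        rec3d = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(rec3d).tobytes())

    sidecar = {
        "fs": fs,
        "n_samples": int(n_samples),
        "montage": {
            "eeg_labels": list(rec.montage.eeg_labels),
            "eog_labels": list(rec.montage.eog_labels),
            "reference_label": rec.montage.reference_label,
            "fs": fs,
        },
        "schedule": rec.events.to_dict() if rec.events is not None else None,
        "blink_truth": [dataclasses.asdict(b) for b in rec.blink_truth],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path) -> Recording:
    """Read an EDF + JSON sidecar pair written by :func:`write_recording`.

    The EDF signals are parsed by :mod:`mne` (an independent reader); header
    and sidecar sampling rates are cross-checked.
    """
    import mne

    path = Path(path).with_suffix(".edf")
    side_path = path.with_suffix(".json")
    if not side_path.exists():
        raise RecordingIOError(f"missing JSON sidecar: {side_path}")
    try:
        side = json.loads(side_path.read_text())
    except json.JSONDecodeError as e:
        raise RecordingIOError(f"sidecar is not valid JSON: {e}") from e
    for key in ("fs", "n_samples", "montage"):
        if key not in side:
            raise RecordingIOError(f"sidecar missing required field {key!r}")

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if abs(raw.info["sfreq"] - side["fs"]) > 1e-6:
        raise RecordingIOError(
            f"fs mismatch: EDF header says {raw.info['sfreq']}, "
            f"sidecar says {side['fs']}")
    data = raw.get_data() * 1e6      # mne converts uV-dimensioned EDF to V
    data = data[:, : side["n_samples"]]

    m = side["montage"]
    montage = MontageSpec(tuple(m["eeg_labels"]), tuple(m["eog_labels"]),
                          m["reference_label"], float(m["fs"]))
    if list(raw.ch_names) != list(montage.ch_names):
        raise RecordingIOError("channel labels differ between EDF and sidecar")
    schedule = TrialSchedule.from_dict(side["schedule"]) if side.get("schedule") else None
    blinks = [BlinkTruth(**b) for b in side.get("blink_truth", [])]
    return Recording(data, montage, schedule, blinks)
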