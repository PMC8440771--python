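"""Minimal European Data Format (EDF) writer.

Writes continuous multichannel recordings as standard 16-bit EDF with one
data record per second, enough for any EDF-compliant reader (the test
suite round-trips files through MNE's built-in EDF reader).  Only the
features this package needs are implemented: uniform sampling, a common
integer sampling rate across channels, and physical units of µV.
"""

from __future__ import annotations

from datetime import datetime
from pathlib import Path

import numpy as np

from .recording import EEGRecording

__all__ = ["write_edf"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii_field(value: str, width: int) -> bytes:
    b = value.encode("ascii", "replace")[:width]
    return b.ljust(width)


def write_edf(recording: EEGRecording, path: str | Path,
              patient: str = "X", recording_id: str = "sleepdrive",
              start: datetime | None = None) -> Path:
    """Write a recording to ``path`` as 16-bit EDF (µV physical units).

    The sampling rate must be a positive integer (samples per 1 s data
    record).  Trailing samples that do not fill a whole record are dropped.
    """
    path = Path(path)
    sfreq = recording.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9 or sfreq <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))
    n_records = recording.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1 s data record")
    n_sig = len(recording.channels)
    data = recording.data[:, : n_records * spr]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None] + _DIG_MIN),
        _DIG_MIN, _DIG_MAX).astype("<i2")

    start = start or datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(patient, 80),
        _ascii_field(recording_id, 80),
        _ascii_field(start.strftime("%d.%m.%y"), 8),
        _ascii_field(start.strftime("%H.%M.%S"), 8),
        _ascii_field(str(256 * (1 + n_sig)), 8),
        _ascii_field("", 44),
        _ascii_field(str(n_records), 8),
        _ascii_field("1", 8),
        _ascii_field(str(n_sig), 4),
    ])
    fields = [
        [_ascii_field(lb, 16) for lb in recording.channels],
        [_ascii_field("AgAgCl electrode", 80)] * n_sig,
        [_ascii_field("uV", 8)] * n_sig,
        [_ascii_field(f"{v:.6g}"[:8], 8) for v in phys_min],
        [_ascii_field(f"{v:.6g}"[:8], 8) for v in phys_max],
        [_ascii_field(str(_DIG_MIN), 8)] * n_sig,
        [_ascii_field(str(_DIG_MAX), 8)] * n_sig,
        [_ascii_field("", 80)] * n_sig,
        [_ascii_field(str(spr), 8)] * n_sig,
        [_ascii_field("", 32)] * n_sig,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.writelines(group)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    return path
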