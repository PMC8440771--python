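"""In-memory containers for multichannel EEG/EOG recordings and artifact masks.

A recording holds a (channels x samples) array of microvolt traces sampled
uniformly, together with channel labels and roles.  The montage used
throughout the package is the midline scalp line (Fz, Cz, Pz, Oz), a
bilateral EOG pair (EOG-L, EOG-R) and the two mastoids (A1, A2) that serve
as the offline reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default role of each montage label
DEFAULT_ROLES: dict[str, str] = {
    "Fz": "scalp",
    "Cz": "scalp",
    "Pz": "scalp",
    "Oz": "scalp",
    "EOG-L": "eog",
    "EOG-R": "eog",
    "A1": "mastoid",
    "A2": "mastoid",
}

SCALP_CHANNELS = ("Fz", "Cz", "Pz", "Oz")
EOG_CHANNELS = ("EOG-L", "EOG-R")
MASTOID_CHANNELS = ("A1", "A2")


@dataclass
class EEGRecording:
    """Uniformly sampled multichannel recording in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Channel traces in µV.
    channels : list of str
        Unique channel labels, one per row of ``data``.
    sfreq : float
        Sampling rate in Hz (> 0).
    start_s : float
        Time offset of the first sample from drive start, in seconds.
    roles : dict, optional
        Channel label -> role ("scalp" | "eog" | "mastoid").  Labels absent
        from the mapping fall back to :data:`DEFAULT_ROLES` and then to
        "scalp".
    """

    data: np.ndarray
    channels: list[str]
    sfreq: float
    start_s: float = 0.0
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channels)} channel labels were given"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if not self.sfreq > 0:
            raise ValueError("sampling rate must be positive")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    @property
    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.sfreq

    def role(self, label: str) -> str:
        return self.roles.get(label, DEFAULT_ROLES.get(label, "scalp"))

    def get(self, label: str) -> np.ndarray:
        """Return the trace of channel ``label`` (a view, not a copy)."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None
        return self.data[idx]

    def pick(self, labels: list[str]) -> "EEGRecording":
        """Sub-recording restricted to ``labels`` (copies the data)."""
        rows = [self.channels.index(lb) for lb in labels]
        return EEGRecording(
            self.data[rows].copy(), list(labels), self.sfreq, self.start_s,
            dict(self.roles),
        )

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.data.copy(), list(self.channels), self.sfreq, self.start_s,
            dict(self.roles),
        )


def _merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/touching half-open intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2))
    iv = np.asarray(intervals, dtype=float)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].copy()]
    for lo, hi in iv[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append(np.array([lo, hi]))
    return np.array(merged)


@dataclass
class ArtifactMask:
    """Per-recording exclusion intervals ``[start_s, end_s)``.

    Intervals are stored sorted, merged and clipped to
    ``[0, recording_duration_s)``.
    """

    intervals: np.ndarray
    recording_duration_s: float

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        iv = np.clip(iv, 0.0, self.recording_duration_s)
        iv = iv[iv[:, 1] > iv[:, 0]]
        self.intervals = _merge_intervals(iv)

    @property
    def excluded_s(self) -> float:
        if len(self.intervals) == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))

    @property
    def excluded_fraction(self) -> float:
        return self.excluded_s / self.recording_duration_s

    def contains(self, t: float | np.ndarray) -> np.ndarray:
        """Boolean: does time ``t`` fall inside an excluded interval?"""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros(t.shape, dtype=bool)
        for lo, hi in self.intervals:
            out |= (t >= lo) & (t < hi)
        return out

    def complement(self) -> np.ndarray:
        """Clean intervals = recording minus mask, as an (n, 2) array."""
        out = []
        cursor = 0.0
        for lo, hi in self.intervals:
            if lo > cursor:
                out.append((cursor, lo))
            cursor = max(cursor, hi)
        if cursor < self.recording_duration_s:
            out.append((cursor, self.recording_duration_s))
        return np.array(out).reshape(-1, 2)


@dataclass
class Segment:
    """One artifact-free stretch of a recording."""

    start_s: float
    data: np.ndarray  # (n_channels, n_samples)

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ContiguousSegments:
    """Clean stretches surviving artifact excision, with their sample data."""

    segments: list[Segment]
    channels: list[str]
    sfreq: float

    @property
    def total_retained_s(self) -> float:
        return sum(s.n_samples for s in self.segments) / self.sfreq

    @property
    def intervals(self) -> np.ndarray:
        return np.array(
            [[s.start_s, s.start_s + s.n_samples / self.sfreq]
             for s in self.segments]
        ).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.segments)
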