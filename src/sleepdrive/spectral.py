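"""Welch spectral estimation and band-specific envelope synchrony (BDM).

The binarized derivative method (BDM) reduces each channel's band-limited
power envelope to the sign of its first derivative (+1 = power rising,
−1 = falling) and scores, at every sample, how unanimously the channels
move together.  The per-sample agreement is |Σ_c s_c| / C, whose time
average is the synchrony scalar: 1 when all channels' envelopes rise and
fall together, and E|Σ| / C for independent channels (0.375 for C = 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import ContiguousSegments

__all__ = [
    "BandDefinition", "DEFAULT_BANDS", "PSDResult",
    "welch_psd", "bdm_synchrony", "synchrony_profile", "BandSynchrony",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[low_hz, high_hz]``."""

    name: str
    low_hz: float
    high_hz: float

    def validate(self, sfreq: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"band {self.name}: need 0 < low < high")
        if self.high_hz >= sfreq / 2:
            raise ValueError(
                f"band {self.name}: high edge {self.high_hz} Hz is at or "
                f"above Nyquist ({sfreq / 2} Hz)"
            )


#: canonical band set: delta, theta, alpha, beta, gamma
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 25.0),
    BandDefinition("gamma", 26.0, 40.0),
)


@dataclass
class PSDResult:
    """Welch PSD on a common frequency grid.

    ``power`` is (n_channels, n_freqs) in µV²/Hz; ``mean_power`` is the
    channel average.
    """

    freqs: np.ndarray
    power: np.ndarray
    channels: list[str]

    @property
    def mean_power(self) -> np.ndarray:
        return self.power.mean(axis=0)


def welch_psd(segments: ContiguousSegments,
              window_s: float = 4.0,
              overlap_frac: float = 0.5) -> PSDResult:
    """Average Welch periodogram over all clean segments.

    Each segment at least ``window_s`` long contributes Hann-windowed
    periodograms; segment PSDs are combined weighted by segment duration.

    Raises
    ------
    ValueError
        If no segment is at least ``window_s`` long.
    """
    sfreq = segments.sfreq
    nperseg = int(round(window_s * sfreq))
    noverlap = int(round(nperseg * overlap_frac))
    usable = [s for s in segments.segments if s.n_samples >= nperseg]
    if not usable:
        raise ValueError(
            f"no clean segment is at least {window_s} s long; cannot "
            "estimate a Welch PSD"
        )
    acc = None
    total_w = 0.0
    freqs = None
    for seg in usable:
        freqs, pxx = signal.welch(seg.data, fs=sfreq, nperseg=nperseg,
                                  noverlap=noverlap, axis=1)
        w = seg.n_samples
        acc = pxx * w if acc is None else acc + pxx * w
        total_w += w
    return PSDResult(freqs, acc / total_w, list(segments.channels))


# ---------------------------------------------------------------------------
# BDM synchrony
# ---------------------------------------------------------------------------

def _band_sos(band: BandDefinition, sfreq: float, order: int = 4) -> np.ndarray:
    return signal.butter(order, [band.low_hz, band.high_hz], "bandpass",
                         fs=sfreq, output="sos")


def envelope_sign_pattern(data: np.ndarray,
                          band: BandDefinition,
                          sfreq: float) -> np.ndarray:
    """Binarized envelope derivative for each channel of one segment.

    Steps: band-pass filter, power envelope via the squared magnitude of the
    analytic (Hilbert) signal, first difference, signum (ties mapped to +1).
    Returns an (n_channels, n_samples - 1) array of ±1.
    """
    band.validate(sfreq)
    sos = _band_sos(band, sfreq)
    filtered = signal.sosfiltfilt(sos, data, axis=1)
    envelope = np.abs(signal.hilbert(filtered, axis=1)) ** 2
    deriv = np.diff(envelope, axis=1)
    return np.where(deriv >= 0, 1.0, -1.0)


def _segment_agreement(signs: np.ndarray) -> np.ndarray:
    """Per-sample agreement |Σ_c s_c| / C in [0, 1]."""
    return np.abs(signs.sum(axis=0)) / signs.shape[0]


def bdm_synchrony(segments: ContiguousSegments,
                  band: BandDefinition,
                  edge_guard_s: float = 1.0,
                  min_segment_s: float | None = None) -> float:
    """Band-specific BDM synchrony across channels, in [0, 1].

    Each clean segment is filtered independently (filtering never crosses
    artifact-excised gaps); ``edge_guard_s`` is dropped at both segment
    boundaries to discard filter edge effects; per-segment time averages of
    the agreement are combined weighted by retained duration.

    Raises
    ------
    ValueError
        If fewer than two channels are present (synchrony undefined) or no
        segment survives the guard/minimum-length requirements.
    """
    if len(segments.channels) < 2:
        raise ValueError("synchrony requires at least two channels")
    sfreq = segments.sfreq
    guard = int(round(edge_guard_s * sfreq))
    # a segment must leave room for the guard plus a few cycles of the
    # band's low edge
    min_len = min_segment_s if min_segment_s is not None else 2.0 / band.low_hz
    min_samples = int(round(min_len * sfreq)) + 2 * guard
    acc = 0.0
    total_w = 0
    for seg in segments.segments:
        if seg.n_samples < max(min_samples, 2 * guard + 2):
            continue
        signs = envelope_sign_pattern(seg.data, band, sfreq)
        if guard:
            signs = signs[:, guard:-guard]
        agreement = _segment_agreement(signs)
        acc += agreement.sum()
        total_w += agreement.size
    if total_w == 0:
        raise ValueError(
            f"no clean segment long enough for band {band.name!r}"
        )
    return float(acc / total_w)


@dataclass
class BandSynchrony:
    """Per-band synchrony scalars for one session."""

    synchrony: dict[str, float]
    retained_s: float

    def __getitem__(self, band_name: str) -> float:
        return self.synchrony[band_name]


def synchrony_profile(segments: ContiguousSegments,
                      bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                      edge_guard_s: float = 1.0) -> BandSynchrony:
    """One BDM synchrony scalar per band for one session's clean segments."""
    if len(segments) == 0:
        raise ValueError("empty segment set; nothing to synchronize")
    values = {
        band.name: bdm_synchrony(segments, band, edge_guard_s=edge_guard_s)
        for band in bands
    }
    return BandSynchrony(values, segments.total_retained_s)
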