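"""EEG preprocessing: mastoid re-referencing, the offline filter chain, and
automated excision of ocular-artifact segments.

The cleaning strategy is deliberately simple and conservative: the product
of the two EOG traces is a sensitive marker of blinks and eye movements
(both in-phase and anti-phase deflections make its magnitude large), and a
fixed window centred on every super-threshold excursion is excised before
any spectral or synchrony analysis of the scalp channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import (
    ArtifactMask,
    ContiguousSegments,
    EEGRecording,
    MASTOID_CHANNELS,
    Segment,
)


@dataclass(frozen=True)
class FilterSpec:
    """Offline filter chain: zero-phase band-pass plus mains notch.

    Defaults follow a clinical EEG amplifier convention: 0.4823 Hz high-pass
    (equivalent to a 0.33 s time constant, 1/(2π·0.33) ≈ 0.482) with a
    12 dB/octave slope, 70 Hz low-pass at 24 dB/octave and a 60 Hz mains
    notch.  Slopes are realised as Butterworth orders 2 and 4, applied
    forward-backward for zero phase.
    """

    highpass_hz: float = 0.4823
    highpass_order: int = 2          # 12 dB/octave
    lowpass_hz: float = 70.0
    lowpass_order: int = 4           # 24 dB/octave
    notch_hz: float | None = 60.0
    notch_q: float = 30.0

    def validate(self, sfreq: float) -> None:
        nyq = sfreq / 2.0
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError(
                "need 0 < highpass_hz < lowpass_hz, got "
                f"{self.highpass_hz} and {self.lowpass_hz}"
            )
        if self.lowpass_hz >= nyq:
            raise ValueError(
                f"low-pass cutoff {self.lowpass_hz} Hz is at or above the "
                f"Nyquist frequency {nyq} Hz"
            )
        if self.notch_hz is not None and self.notch_hz >= nyq:
            raise ValueError(
                f"notch frequency {self.notch_hz} Hz is at or above the "
                f"Nyquist frequency {nyq} Hz"
            )


def rereference(recording: EEGRecording) -> EEGRecording:
    """Re-reference every scalp/EOG channel to the averaged mastoids.

    Subtracts (A1 + A2)/2 from each non-mastoid channel and drops the
    mastoid channels from the output.

    Raises
    ------
    ValueError
        If a mastoid channel is missing (the error names it).
    """
    for m in MASTOID_CHANNELS:
        if m not in recording.channels:
            raise ValueError(f"mastoid channel {m!r} missing; cannot re-reference")
    ref = 0.5 * (recording.get("A1") + recording.get("A2"))
    keep = [c for c in recording.channels if recording.role(c) != "mastoid"]
    rows = [recording.channels.index(c) for c in keep]
    data = recording.data[rows] - ref[None, :]
    return EEGRecording(data, keep, recording.sfreq, recording.start_s,
                        {c: recording.role(c) for c in keep})


def _sos_chain(spec: FilterSpec, sfreq: float) -> list[np.ndarray]:
    sos = [
        signal.butter(spec.highpass_order, spec.highpass_hz, "highpass",
                      fs=sfreq, output="sos"),
        signal.butter(spec.lowpass_order, spec.lowpass_hz, "lowpass",
                      fs=sfreq, output="sos"),
    ]
    if spec.notch_hz is not None:
        b, a = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=sfreq)
        sos.append(signal.tf2sos(b, a))
    return sos


def filter_chain(recording: EEGRecording,
                 spec: FilterSpec | None = None) -> EEGRecording:
    """Apply the zero-phase band-pass + notch chain to every channel.

    DC is removed by the high-pass stage; each stage is applied with
    ``sosfiltfilt`` (forward-backward, zero phase).
    """
    spec = spec or FilterSpec()
    spec.validate(recording.sfreq)
    out = recording.copy()
    data = out.data - out.data.mean(axis=1, keepdims=True)
    for sos in _sos_chain(spec, recording.sfreq):
        data = signal.sosfiltfilt(sos, data, axis=1)
    out.data = data
    return out


def detect_ocular_artifacts(eog_left: np.ndarray,
                            eog_right: np.ndarray,
                            sfreq: float,
                            k_sd: float = 3.0,
                            window_s: float = 2.0) -> ArtifactMask:
    """Mark eye movements and blinks from the EOG product signal.

    The magnitude of the product of the two EOG traces is used as the
    marker; ``window_s`` seconds centred on every sample whose magnitude
    exceeds ``mean + k_sd * SD`` of the magnitude are excluded.  Overlapping
    windows are merged and the mask is clipped to the recording bounds.

    Returns an empty mask (with a warning) when the product has zero
    variance, i.e. the threshold is undefined.
    """
    eog_left = np.asarray(eog_left, dtype=float)
    eog_right = np.asarray(eog_right, dtype=float)
    if eog_left.shape != eog_right.shape:
        raise ValueError("EOG traces must have the same length")
    n = eog_left.size
    duration_s = n / sfreq
    magnitude = np.abs(eog_left * eog_right)
    sd = magnitude.std()
    if sd == 0.0:
        warnings.warn("EOG product has zero variance; no artifacts marked")
        return ArtifactMask(np.empty((0, 2)), duration_s)
    threshold = magnitude.mean() + k_sd * sd
    hits = np.flatnonzero(magnitude > threshold)
    if hits.size == 0:
        return ArtifactMask(np.empty((0, 2)), duration_s)
    centers = hits / sfreq
    half = window_s / 2.0
    intervals = np.column_stack([centers - half, centers + half])
    return ArtifactMask(intervals, duration_s)


def apply_mask(recording: EEGRecording,
               mask: ArtifactMask,
               min_segment_s: float = 2.0) -> ContiguousSegments:
    """Cut the recording into clean stretches at least ``min_segment_s`` long.

    Retained plus excluded duration always equals the recording duration to
    within one sample (segments shorter than ``min_segment_s`` are dropped
    from the output but still counted as clean time by the mask).
    """
    sfreq = recording.sfreq
    clean = mask.complement()
    segments: list[Segment] = []
    for lo, hi in clean:
        i0 = int(round(lo * sfreq))
        i1 = int(round(hi * sfreq))
        i1 = min(i1, recording.n_samples)
        if (i1 - i0) / sfreq >= min_segment_s:
            segments.append(Segment(i0 / sfreq, recording.data[:, i0:i1]))
    if not segments:
        warnings.warn("artifact mask leaves no usable segment")
    return ContiguousSegments(segments, list(recording.channels), sfreq)


def preprocess_session(recording: EEGRecording,
                       spec: FilterSpec | None = None,
                       k_sd: float = 3.0,
                       window_s: float = 2.0,
                       min_segment_s: float = 2.0,
                       ) -> tuple[EEGRecording, ArtifactMask, ContiguousSegments]:
    """Full preprocessing: re-reference, filter, mask ocular artifacts.

    Returns the filtered recording (mastoids dropped), the artifact mask
    computed from the filtered EOG pair, and the clean scalp segments.
    """
    reref = rereference(recording)
    filtered = filter_chain(reref, spec)
    mask = detect_ocular_artifacts(filtered.get("EOG-L"), filtered.get("EOG-R"),
                                   filtered.sfreq, k_sd=k_sd, window_s=window_s)
    scalp = filtered.pick([c for c in filtered.channels
                           if filtered.role(c) == "scalp"])
    segments = apply_mask(scalp, mask, min_segment_s=min_segment_s)
    return filtered, mask, segments
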