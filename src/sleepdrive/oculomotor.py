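"""Rule-based detection of slow rolling eye movements (SREMs) on the EOG pair.

SREMs — slow, out-of-phase deflections visible in both EOG channels for at
least half a second — are a physiological signature of the wake-to-sleep
transition.  The detector operationalizes the scoring definition: both
slow-filtered EOG traces must exceed an amplitude threshold while their
short-window correlation is strongly negative, for at least the minimum
duration.  Blinks, which are in-phase across the two channels, fail the
anti-phase criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import ArtifactMask

__all__ = [
    "SREMEvent", "SREMDetectorParams", "SurvivalRecord",
    "detect_srems", "count_srems", "time_to_first_srem",
]


@dataclass(frozen=True)
class SREMDetectorParams:
    """Tunable detector parameters.

    slow_band_hz : pass band isolating rolling eye movements (default
        0.1–1.5 Hz); amplitude and anti-phase gating happen here.
    measure_band_hz : wider band (default 0.1–8 Hz) on which each
        candidate's duration is re-measured.  The slow band alone cannot
        time-resolve 0.5 s — its impulse-response envelope is itself about
        half a second wide — so a brief saccadic spike smeared by the slow
        filter would otherwise masquerade as a slow movement.
    amplitude_threshold_uv : absolute amplitude both channels must exceed;
        ``None`` uses ``robust_scale_mult`` times the MAD-based background
        estimate of each slow-filtered trace, floored at
        ``min_amplitude_uv`` (sub-µV residue is never an eye movement).
    antiphase_threshold : sliding-window Pearson correlation must be at or
        below this (default −0.5).
    corr_window_s : correlation window length (default 0.5 s).
    min_duration_s : minimum event duration (default 0.5 s).
    duration_peak_frac : fraction of the event's wide-band envelope peak
        that defines its measured onset/offset (default 0.35).
    merge_gap_s : events separated by less than this are merged (default
        0.25 s) to avoid double-counting one rolling movement.
    """

    slow_band_hz: tuple[float, float] = (0.1, 1.5)
    measure_band_hz: tuple[float, float] = (0.1, 8.0)
    amplitude_threshold_uv: float | None = None
    robust_scale_mult: float = 3.0
    min_amplitude_uv: float = 5.0
    duration_peak_frac: float = 0.35
    antiphase_threshold: float = -0.5
    corr_window_s: float = 0.5
    min_duration_s: float = 0.5
    merge_gap_s: float = 0.25


@dataclass
class SREMEvent:
    """One detected slow rolling eye movement."""

    onset_s: float
    duration_s: float
    antiphase_score: float  # mean correlation inside the event, in [-1, 0)

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SurvivalRecord:
    """Time to first SREM for one drive, with censoring.

    ``event = 1`` when a SREM was observed at ``time_s``; ``event = 0`` when
    the drive ended (possibly prematurely) without one.
    """

    subject: str
    condition: str
    time_s: float
    event: int


def _slow_filter(x: np.ndarray, sfreq: float,
                 band: tuple[float, float]) -> np.ndarray:
    sos = signal.butter(2, band, "bandpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, x)


def _rolling_corr(x: np.ndarray, y: np.ndarray, win: int) -> np.ndarray:
    """Centered sliding-window Pearson correlation via cumulative sums."""
    n = x.size
    kernel = np.ones(win)

    def box(v: np.ndarray) -> np.ndarray:
        return signal.fftconvolve(v, kernel, mode="same")

    sx, sy = box(x), box(y)
    sxx, syy, sxy = box(x * x), box(y * y), box(x * y)
    cnt = box(np.ones(n))
    cov = sxy / cnt - (sx / cnt) * (sy / cnt)
    vx = np.maximum(sxx / cnt - (sx / cnt) ** 2, 0.0)
    vy = np.maximum(syy / cnt - (sy / cnt) ** 2, 0.0)
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_srems(eog_left: np.ndarray,
                 eog_right: np.ndarray,
                 sfreq: float,
                 params: SREMDetectorParams | None = None,
                 artifact_mask: ArtifactMask | None = None,
                 ) -> list[SREMEvent]:
    """Detect slow rolling eye movements on a preprocessed EOG pair.

    A sample is SREM-candidate when both slow-filtered traces exceed the
    amplitude threshold and the sliding-window correlation between them is
    at or below the anti-phase threshold.  Candidate runs are merged across
    gaps shorter than ``merge_gap_s`` and kept when at least
    ``min_duration_s`` long.  Events overlapping ``artifact_mask`` (if
    given) are discarded.
    """
    params = params or SREMDetectorParams()
    eog_left = np.asarray(eog_left, dtype=float)
    eog_right = np.asarray(eog_right, dtype=float)
    if eog_left.shape != eog_right.shape:
        raise ValueError("EOG traces must have the same length")

    slow_l = _slow_filter(eog_left, sfreq, params.slow_band_hz)
    slow_r = _slow_filter(eog_right, sfreq, params.slow_band_hz)

    if params.amplitude_threshold_uv is not None:
        thr_l = thr_r = params.amplitude_threshold_uv
    else:
        # 1.4826 * MAD estimates the Gaussian background SD robustly even
        # when large deflections are present; the absolute floor keeps
        # sub-physiological residue (e.g. filter ringing of brief saccadic
        # spikes) from counting as slow deflections on very quiet traces
        thr_l = max(params.robust_scale_mult * 1.4826
                    * np.median(np.abs(slow_l)), params.min_amplitude_uv)
        thr_r = max(params.robust_scale_mult * 1.4826
                    * np.median(np.abs(slow_r)), params.min_amplitude_uv)

    win = max(int(round(params.corr_window_s * sfreq)), 2)
    corr = _rolling_corr(slow_l, slow_r, win)

    candidate = (
        (np.abs(slow_l) > thr_l)
        & (np.abs(slow_r) > thr_r)
        & (corr <= params.antiphase_threshold)
    )

    gap = int(round(params.merge_gap_s * sfreq))
    runs = _runs(candidate)
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and i0 - merged[-1][1] < gap:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])

    wide_l = _slow_filter(eog_left, sfreq, params.measure_band_hz)
    wide_r = _slow_filter(eog_right, sfreq, params.measure_band_hz)
    pad = int(round(1.0 * sfreq))
    n = eog_left.size
    events: list[SREMEvent] = []
    for i0, i1 in merged:
        span = _measured_span(wide_l, wide_r, i0, i1, pad, n,
                              params.duration_peak_frac,
                              params.min_amplitude_uv)
        if span is None:
            continue
        j0, j1 = span
        onset = j0 / sfreq
        duration = (j1 - j0) / sfreq
        if duration < params.min_duration_s:
            continue
        if artifact_mask is not None:
            probe = np.array([onset, onset + duration / 2, onset + duration])
            if artifact_mask.contains(probe).any():
                continue
        score = float(np.mean(corr[i0:i1]))
        events.append(SREMEvent(onset, duration, min(score, -1e-12)))
    return events


def _measured_span(wide_l: np.ndarray, wide_r: np.ndarray, i0: int, i1: int,
                   pad: int, n: int, peak_frac: float,
                   floor: float) -> tuple[int, int] | None:
    """Onset-to-offset span of a candidate on the wide-band envelopes.

    The span is the contiguous stretch around the candidate's peak where
    both channels' analytic envelopes stay above ``peak_frac`` of their own
    event peak (floored at the absolute minimum amplitude) — approximating
    how a scorer marks a deflection from where it visibly starts to where
    it ends.
    """
    a0, a1 = max(0, i0 - pad), min(n, i1 + pad)
    env_l = np.abs(signal.hilbert(wide_l[a0:a1]))
    env_r = np.abs(signal.hilbert(wide_r[a0:a1]))
    c0, c1 = i0 - a0, i1 - a0
    peak_l = env_l[c0:c1].max()
    peak_r = env_r[c0:c1].max()
    if peak_l <= floor or peak_r <= floor:
        return None
    above = ((env_l > max(peak_frac * peak_l, floor))
             & (env_r > max(peak_frac * peak_r, floor)))
    # contiguous run containing the candidate's peak
    ipeak = c0 + int(np.argmax(env_l[c0:c1] * env_r[c0:c1]))
    if not above[ipeak]:
        return None
    j0 = ipeak
    while j0 > 0 and above[j0 - 1]:
        j0 -= 1
    j1 = ipeak
    while j1 < above.size - 1 and above[j1 + 1]:
        j1 += 1
    return a0 + j0, a0 + j1 + 1


def count_srems(events: list[SREMEvent]) -> int:
    """Number of SREMs in one session."""
    return len(events)


def time_to_first_srem(events: list[SREMEvent],
                       drive_duration_s: float,
                       subject: str = "",
                       condition: str = "",
                       terminated_early_at_s: float | None = None,
                       ) -> SurvivalRecord:
    """Time-to-first-SREM record with censoring at drive end.

    A drive with no SREM is censored at its (possibly premature) end.
    """
    if drive_duration_s <= 0:
        raise ValueError("drive duration must be positive")
    end = drive_duration_s
    if terminated_early_at_s is not None:
        end = min(end, terminated_early_at_s)
    observed = [e for e in events if e.onset_s <= end]
    if observed:
        first = min(e.onset_s for e in observed)
        return SurvivalRecord(subject, condition, float(first), 1)
    return SurvivalRecord(subject, condition, float(end), 0)
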