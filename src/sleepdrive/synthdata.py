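"""Seeded synthetic cohorts of paired drive sessions.

Each subject completes two ~48-minute simulated drives — one manually
controlled, one supervising a self-driving vehicle — in counterbalanced
order.  The generator produces, per session:

* an 8-channel EEG/EOG recording (Fz, Cz, Pz, Oz, EOG-L, EOG-R, A1, A2) in
  which each EEG band is a narrowband carrier amplitude-modulated by a
  mixture of a session-shared slow envelope (weight = the band's coupling
  level for that condition) and a channel-private envelope — the structure
  the BDM synchrony measure is designed to detect;
* injected ocular events: in-phase biexponential blinks and anti-phase
  half-sine slow rolling eye movements (SREMs) lasting 0.5–4 s;
* behavioral outcomes: PVT reaction-time trials (shifted-lognormal body
  plus a lapse tail), an ordinal KSS rating from a thresholded latent
  normal, and a 14-day actigraphy-style sleep history.

SREM counts are negative-binomial via a per-subject gamma frailty shared
between the subject's two drives (which also induces the within-subject
correlation the repeated-measures count models expect).  The self-driving
condition multiplies the SREM rate by ``exp(condition_effect_srem_log_rr)``
and, by default, expresses the habitual-sleep slope only in the
self-driving condition — short sleepers unmask more SREMs when supervising
than when driving.

Every stochastic element is recorded in :class:`GroundTruth`, so detector
recall/precision and model recovery are computable downstream.  All outputs
are deterministic functions of ``(config, seed)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = [
    "CohortConfig", "SubjectSession", "GroundTruth", "BehavioralRecord",
    "Cohort", "generate_cohort", "generate_eeg_eog", "generate_behavioral",
    "REDUCED_PROFILE",
]

_BAND_CENTERS = {  # (center Hz, half-bandwidth Hz) of each synthetic carrier
    "delta": (2.0, 1.0),
    "theta": (5.5, 1.5),
    "alpha": (10.0, 2.0),
    "beta": (19.0, 6.0),
    "gamma": (33.0, 7.0),
}
_BAND_AMPLITUDE_UV = {  # roughly 1/f-shaped band amplitudes
    "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 6.0, "gamma": 3.0,
}

# rng stream tags so each generator draws from an independent substream
_TAG_DESIGN, _TAG_SUBJECT, _TAG_EVENTS, _TAG_SIGNAL, _TAG_BEHAVIOR = range(5)


def _default_band_coupling() -> dict[str, dict[str, float]]:
    # self-driving couples less in delta (strongest), alpha, and mildly
    # theta; beta/gamma unchanged — the direction of the band-specific
    # synchrony findings this pipeline is built to measure
    return {
        "manual": {"delta": 0.60, "theta": 0.50, "alpha": 0.55,
                   "beta": 0.45, "gamma": 0.40},
        "self-driving": {"delta": 0.45, "theta": 0.45, "alpha": 0.45,
                         "beta": 0.45, "gamma": 0.40},
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults emulate the laboratory design: 20 subjects, paired 48-minute
    drives at 500 Hz, a manual-drive SREM mean of 5 with a self-driving log
    rate ratio of ~1.06 (5 → ~14.5), over-dispersed counts, a −0.48/hour
    habitual-sleep slope expressed in the self-driving condition, ~5 ocular
    artifacts per minute, a +1.4 KSS latent shift, and PVT reaction times
    around 300 ms (manual) that slow by ~20 ms with more lapses when
    supervising.
    """

    n_subjects: int = 20
    drive_duration_s: float = 2880.0
    sampling_rate_hz: float = 500.0
    seed: int = 0

    # SREM count model
    manual_srem_mean: float = 5.0
    condition_effect_srem_log_rr: float = 1.0626
    sleep_slope_log_b: float = -0.48
    sleep_slope_conditions: tuple[str, ...] = ("self-driving",)
    nb_dispersion: float = 0.8      # NB2 alpha: Var = mu + alpha mu^2
    srem_temporal_profile: str = "uniform"  # or "ramp"
    srem_duration_range_s: tuple[float, float] = (0.6, 4.0)
    srem_amplitude_range_uv: tuple[float, float] = (40.0, 80.0)
    srem_roll_freq_hz: tuple[float, float] = (0.4, 0.9)

    # habitual sleep
    sleep_mean_h: float = 5.9
    sleep_sd_h: float = 0.9
    sleep_daily_sd_min: float = 45.0

    # EEG structure
    band_coupling: dict[str, dict[str, float]] = field(
        default_factory=_default_band_coupling)
    eeg_noise_uv: float = 2.0
    envelope_bandwidth_hz: float = 0.5

    # ocular artifacts
    artifact_rate_per_min: float = 5.0
    blink_duration_s: float = 0.3
    blink_amplitude_uv: float = 180.0
    eog_noise_uv: float = 4.0

    # KSS
    kss_latent_mean: float = 5.35
    kss_latent_subject_sd: float = 1.6
    kss_latent_noise_sd: float = 1.2
    kss_shift: float = 1.4

    # PVT (adjusted-RT scale, ms)
    n_pvt_trials: int = 45
    pvt_mu_ms: dict[str, float] = field(
        default_factory=lambda: {"manual": 300.0, "self-driving": 320.0})
    pvt_sigma_ms: dict[str, float] = field(
        default_factory=lambda: {"manual": 45.0, "self-driving": 50.0})
    lapse_prob: dict[str, float] = field(
        default_factory=lambda: {"manual": 0.015, "self-driving": 0.0375})
    pvt_subject_sd_ms: float = 40.0
    pvt_shift_ms: float = 150.0
    pvt_system_latency_ms: float = 82.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.drive_duration_s <= 0:
            raise ValueError("drive_duration_s must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.manual_srem_mean < 0:
            raise ValueError("manual_srem_mean must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.artifact_rate_per_min < 0:
            raise ValueError("artifact_rate_per_min must be >= 0")
        for cond, bands in self.band_coupling.items():
            for band, w in bands.items():
                if not 0.0 <= w <= 1.0:
                    raise ValueError(
                        f"band_coupling[{cond!r}][{band!r}] = {w} outside [0, 1]"
                    )
        for cond, p in self.lapse_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"lapse_prob[{cond!r}] outside [0, 1]")
        if self.srem_temporal_profile not in ("uniform", "ramp"):
            raise ValueError("srem_temporal_profile must be 'uniform' or 'ramp'")


#: small profile for quick experiments: 8 subjects, 6-minute drives, 250 Hz
REDUCED_PROFILE = dict(n_subjects=8, drive_duration_s=360.0,
                       sampling_rate_hz=250.0)


@dataclass(frozen=True)
class SubjectSession:
    """One drive of one subject."""

    subject: str
    subject_index: int
    condition: str            # "manual" | "self-driving"
    order_index: int          # 0 = first drive of the visit, 1 = second
    drive_duration_s: float
    sampling_rate_hz: float
    terminated_early_at_s: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject, self.condition)


@dataclass
class GroundTruth:
    """Everything the generator randomized, keyed for oracle comparisons."""

    srem_events: dict[tuple[str, str], list[tuple[float, float]]]
    srem_counts: dict[tuple[str, str], int]
    artifact_intervals: dict[tuple[str, str], list[tuple[float, float]]]
    sleep_hours: dict[str, float]
    frailty: dict[str, float]           # per-subject gamma frailty (mean 1)
    band_coupling: dict[str, dict[str, float]]


@dataclass
class BehavioralRecord:
    """Behavioral outcomes for one session."""

    subject: str
    condition: str
    pvt_raw_rts_ms: np.ndarray
    kss: int
    sleep_daily_minutes: np.ndarray     # 14 daily totals, shared per subject


@dataclass
class Cohort:
    """A generated cohort: paired sessions plus ground truth."""

    config: CohortConfig
    sessions: list[SubjectSession]
    truth: GroundTruth

    def session(self, subject: str, condition: str) -> SubjectSession:
        for s in self.sessions:
            if s.subject == subject and s.condition == condition:
                return s
        raise KeyError((subject, condition))

    @property
    def subjects(self) -> list[str]:
        seen: list[str] = []
        for s in self.sessions:
            if s.subject not in seen:
                seen.append(s.subject)
        return seen


def _rng(config: CohortConfig, tag: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, tag, *indices]))


# ---------------------------------------------------------------------------
# cohort-level generation
# ---------------------------------------------------------------------------

def _counterbalanced_orders(config: CohortConfig) -> list[str]:
    """First-drive condition per subject, randomized in blocks of four."""
    rng = _rng(config, _TAG_DESIGN)
    orders: list[str] = []
    block = ["manual", "manual", "self-driving", "self-driving"]
    while len(orders) < config.n_subjects:
        perm = [block[i] for i in rng.permutation(4)]
        orders.extend(perm)
    return orders[: config.n_subjects]


def _place_events(rng: np.random.Generator, k: int, duration_s: float,
                  dur_range: tuple[float, float], profile: str,
                  min_gap_s: float = 2.0) -> list[tuple[float, float]]:
    """Place k non-overlapping events of random duration in a drive."""
    durations = rng.uniform(*dur_range, size=k)
    max_fit = int(duration_s // (dur_range[1] + min_gap_s))
    if k > max_fit:
        warnings.warn(
            f"cannot place {k} SREMs in {duration_s:.0f} s; capping at {max_fit}"
        )
        k = max_fit
        durations = durations[:k]
    events: list[tuple[float, float]] = []
    for d in durations:
        for _ in range(200):
            u = rng.uniform()
            if profile == "ramp":      # event density increasing with time
                u = np.sqrt(u)
            onset = u * (duration_s - d)
            if all(onset + d + min_gap_s < o or o + od + min_gap_s < onset
                   for o, od in events):
                events.append((float(onset), float(d)))
                break
    events.sort()
    return events


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the paired-session design and all event-level ground truth.

    Signals and behavioral outcomes are generated lazily per session by
    :func:`generate_eeg_eog` / :func:`generate_behavioral`; this function
    fixes everything they depend on (counts, onsets, artifacts, sleep,
    frailty, order).
    """
    config.validate()
    orders = _counterbalanced_orders(config)

    sessions: list[SubjectSession] = []
    srem_events: dict[tuple[str, str], list[tuple[float, float]]] = {}
    srem_counts: dict[tuple[str, str], int] = {}
    artifacts: dict[tuple[str, str], list[tuple[float, float]]] = {}
    sleep_hours: dict[str, float] = {}
    frailty: dict[str, float] = {}

    hours = config.drive_duration_s / 3600.0
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        rng_subj = _rng(config, _TAG_SUBJECT, i)
        sleep_h = float(np.clip(
            rng_subj.normal(config.sleep_mean_h, config.sleep_sd_h), 3.0, 10.0))
        sleep_hours[subject] = sleep_h
        if config.nb_dispersion > 0:
            g = float(rng_subj.gamma(1.0 / config.nb_dispersion,
                                     config.nb_dispersion))
        else:
            g = 1.0
        frailty[subject] = g

        first = orders[i]
        for order_index, condition in enumerate(
                [first, "self-driving" if first == "manual" else "manual"]):
            session = SubjectSession(subject, i, condition, order_index,
                                     config.drive_duration_s,
                                     config.sampling_rate_hz)
            sessions.append(session)

            rng_ev = _rng(config, _TAG_EVENTS, i,
                          0 if condition == "manual" else 1)
            log_mu = np.log(max(config.manual_srem_mean, 1e-12))
            if condition == "self-driving":
                log_mu += config.condition_effect_srem_log_rr
            if condition in config.sleep_slope_conditions:
                log_mu += config.sleep_slope_log_b * (sleep_h - config.sleep_mean_h)
            mu = np.exp(log_mu)
            count = int(rng_ev.poisson(mu * g)) if mu > 0 else 0
            events = _place_events(rng_ev, count, config.drive_duration_s,
                                   config.srem_duration_range_s,
                                   config.srem_temporal_profile)
            srem_events[session.key] = events
            srem_counts[session.key] = len(events)

            n_blinks = rng_ev.poisson(config.artifact_rate_per_min * hours * 60)
            starts = np.sort(rng_ev.uniform(
                0, config.drive_duration_s - config.blink_duration_s,
                size=n_blinks))
            # blinking is suppressed while the eyes roll: no blinks inside
            # (or abutting) a SREM window
            def _clear(t: float) -> bool:
                return all(t + config.blink_duration_s < o - 0.5
                           or t > o + d + 0.5 for o, d in events)
            artifacts[session.key] = [
                (float(t), float(t + config.blink_duration_s))
                for t in starts if _clear(float(t))]

    truth = GroundTruth(srem_events, srem_counts, artifacts, sleep_hours,
                        frailty, {c: dict(b)
                                  for c, b in config.band_coupling.items()})
    return Cohort(config, sessions, truth)


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _slow_envelope(rng: np.random.Generator, n: int, sfreq: float,
                   bw_hz: float) -> np.ndarray:
    """Positive slow envelope: |low-pass-filtered Gaussian noise|, mean 1."""
    sos = signal.butter(2, bw_hz, "lowpass", fs=sfreq, output="sos")
    env = np.abs(signal.sosfiltfilt(sos, rng.standard_normal(n)))
    return env / (env.mean() + 1e-30)


def _fm_carrier(rng: np.random.Generator, n: int, sfreq: float,
                f0: float, half_bw: float) -> np.ndarray:
    """Unit-amplitude narrowband carrier: tone with slow frequency drift."""
    sos = signal.butter(2, min(0.2, f0 / 10), "lowpass", fs=sfreq, output="sos")
    drift = signal.sosfiltfilt(sos, rng.standard_normal(n))
    drift /= drift.std() + 1e-30
    freq = f0 + 0.3 * half_bw * drift
    phase = 2 * np.pi * np.cumsum(freq) / sfreq + rng.uniform(0, 2 * np.pi)
    return np.cos(phase)


def _blink_kernel(sfreq: float, duration_s: float) -> np.ndarray:
    """Biexponential blink: fast rise, slower decay, unit peak."""
    t = np.arange(int(round(duration_s * sfreq))) / sfreq
    tau_r, tau_d = duration_s / 8.0, duration_s / 3.0
    k = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    return k / (k.max() + 1e-30)


def generate_eeg_eog(session: SubjectSession, truth: GroundTruth,
                     config: CohortConfig) -> EEGRecording:
    """Synthesize the 8-channel recording for one session.

    EEG channels sum five band-limited carriers whose envelopes mix a
    session-shared component (weight = that band's coupling for the
    session's condition) with channel-private components, plus white noise.
    EOG channels carry baseline noise, injected in-phase blinks at the
    ground-truth artifact times and anti-phase half-sine deflections at the
    ground-truth SREM onsets (EOG-R = −0.9 × EOG-L).
    """
    config.validate()
    sfreq = config.sampling_rate_hz
    n = int(round(session.drive_duration_s * sfreq))
    coupling = config.band_coupling[session.condition]
    scalp = ("Fz", "Cz", "Pz", "Oz")
    rng = _rng(config, _TAG_SIGNAL, session.subject_index,
               session.order_index)

    data = np.zeros((8, n))
    # only bands listed in the condition's coupling map are synthesized
    for band, (f0, half_bw) in _BAND_CENTERS.items():
        if band not in coupling:
            continue
        w = coupling[band]
        shared = _slow_envelope(rng, n, sfreq, config.envelope_bandwidth_hz)
        amp = _BAND_AMPLITUDE_UV[band]
        for ci in range(len(scalp)):
            private = _slow_envelope(rng, n, sfreq,
                                     config.envelope_bandwidth_hz)
            env = w * shared + (1.0 - w) * private
            carrier = _fm_carrier(rng, n, sfreq, f0, half_bw)
            data[ci] += amp * env * carrier
    if config.eeg_noise_uv > 0:
        data[:4] += rng.normal(0, config.eeg_noise_uv, size=(4, n))

    # EOG pair: baseline noise + blinks (in-phase) + SREMs (anti-phase)
    eog_l = rng.normal(0, config.eog_noise_uv, size=n) if config.eog_noise_uv \
        else np.zeros(n)
    eog_r = rng.normal(0, config.eog_noise_uv, size=n) if config.eog_noise_uv \
        else np.zeros(n)
    blink = _blink_kernel(sfreq, config.blink_duration_s)
    for start, _end in truth.artifact_intervals.get(session.key, []):
        i0 = int(round(start * sfreq))
        i1 = min(i0 + blink.size, n)
        amp = config.blink_amplitude_uv * rng.uniform(0.8, 1.3)
        eog_l[i0:i1] += amp * blink[: i1 - i0]
        eog_r[i0:i1] += amp * blink[: i1 - i0]
    for onset, dur in truth.srem_events.get(session.key, []):
        i0 = int(round(onset * sfreq))
        i1 = min(i0 + int(round(dur * sfreq)), n)
        t = np.arange(i1 - i0) / sfreq
        amp = rng.uniform(*config.srem_amplitude_range_uv)
        # rolling movement: slow oscillation (0.4-0.9 Hz) under a half-sine
        # window; purely sub-0.4 Hz deflections would not survive the
        # 0.48 Hz acquisition high-pass that precedes scoring
        f_roll = rng.uniform(*config.srem_roll_freq_hz)
        deflection = (amp * np.sin(np.pi * t / dur)
                      * np.cos(2 * np.pi * f_roll * (t - dur / 2.0)))
        eog_l[i0:i1] += deflection
        eog_r[i0:i1] -= 0.9 * deflection
    data[4], data[5] = eog_l, eog_r

    # mastoids: low-amplitude noise (dropped after re-referencing)
    data[6] = rng.normal(0, 1.0, size=n)
    data[7] = rng.normal(0, 1.0, size=n)

    return EEGRecording(data, ["Fz", "Cz", "Pz", "Oz", "EOG-L", "EOG-R",
                               "A1", "A2"], sfreq)


# ---------------------------------------------------------------------------
# behavioral outcomes
# ---------------------------------------------------------------------------

def _shifted_lognormal(rng: np.random.Generator, n: int, mean: float,
                       sd: float, shift: float) -> np.ndarray:
    """Shifted lognormal with target mean/sd (of the whole variate)."""
    body_mean = max(mean - shift, 1.0)
    v = np.log1p((sd / body_mean) ** 2)
    m = np.log(body_mean) - v / 2.0
    return shift + rng.lognormal(m, np.sqrt(v), size=n)


def generate_behavioral(session: SubjectSession, truth: GroundTruth,
                        config: CohortConfig) -> BehavioralRecord:
    """PVT trials, KSS rating and sleep history for one session.

    Raw PVT reaction times are the adjusted-scale mixture (shifted-lognormal
    body, lapse tail > 500 ms with condition-specific probability) plus the
    system latency and a per-subject speed offset.  The KSS is a latent
    normal (subject effect + condition shift + noise) thresholded to 1–9.
    The 14-day sleep history is shared between a subject's two sessions.
    """
    config.validate()
    cond = session.condition
    rng_subj = _rng(config, _TAG_BEHAVIOR, session.subject_index)
    subject_rt = rng_subj.normal(0, config.pvt_subject_sd_ms)
    subject_kss = rng_subj.normal(0, config.kss_latent_subject_sd)
    sleep_h = truth.sleep_hours[session.subject]
    daily = np.clip(
        rng_subj.normal(sleep_h * 60.0, config.sleep_daily_sd_min, size=14),
        0.0, 1440.0)

    rng_sess = _rng(config, _TAG_BEHAVIOR, session.subject_index,
                    session.order_index + 1)
    n = config.n_pvt_trials
    body = _shifted_lognormal(rng_sess, n, config.pvt_mu_ms[cond],
                              config.pvt_sigma_ms[cond], config.pvt_shift_ms)
    is_lapse = rng_sess.uniform(size=n) < config.lapse_prob[cond]
    lapse_rts = 505.0 + rng_sess.exponential(120.0, size=n)
    adjusted = np.where(is_lapse, lapse_rts, body) + subject_rt
    raw = adjusted + config.pvt_system_latency_ms

    latent = (config.kss_latent_mean + subject_kss
              + (config.kss_shift if cond == "self-driving" else 0.0)
              + rng_sess.normal(0, config.kss_latent_noise_sd))
    kss = int(np.clip(round(latent), 1, 9))

    return BehavioralRecord(session.subject, cond, raw, kss, daily)


def reduced_config(**overrides) -> CohortConfig:
    """A small-scale cohort configuration for quick runs and CI."""
    params = {**REDUCED_PROFILE, **overrides}
    return replace(CohortConfig(), **params)
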