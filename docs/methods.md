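# Methods

This note documents the models, algorithms and design choices behind
`sleepdrive`, in the spirit of a model-description appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic validation does and does not establish.

## The measurement problem

A paired within-subject design compares two ~48-minute simulated drives per
participant — one manually controlled, one supervising a self-driving
vehicle — on four families of endpoints: slow rolling eye movements (SREMs)
in the EOG, band-specific neural synchrony in four midline EEG channels,
subjective sleepiness (KSS), and psychomotor vigilance (PVT). The package
implements the full chain from raw multichannel signal to the final
statistical battery, and, because the human recordings are not public, a
generator that produces signal and behavioral data with the statistical
structure that chain assumes.

## Preprocessing

Re-referencing subtracts the averaged mastoids (A1 + A2)/2 from every
scalp/EOG channel. The filter chain is a zero-phase band-pass: high-pass at
0.4823 Hz realized as a 2nd-order Butterworth (12 dB/octave; the equivalent
0.33 s time constant is redundant with the cutoff, 1/(2π·0.33) ≈ 0.482),
low-pass at 70 Hz as a 4th-order Butterworth (24 dB/octave), and a 60 Hz
notch (Q = 30). All stages run forward-backward (`sosfiltfilt`), so the
quoted slopes are the single-pass designs.

Ocular artifacts are flagged on the magnitude of the product of the two
EOG traces — large for blinks (in-phase) and eye movements (anti-phase)
alike. The threshold is mean + 3 SD of the magnitude, computed per session
("three standard deviations" is read as mean + 3·SD of the absolute
product, the only reading that yields a usable scalar); 2 s windows
centered on every super-threshold sample are excised, merged, and clipped
to the recording. The complement is cut into contiguous clean segments; a
2 s minimum segment keeps stretches long enough to support 1 Hz band
estimation. Retained + excluded time equals the recording duration to one
sample. On default synthetic cohorts the mean excluded fraction lands near
16%, the scale reported for real sessions.

## SREM detection

The detector automates the scoring definition (out-of-phase rolling
deflections ≥ 0.5 s in both EOG channels):

1. Band-pass both EOG channels to the slow band, 0.1–1.5 Hz.
2. Candidate samples: both |slow traces| above an amplitude threshold —
   3 × the MAD-based background SD estimate, floored at 5 µV — while the
   0.5 s sliding-window Pearson correlation between the channels is
   ≤ −0.5 (the anti-phase criterion; blinks are in-phase and fail it).
3. Candidate runs merged across gaps < 0.25 s (one rolling movement can
   dip through zero crossings).
4. Each candidate's duration is then re-measured on a wider 0.1–8 Hz
   band: the event spans the contiguous stretch around its peak where both
   channels' analytic envelopes stay above 35% of their event peak. This
   step exists for a physical reason: the slow band's own impulse-response
   envelope is ≈ 0.5 s wide, so duration measured there cannot distinguish
   a genuine 0.5 s slow movement from the filter's smearing of a brief
   saccadic spike. Events ≥ 0.5 s on the wide-band measurement are kept.

Amplitude defaults were calibrated on synthetic cohorts (no amplitude
criterion exists in the human scoring rule); at default SNR the detector
reaches recall and precision ≥ 0.9 against injected ground truth.
Detected counts are per-session; time-to-first-SREM records carry an event
flag and are censored at (possibly premature) drive end.

## Welch PSD and BDM synchrony

PSDs use Welch's averaged modified periodogram (4 s Hann windows, 50%
overlap) per clean segment, combined weighted by segment duration, then
channel-averaged; units µV²/Hz.

BDM synchrony, per band (δ 1–3, θ 4–7, α 8–12, β 13–25, γ 26–40 Hz):
band-pass (4th-order Butterworth, zero phase), power envelope =
|analytic signal|² via the Hilbert transform, first difference, signum
(ties to +1 — measure zero for continuous data), then the per-sample
agreement |Σ_c s_c| / C averaged over time. The "average sum" is
normalized this way so the statistic lies in [0, 1], reads as the
proportion of channels moving together, and has an analytic independence
baseline (E|Σ of 4 iid signs|/4 = 24/64 = 0.375). Squaring the envelope
does not affect the statistic (monotone transform preserves derivative
signs; verified as a test). Filtering never crosses artifact-excised gaps:
each segment is processed independently and a 1 s edge guard is dropped at
segment boundaries. Scaling any channel by a positive constant leaves the
result unchanged.

## Behavioral summaries

PVT: every raw RT is adjusted by the 82 ms system latency; the summary is
the mean adjusted RT and the lapse count, with the lapse inequality strict
(adjusted RT > 500 ms). Sleep history: device-classified 1-minute epochs
are summed inside the diary's main rest interval plus attributed naps, per
day, capped at 1440 min, averaged over the 14-day window (the proprietary
sleep-scoring algorithm is not re-implemented; epochs arrive
pre-classified). When the diary is missing, bedtime is the first epoch
with activity count < 150 scored "sleep", waketime the first subsequent
epoch with count > 150 scored "active". KSS ratings pass through as
integers 1–9.

## Statistical battery

* **SREM counts, PVT lapses** — counts are over-dispersed, so a
  negative-binomial regression on condition, with within-subject
  correlation handled by GEE (exchangeable working correlation, robust
  covariance). The NB2 dispersion α (Var = μ + αμ²) is fixed at a moment
  estimate from a preliminary Poisson fit. Reported: log rate ratio,
  robust Wald χ²(1), p. Under a frailty null at n = 50 the empirical size
  is ≈ 0.06.
* **SREM counts vs habitual sleep** — per-condition NB maximum-likelihood
  regression; slope log b per hour of sleep with 95% CI.
* **Time to first SREM** — log-rank test stratified by subject (each
  stratum contributes its observed-minus-expected and hypergeometric
  variance; χ²(1) on the sums). When every stratum is uninformative the
  test falls back, with a warning, to the unstratified statistic (which
  matches `lifelines` exactly, as tested).
* **KSS** — Wilcoxon signed-rank on paired ratings; V is the positive-rank
  sum; exact p for ≤ 25 untied pairs (verified against full enumeration),
  tie-corrected normal approximation otherwise; zero differences dropped.
* **PVT mean RT, synchrony** — linear mixed model with a per-subject
  random intercept, REML. The condition effect is tested against a t
  reference with n_subjects − 1 degrees of freedom rather than a Wald
  normal: on balanced complete data this makes the test *exactly* the
  paired t-test, which is the behavior a paired design should recover
  (a single random intercept makes "unstructured covariances" a scalar
  variance). Boundary/singular REML fits fall back to the paired t-test
  with a warning.
* **Effect sizes** — adjusted Hedge's g with the RMS-pooled SD
  (√((SD1²+SD2²)/2)) and the (N−3)/(N−2.25)·√((N−2)/N) small-sample
  correction; N is the number of paired participants in that comparison.
  Printed-value comparisons round half-up to 2 decimals.
* **Sample size** — n = ⌈(z₁₋α/₂ + z_power)²σ²/δ²⌉; the 50 ms / 65 ms /
  80% / 0.05 design gives 14.
* No multiple-testing correction is applied anywhere (matching the
  analysis this package reimplements); α = 0.05.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions, not tuning knobs.

* **Design**: n = 20 subjects, two 2880 s drives at 500 Hz, order
  randomized in counterbalanced blocks of four (20 subjects → exactly 10
  manual-first).
* **SREM counts**: negative-binomial via a per-subject gamma frailty
  (mean 1, variance α = 0.8) shared between a subject's two drives — this
  yields the configured NB2 marginals *and* the within-subject correlation
  the GEE expects. The manual-condition mean is 5.0; the self-driving log
  rate ratio is 1.0626 (5 → ≈ 14.5, the Study-1 scale). The habitual-sleep
  slope (−0.48 per hour, centered at 5.9 h) is expressed only in the
  self-driving condition by default: short sleepers unmask more SREMs when
  supervising but not when driving — the asymmetry the studies report.
  Event onsets are uniform over the drive (a "ramp" profile with hazard
  increasing in time is available but uncalibrated: per-condition SREM
  rate *over time* is not reported anywhere usable); durations are uniform
  on 0.6–4 s with ≥ 2 s separation.
* **SREM waveform**: an anti-phase (EOG-R = −0.9 × EOG-L), half-sine-
  windowed slow oscillation at 0.4–0.9 Hz, 40–80 µV. A plain half-sine was
  rejected deliberately: a smooth 3–4 s half-sine concentrates its energy
  below 0.2 Hz, which the 0.4823 Hz acquisition high-pass all but erases
  (|H| ≈ 0.005 after zero-phase application) — such an event could not
  survive the very preprocessing that precedes scoring, whereas "rolling"
  movements are oscillatory and do.
* **Blinks**: in-phase biexponential spikes, ~0.3 s, ~180 µV, Poisson at
  5/min (≈ 16% excision once the ±1 s windows are applied). Blinks are not
  placed inside or abutting SREM windows — eyelid closure suppresses
  blinking during rolling movements — which also keeps the two
  ground-truth event classes cleanly separable for oracle tests.
* **EEG**: each band is a unit-amplitude narrowband carrier (a tone with
  slow random frequency drift, ±30% of the band half-width) multiplied by
  a positive slow envelope (|low-pass-filtered Gaussian|, < 0.5 Hz,
  mean 1). The channel envelope is w·(shared) + (1−w)·(private), with w
  the band's coupling for that condition — exactly the structure BDM
  measures; synchrony is monotone in w (Spearman ρ ≈ 0.99 across w ∈
  [0, 1]). Default coupling: manual δ/θ/α/β/γ = .60/.50/.55/.45/.40,
  self-driving .45/.45/.45/.45/.40 — the δ > α > θ ordering of the
  reported condition effects, with β/γ null. Band amplitudes are
  1/f-shaped (20/10/15/6/3 µV) plus 2 µV white noise. Only bands present
  in the coupling map are synthesized (a delta-only map is a cheap
  single-band cohort).
* **Behavior**: adjusted-scale RTs are a shifted-lognormal body (150 ms
  shift; manual mean 300 ms, self-driving 320 ms) mixed with a lapse tail
  (505 ms + Exp(120); manual probability 0.015, self-driving 0.0375 —
  ≈ 0.7 vs ≈ 1.7 lapses per 45-trial, five-minute session), plus a 40 ms
  SD per-subject speed offset; raw RTs add the 82 ms latency. At large σ
  the lognormal body itself can exceed 500 ms, so configured lapse
  probabilities are exact only for tight bodies. KSS is a latent normal
  (baseline 5.35, subject SD 1.6, noise SD 1.2, self-driving shift +1.4)
  rounded and clipped to 1–9. Habitual sleep is N(5.9 h, 0.9 h) per
  subject, with 14 daily values at ±45 min.
* **Determinism**: every draw comes from a `SeedSequence(seed, stream,
  indices…)` substream, so cohorts, signals and behavior are bit-identical
  given (config, seed) and independent of call order.

What the generator does *not* emulate: realistic sleep-stage EEG
microstructure, eyelid/video dynamics, non-stationary artifact rates, EEG
leakage into EOG, or any driving-scene content. Passing tests therefore
demonstrate that the pipeline measures what it claims on data satisfying
its own assumptions — not that it would reach the same numbers on human
recordings.

## Problem sizes and numerical choices

Test and validation runs use reduced profiles — 8–20 subjects, 30–360 s
drives at 250 Hz — chosen because session length and sampling rate are
research-design parameters, not algorithmic ones; every algorithmic path
(filtering, masking, detection, synchrony, the full battery) is identical
at full scale. Calibration checks use 1000 replicates for test size
(NB-GEE ≈ 0.06, stratified log-rank ≈ 0.055 at nominal 0.05), 200–300 for
CI coverage (≈ 0.93–0.95), and 100 seeded cohorts for the effect-direction
recovery (100/100 on every endpoint). Null p-value uniformity is checked
on the continuous RT endpoint (Kolmogorov–Smirnov over 200 null cohorts);
discrete endpoints (KSS, counts) have intrinsically non-uniform p-values
at these sample sizes and are checked for size rather than uniformity.

Other conventions: signum(0) → +1; envelope derivative = first difference
at the sampling interval, no smoothing; Wilcoxon switches from exact to
normal approximation at n > 25 or in the presence of ties; EDF output
quantizes to 16 bits with per-channel symmetric physical ranges.

## Known limitations

* The artifact threshold is per-session; whether the original analysis
  pooled across sessions is unknowable from the text (flagged in config).
* The detector's amplitude criterion has no human-scoring analogue and is
  calibrated only on synthetic data.
* The stratified log-rank with two observations per stratum is
  conservative-to-slightly-liberal in small samples (empirical size 0.055
  at 50 subjects); the exact stratification used by the original software
  is not documented.
* The printed Study-1 PVT-lapse effect size (0.58) is not reproducible
  from its printed moments with any pooled-SD convention tried (the
  formula gives 0.64 with N = 9); that comparison is therefore excluded
  from the verification table rather than guessed at.
* Absolute synchrony levels are validated against the analytic baseline
  and coupling monotonicity only; no numeric axis values exist to compare
  against.
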