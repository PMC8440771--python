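"""Generator contracts: determinism, counterbalancing, moment recovery,
signal structure and ground-truth completeness."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import signal as scisig
from scipy import stats as sps

import sleepdrive as sd
from sleepdrive.synthdata import (CohortConfig, _BAND_CENTERS, _fm_carrier,
                                  _slow_envelope, generate_behavioral,
                                  generate_cohort, generate_eeg_eog,
                                  reduced_config)


def _null_config(**kw):
    return reduced_config(condition_effect_srem_log_rr=0.0,
                          sleep_slope_log_b=0.0, kss_shift=0.0,
                          pvt_mu_ms={"manual": 300.0, "self-driving": 300.0},
                          pvt_sigma_ms={"manual": 45.0, "self-driving": 45.0},
                          lapse_prob={"manual": 0.02, "self-driving": 0.02},
                          **kw)


class TestDesign:
    def test_counterbalanced_blocks_of_four(self):
        cfg = reduced_config(n_subjects=20, seed=3)
        cohort = generate_cohort(cfg)
        first = [s.condition for s in cohort.sessions if s.order_index == 0]
        assert len(first) == 20
        assert sum(c == "manual" for c in first) == 10
        # exact balance inside every block of four
        for b in range(5):
            block = first[4 * b: 4 * b + 4]
            assert sum(c == "manual" for c in block) == 2

    def test_each_subject_has_both_conditions(self, reduced_cohort):
        _cfg, cohort = reduced_cohort
        for subj in cohort.subjects:
            conds = {s.condition for s in cohort.sessions
                     if s.subject == subj}
            assert conds == {"manual", "self-driving"}

    @pytest.mark.parametrize("field,value", [
        ("n_subjects", 0), ("drive_duration_s", -1.0),
        ("sampling_rate_hz", 0.0), ("nb_dispersion", -0.5),
        ("artifact_rate_per_min", -2.0),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = replace(CohortConfig(), **{field: value})
        with pytest.raises(ValueError, match=field.split("_")[0]):
            cfg.validate()

    def test_coupling_outside_unit_interval_rejected(self):
        bad = {"manual": {"delta": 1.2}, "self-driving": {"delta": 0.5}}
        with pytest.raises(ValueError, match="delta"):
            replace(CohortConfig(), band_coupling=bad).validate()


class TestDeterminism:
    def test_identical_seed_bitwise_identical(self):
        cfg = reduced_config(seed=9, n_subjects=2, drive_duration_s=30.0)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        assert a.truth.srem_events == b.truth.srem_events
        ra = generate_eeg_eog(a.sessions[0], a.truth, cfg)
        rb = generate_eeg_eog(b.sessions[0], b.truth, cfg)
        assert np.array_equal(ra.data, rb.data)
        ba = generate_behavioral(a.sessions[0], a.truth, cfg)
        bb = generate_behavioral(b.sessions[0], b.truth, cfg)
        assert np.array_equal(ba.pvt_raw_rts_ms, bb.pvt_raw_rts_ms)
        assert ba.kss == bb.kss

    def test_different_seed_differs(self):
        c1 = reduced_config(seed=9, n_subjects=2, drive_duration_s=30.0)
        c2 = replace(c1, seed=10)
        a, b = generate_cohort(c1), generate_cohort(c2)
        ra = generate_eeg_eog(a.sessions[0], a.truth, c1)
        rb = generate_eeg_eog(b.sessions[0], b.truth, c2)
        assert not np.array_equal(ra.data, rb.data)


class TestCountModel:
    def test_null_effect_counts_equidistributed(self):
        cfg = _null_config(n_subjects=300, seed=17)
        cohort = generate_cohort(cfg)
        man = np.array([cohort.truth.srem_counts[(s, "manual")]
                        for s in cohort.subjects])
        sdr = np.array([cohort.truth.srem_counts[(s, "self-driving")]
                        for s in cohort.subjects])
        # same marginal rate: paired mean difference compatible with zero
        t = sps.ttest_rel(man, sdr)
        assert t.pvalue > 0.01

    def test_overdispersion_and_moment_recovery(self):
        # variance of NB counts must match m + alpha m^2 within 5% at large n
        cfg = CohortConfig(n_subjects=5000, sleep_slope_log_b=0.0, seed=5)
        cohort = generate_cohort(cfg)
        for cond in ("manual", "self-driving"):
            c = np.array([cohort.truth.srem_counts[(s, cond)]
                          for s in cohort.subjects])
            mu = cfg.manual_srem_mean
            if cond == "self-driving":
                mu *= np.exp(cfg.condition_effect_srem_log_rr)
            var = mu + cfg.nb_dispersion * mu ** 2
            assert c.var(ddof=1) > c.mean()          # over-dispersed
            assert abs(c.mean() - mu) / mu < 0.05
            assert abs(c.var(ddof=1) - var) / var < 0.05

    def test_ground_truth_completeness_and_bounds(self, reduced_cohort):
        cfg, cohort = reduced_cohort
        for key, events in cohort.truth.srem_events.items():
            assert cohort.truth.srem_counts[key] == len(events)
            for onset, dur in events:
                assert dur >= 0.5
                assert 0 <= onset <= onset + dur <= cfg.drive_duration_s
        for key, ivs in cohort.truth.artifact_intervals.items():
            for lo, hi in ivs:
                assert 0 <= lo < hi <= cfg.drive_duration_s


class TestSignals:
    @pytest.mark.parametrize("weight,corr_bound", [(1.0, 0.95), (0.0, 0.5)])
    def test_shared_envelope_weight_controls_envelope_identity(self, weight,
                                                               corr_bound):
        # full coupling -> the four channels carry one common band envelope
        # (near-perfect correlation); zero coupling -> envelopes unrelated
        bc = {c: {b: weight for b in _BAND_CENTERS} for c in
              ("manual", "self-driving")}
        cfg = reduced_config(n_subjects=1, drive_duration_s=30.0,
                             band_coupling=bc, eeg_noise_uv=0.0,
                             manual_srem_mean=0.0, artifact_rate_per_min=0.0,
                             seed=2)
        cohort = generate_cohort(cfg)
        rec = generate_eeg_eog(cohort.sessions[0], cohort.truth, cfg)
        sf = rec.sfreq
        sos = scisig.butter(4, [1, 3], "bandpass", fs=sf, output="sos")
        lp = scisig.butter(2, 1.0, "lowpass", fs=sf, output="sos")
        envs = []
        for ch in ("Fz", "Cz", "Pz", "Oz"):
            x = scisig.sosfiltfilt(sos, rec.get(ch))
            env = scisig.sosfiltfilt(lp, np.abs(scisig.hilbert(x)))
            envs.append(env[int(2 * sf):-int(2 * sf)])  # trim filter edges
        cc = np.corrcoef(np.array(envs))[np.triu_indices(4, 1)]
        if weight == 1.0:
            assert cc.min() > corr_bound
        else:
            assert cc.max() < corr_bound

    def test_srem_injection_antiphase_at_ground_truth_onsets(self):
        cfg = reduced_config(n_subjects=1, seed=4, artifact_rate_per_min=0.0,
                             eog_noise_uv=0.5)
        cohort = generate_cohort(cfg)
        ses = next(s for s in cohort.sessions
                   if cohort.truth.srem_counts[s.key] >= 3)
        rec = generate_eeg_eog(ses, cohort.truth, cfg)
        sf = rec.sfreq
        for onset, dur in cohort.truth.srem_events[ses.key]:
            i0, i1 = int(onset * sf), int((onset + dur) * sf)
            l, r = rec.get("EOG-L")[i0:i1], rec.get("EOG-R")[i0:i1]
            assert dur >= 0.5
            assert np.abs(l).max() > 10.0          # well above background
            assert np.corrcoef(l, r)[0, 1] < -0.9  # anti-phase

    @pytest.mark.parametrize("band", list(_BAND_CENTERS))
    def test_band_carrier_power_concentrated_in_band(self, band):
        f0, half_bw = _BAND_CENTERS[band]
        rng = np.random.default_rng(6)
        sf, n = 250.0, 250 * 120
        x = _slow_envelope(rng, n, sf, 0.5) * _fm_carrier(rng, n, sf, f0,
                                                          half_bw)
        freqs, pxx = scisig.welch(x, fs=sf, nperseg=4096)
        lo, hi = {"delta": (1, 3), "theta": (4, 7), "alpha": (8, 12),
                  "beta": (13, 25), "gamma": (26, 40)}[band]
        inside = pxx[(freqs >= lo) & (freqs <= hi)].sum()
        assert inside / pxx.sum() >= 0.90


class TestBehavioral:
    def test_zero_lapse_probability_yields_zero_lapses(self):
        cfg = reduced_config(n_subjects=1, n_pvt_trials=10_000,
                             lapse_prob={"manual": 0.0, "self-driving": 0.0},
                             pvt_sigma_ms={"manual": 20.0,
                                           "self-driving": 20.0},
                             pvt_subject_sd_ms=0.0, seed=8)
        cohort = generate_cohort(cfg)
        beh = generate_behavioral(cohort.sessions[0], cohort.truth, cfg)
        pvt = sd.summarize_pvt(beh.pvt_raw_rts_ms)
        assert pvt.lapses == 0
        assert pvt.n_trials == 10_000

    def test_rt_mean_targets_configured_moment(self):
        cfg = reduced_config(n_subjects=1, n_pvt_trials=10_000,
                             pvt_mu_ms={"manual": 300.0,
                                        "self-driving": 300.0},
                             pvt_sigma_ms={"manual": 65.0,
                                           "self-driving": 65.0},
                             lapse_prob={"manual": 0.0, "self-driving": 0.0},
                             pvt_subject_sd_ms=0.0, seed=8)
        cohort = generate_cohort(cfg)
        beh = generate_behavioral(cohort.sessions[0], cohort.truth, cfg)
        pvt = sd.summarize_pvt(beh.pvt_raw_rts_ms)
        assert abs(pvt.mean_rt_ms - 300.0) < 2.0

    def test_lapse_fraction_matches_binomial_rate(self):
        cfg = reduced_config(n_subjects=1, n_pvt_trials=10_000,
                             lapse_prob={"manual": 0.05,
                                         "self-driving": 0.05},
                             pvt_sigma_ms={"manual": 25.0,
                                           "self-driving": 25.0},
                             pvt_subject_sd_ms=0.0, seed=8)
        cohort = generate_cohort(cfg)
        beh = generate_behavioral(cohort.sessions[0], cohort.truth, cfg)
        pvt = sd.summarize_pvt(beh.pvt_raw_rts_ms)
        assert abs(pvt.lapses / pvt.n_trials - 0.05) < 0.01

    def test_null_effect_kss_differences_centered(self):
        cfg = _null_config(n_subjects=200, seed=21)
        cohort = generate_cohort(cfg)
        diffs = []
        for subj in cohort.subjects:
            k = {}
            for ses in cohort.sessions:
                if ses.subject == subj:
                    k[ses.condition] = generate_behavioral(
                        ses, cohort.truth, cfg).kss
            diffs.append(k["self-driving"] - k["manual"])
        assert abs(np.mean(diffs)) < 0.3
        assert sps.wilcoxon(np.array(diffs)[np.array(diffs) != 0]).pvalue > 0.01

    def test_kss_in_ordinal_range_and_sleep_history_shape(self,
                                                          reduced_cohort):
        cfg, cohort = reduced_cohort
        for ses in cohort.sessions[:4]:
            beh = generate_behavioral(ses, cohort.truth, cfg)
            assert 1 <= beh.kss <= 9
            assert beh.sleep_daily_minutes.shape == (14,)
            assert np.all((beh.sleep_daily_minutes >= 0)
                          & (beh.sleep_daily_minutes <= 1440))
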