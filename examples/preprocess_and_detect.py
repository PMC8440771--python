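"""Preprocess one session and detect slow rolling eye movements.

The chain: re-reference to averaged mastoids, band-pass 0.48-70 Hz with a
60 Hz notch (zero phase), mask ocular artifacts from the |EOG-L x EOG-R|
product, then run the rule-based SREM detector (both slow-filtered EOG
channels above threshold, strongly anti-phase, for at least 0.5 s).
"""

from sleepdrive import (detect_srems, generate_cohort, generate_eeg_eog,
                        preprocess_session, time_to_first_srem)
from sleepdrive.synthdata import reduced_config

config = reduced_config(n_subjects=2, seed=11)
cohort = generate_cohort(config)
# the self-driving drive with the most injected SREMs
session = max((s for s in cohort.sessions
               if s.condition == "self-driving"),
              key=lambda s: cohort.truth.srem_counts[s.key])

recording = generate_eeg_eog(session, cohort.truth, config)
filtered, mask, segments = preprocess_session(recording)

print(f"session: {session.subject} / {session.condition}, "
      f"{recording.duration_s:.0f} s at {recording.sfreq:.0f} Hz")
print(f"ocular artifacts excised: {100 * mask.excluded_fraction:.1f}% of "
      f"the recording ({len(mask.intervals)} intervals)")
print(f"clean EEG segments: {len(segments)} "
      f"({segments.total_retained_s:.0f} s retained)\n")

events = detect_srems(filtered.get("EOG-L"), filtered.get("EOG-R"),
                      filtered.sfreq)
truth = cohort.truth.srem_events[session.key]
print(f"SREMs detected: {len(events)} (ground truth: {len(truth)})")
for e in events[:5]:
    print(f"  onset {e.onset_s:7.1f} s, duration {e.duration_s:.2f} s, "
          f"anti-phase score {e.antiphase_score:.2f}")

record = time_to_first_srem(events, session.drive_duration_s,
                            session.subject, session.condition)
state = "observed" if record.event else "censored at drive end"
print(f"\ntime to first SREM: {record.time_s:.1f} s ({state})")
print("Earlier first SREMs and higher counts mark the transition toward "
      "sleep while supervising the automation.")
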