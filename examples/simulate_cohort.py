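"""Generate a small synthetic cohort and inspect its ground truth.

Each subject completes one manually controlled and one self-driving drive
in counterbalanced order.  SREM (slow rolling eye movement) counts are
negative-binomial with a higher rate in the self-driving condition and,
for short sleepers, a further rate increase expressed only while
supervising the automation.
"""

import numpy as np

from sleepdrive import generate_cohort
from sleepdrive.synthdata import reduced_config

config = reduced_config(n_subjects=8, seed=42)
cohort = generate_cohort(config)

print(f"{config.n_subjects} subjects, {len(cohort.sessions)} sessions "
      f"({config.drive_duration_s:.0f} s each at "
      f"{config.sampling_rate_hz:.0f} Hz)\n")

print(f"{'subject':8s} {'sleep(h)':>8s} {'manual':>7s} {'self-driving':>13s}")
for subj in cohort.subjects:
    print(f"{subj:8s} {cohort.truth.sleep_hours[subj]:8.1f} "
          f"{cohort.truth.srem_counts[(subj, 'manual')]:7d} "
          f"{cohort.truth.srem_counts[(subj, 'self-driving')]:13d}")

manual = [cohort.truth.srem_counts[(s, "manual")] for s in cohort.subjects]
selfd = [cohort.truth.srem_counts[(s, "self-driving")]
         for s in cohort.subjects]
print(f"\nmean SREM count: manual {np.mean(manual):.1f}, "
      f"self-driving {np.mean(selfd):.1f}")
print("The self-driving condition unmasks sleepiness: same subjects, "
      "same day, several-fold more rolling eye movements.")
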