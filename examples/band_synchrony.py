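"""Band-specific neural synchrony via the binarized derivative method.

BDM reduces each channel's band-limited power envelope to the sign of its
first derivative and averages, over time, |sum of signs| / n_channels.
Identical envelopes give 1.0; four independent channels converge to the
counting baseline E|sum of 4 random signs|/4 = 0.375.
"""

import numpy as np

from sleepdrive import generate_cohort, generate_eeg_eog, synchrony_profile
from sleepdrive.recording import ContiguousSegments, Segment
from sleepdrive.spectral import BandDefinition, bdm_synchrony
from sleepdrive.synthdata import reduced_config

# 1. analytic baseline: independent channels
rng = np.random.default_rng(0)
noise = rng.standard_normal((4, 200_000))
segs = ContiguousSegments([Segment(0.0, noise)], list("abcd"), 250.0)
value = bdm_synchrony(segs, BandDefinition("beta", 13, 25))
print(f"independent channels: synchrony = {value:.3f} "
      "(counting baseline 0.375)")

# 2. a generated session: delta/alpha couple less when self-driving
config = reduced_config(n_subjects=1, drive_duration_s=120.0, seed=3,
                        artifact_rate_per_min=0.0, manual_srem_mean=0.0)
cohort = generate_cohort(config)
print(f"\n{'band':7s} {'manual':>8s} {'self-driving':>13s}")
profiles = {}
for session in cohort.sessions:
    rec = generate_eeg_eog(session, cohort.truth, config)
    scalp = rec.pick(["Fz", "Cz", "Pz", "Oz"])
    segs = ContiguousSegments([Segment(0.0, scalp.data)], scalp.channels,
                              rec.sfreq)
    profiles[session.condition] = synchrony_profile(segs)
for band in ("delta", "theta", "alpha", "beta", "gamma"):
    print(f"{band:7s} {profiles['manual'][band]:8.3f} "
          f"{profiles['self-driving'][band]:13.3f}")
print("\nLower delta/alpha synchrony while supervising the automation "
      "mirrors the reduced cross-channel envelope coupling.")
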