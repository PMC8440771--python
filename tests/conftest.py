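"""Shared fixtures: a small processed synthetic cohort reused across tests.

The "reduced" cohort (8 subjects, 6-minute drives at 250 Hz) is processed
once per test session — re-referenced, filtered, artifact-masked, SREMs
detected — and the per-session results are shared by the detector-fidelity,
mask-coverage and pipeline tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

import sleepdrive as sd
from sleepdrive.synthdata import reduced_config


def pytest_configure(config):
    # statsmodels emits convergence chatter on tiny fits; keep test output
    # readable without hiding our own warnings-as-errors checks
    warnings.filterwarnings("ignore", module="statsmodels")


@dataclass
class ProcessedSession:
    session: object
    mask: object
    segments: object
    events: list
    filtered: object


@pytest.fixture(scope="session")
def reduced_cohort():
    cfg = reduced_config(seed=1)
    return cfg, sd.generate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_cohort(reduced_cohort):
    """Every session of the reduced cohort run through the signal chain."""
    cfg, cohort = reduced_cohort
    out: dict[tuple[str, str], ProcessedSession] = {}
    for session in cohort.sessions:
        rec = sd.generate_eeg_eog(session, cohort.truth, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            filtered, mask, segments = sd.preprocess_session(rec)
        events = sd.detect_srems(filtered.get("EOG-L"),
                                 filtered.get("EOG-R"), filtered.sfreq)
        out[session.key] = ProcessedSession(session, mask, segments,
                                            events, filtered)
    return cfg, cohort, out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
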