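"""Shared fixtures.

The expensive fixture is ``cohort_studies``: twenty independently seeded
48-subject cohorts run end-to-end (simulate -> preprocess -> features ->
cross-validated speller AUC) at a reduced problem size (128 Hz, one test
word, four repetitions, 5 folds). Single-trial AUC levels and cross-subject
correlation structure are insensitive to these reductions; they only shorten
the simulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import rsvpbci as rb
from rsvpbci.features import FEATURE_NAMES

FAST_PARADIGM = rb.ParadigmConfig(sampling_rate=128.0, response_window=0.5,
                                  repetitions=4, test_words=("NEURONS",))

COHORT_SEEDS = [1000 + i for i in range(20)]


@pytest.fixture(scope="session")
def fast_paradigm() -> rb.ParadigmConfig:
    return FAST_PARADIGM


@pytest.fixture(scope="session")
def quiet_profile() -> rb.SubjectProfile:
    """Low-noise subject with known latent parameters."""
    return rb.SubjectProfile(subject_id="sq", amp_mean=2.88, amp_sd=1.0,
                             lat_mean=455.8, lat_sd=60.0, t1_prob=0.9,
                             noise_sd=0.8)


@pytest.fixture(scope="session")
def rsvp_run(quiet_profile, fast_paradigm):
    """One simulated RSVP session with its behavior log (session-scoped)."""
    return rb.generate_rsvp_session(quiet_profile, fast_paradigm, seed=42)


@pytest.fixture(scope="session")
def rsvp_epochs(rsvp_run):
    session, _ = rsvp_run
    return rb.preprocess_session(session)


def make_epochset(data: np.ndarray, labels, rate: float = 128.0,
                  channel_names=None) -> rb.EpochSet:
    """Assemble a minimal EpochSet around a raw (epochs, ch, samples) array."""
    n = data.shape[0]
    labels = np.asarray(labels, dtype=object).astype(str)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(data.shape[1]))
    info = pd.DataFrame({
        "sample": np.arange(n) * data.shape[2],
        "label": labels,
        "trial_id": np.arange(n),
        "flash_id": np.zeros(n, dtype=int),
        "character": ["A"] * n,
    })
    return rb.EpochSet(data=np.asarray(data, dtype=float), labels=labels,
                       rate=rate, channel_names=tuple(channel_names),
                       info=info, reject_mask=np.zeros(n, dtype=bool),
                       reject_reason=np.array([""] * n, dtype=object))


def _run_cohort(seed: int) -> dict:
    cfg = rb.RunConfig(seed=seed, n_subjects=48, paradigm=FAST_PARADIGM,
                       folds=5)
    res = rb.run_full_study(cfg)
    return {
        "seed": seed,
        "features": res.features[list(FEATURE_NAMES)],
        "auc": res.auc,
        "trial_tables": res.trial_tables,
        "logs": res.logs,
        "profiles": res.profiles,
    }


@pytest.fixture(scope="session")
def cohort_studies() -> list[dict]:
    """Twenty reduced-scale 48-subject study runs with distinct seeds."""
    return [_run_cohort(seed) for seed in COHORT_SEEDS]
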