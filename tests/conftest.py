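import numpy as np
import pandas as pd
import pytest

from sleepvoice.assembly import assemble
from sleepvoice.syncohort import (CohortConfig, VrtLink, fig1_preset,
                                  generate_cohort, onsets_from_truth)


@pytest.fixture(scope="session")
def fig1_tables():
    """Cohort with the exact flow composition: 2,230 attempts,
    136 non-speech / 295 invalid / 286 missing sleepiness."""
    return generate_cohort(fig1_preset(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_participants=8, attempts_per_session=6, seed=7)
    return cfg, generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_observations(n_participants=16, attempts_per_session=8, seed=0,
                      slope=0.10, noise_sd=0.72, nonspeech=0.0,
                      invalid=0.0, missing=0.0) -> pd.DataFrame:
    """Analysis-ready observation table built from generator truth
    (no audio involved)."""
    cfg = CohortConfig(n_participants=n_participants,
                       attempts_per_session=attempts_per_session,
                       nonspeech_rate=nonspeech, invalid_strategy_rate=invalid,
                       missing_sleepiness_rate=missing,
                       vrt_link=VrtLink(slope_per_level=slope,
                                        noise_sd=noise_sd),
                       seed=seed)
    participants, ema, sessions = generate_cohort(cfg)
    obs, _ = assemble(onsets_from_truth(sessions), ema, sessions, participants)
    return obs
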