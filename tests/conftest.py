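"""Shared fixtures: seeded generators and small synthetic nights."""

from __future__ import annotations

import numpy as np
import pytest

import cardiosleep as cs
from cardiosleep.features import CONTEXT_FEATURES

#: Feature subset sufficient for the default recognizers + fusion.
STAGING_FEATURES = (
    "HR", "LF", "coRR", "resf", "alpha1", "alpha2", "SE", "P1", "G1", "corr2",
) + CONTEXT_FEATURES


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_night(hours: float, seed: int, features=STAGING_FEATURES):
    """Simulate one night and extract its feature table."""
    cfg = cs.NightConfig(night_hours=hours, seed=seed)
    hyp = cs.simulate_hypnogram(cfg)
    rr = cs.clean_rr(cs.simulate_rr(hyp, cfg, seed=seed + 10_000))
    windows = cs.build_windows(rr, hyp, training=False)
    table = cs.extract_night(rr, windows, hyp=hyp, features=features,
                             record_id=f"night{seed}")
    return table, hyp, rr


@pytest.fixture(scope="session")
def small_nights():
    """Six 3-hour synthetic nights with features, for staging unit tests."""
    return [make_night(3.0, seed)[:2] for seed in range(6)]


@pytest.fixture(scope="session")
def fitted_stager(small_nights):
    model = cs.SleepStagingModel(
        small_nights, context_names=CONTEXT_FEATURES, random_state=0
    )
    return model.fit()
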