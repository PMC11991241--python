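"""Shared fixtures: small synthetic cohorts and their feature tables.

Everything is generated at test time; cohort sizes are kept small so
the default suite runs quickly, while effect sizes stay at the
generator defaults.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from engageeg.preprocess import bandpass_filter, epoch
from engageeg.simulate import SimulationConfig, simulate_cohort
from engageeg.spectral import build_feature_table


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(n_subjects=4, n_older=1, trial_seconds=20.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_cohort(small_cfg, label_source="forced")


def cohort_epochs(cohort, apply_filter: bool = True):
    """Labeled EpochArrays from every session of a simulated cohort."""
    out = []
    for s in cohort.subjects:
        for sess, rec in s.recordings.items():
            if apply_filter:
                rec = bandpass_filter(rec)
            ep = epoch(rec)
            out.append(dataclasses.replace(ep, label=s.labels[sess]))
    return out


@pytest.fixture(scope="session")
def small_features(small_cohort):
    table, meta = build_feature_table(cohort_epochs(small_cohort))
    return table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
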