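"""Shared fixtures: synthetic cohorts and cached latent estimates.

Everything is generated programmatically at session scope so the expensive
pieces (choice-conditioned latent estimation, mixed-model batteries) run
once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

from bmbu.latents import estimate_latents
from bmbu.synth import CohortSpec, make_cohort


@pytest.fixture(scope="session")
def behavior_cohort():
    """Eight boundary-updating observers for behavioral statistics."""
    return make_cohort(CohortSpec(n_subjects=8, seed=11))


@pytest.fixture(scope="session")
def neuro_cohort():
    """Six observers used by the decoding/battery pipeline tests."""
    return make_cohort(CohortSpec(n_subjects=6, seed=21))


@pytest.fixture(scope="session")
def neuro_latents(neuro_cohort):
    """Choice-conditioned latent estimates under the generating parameters."""
    return [
        estimate_latents(r.table, r.params, n_sim=20_000, seed=r.subject)
        for r in neuro_cohort
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
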