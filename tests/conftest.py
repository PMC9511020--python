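"""Shared fixtures.

The expensive end-to-end recovery runs (three seeded cohorts at the
generator defaults, each with a classification and a regression fit)
are computed once per session and shared by the recovery, attribution
and architecture-comparison tests.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from fcage.pipeline import attribution_analysis, run_end_to_end
from fcage.simulate import GeneratorConfig, generate_cohort

logging.getLogger("fcage").setLevel(logging.ERROR)

RECOVERY_SEEDS = (1, 2, 3)
RECOVERY_EPOCHS = 20


@pytest.fixture(scope="session")
def small_cohort():
    """A fast 80-subject, 16-region cohort for unit-level training tests."""
    return generate_cohort(GeneratorConfig(n_subjects=80, p=16, T=150, seed=7))


@pytest.fixture(scope="session")
def recovery_runs():
    """Defaults-scale (n=600, p=32, T=200) recovery runs for three seeds."""
    runs = []
    for seed in RECOVERY_SEEDS:
        cohort = generate_cohort(GeneratorConfig(n_subjects=600, seed=seed))
        res = run_end_to_end(cohort, seed=seed, epochs=RECOVERY_EPOCHS)
        runs.append({"seed": seed, "cohort": cohort, "result": res})
    return runs


@pytest.fixture(scope="session")
def recovery_attributions(recovery_runs):
    """Planted-edge attribution analyses of the recovery classification models."""
    out = []
    for run in recovery_runs:
        out.append(
            attribution_analysis(
                run["cohort"], run["result"]["classification"]["model"], run["result"]["scaler"]
            )
        )
    return out


@pytest.fixture(scope="session")
def toy_trained_model(small_cohort):
    """A briefly trained small classifier for attribution tests."""
    res = run_end_to_end(small_cohort, seed=7, epochs=8, tasks=("classification",))
    return res


@pytest.fixture
def rng():
    return np.random.default_rng(0)
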