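"""Shared fixtures.

The expensive shared resources — the default-design synthetic cohort,
the repeated-cohort power tables, and the cached alpha-power profile
along the fitting ray — are session-scoped so every test that needs
them pays for them once.
"""

from __future__ import annotations

import pytest

import gripalpha as ga

#: master seeds of the repeated synthetic cohorts used for study-level
#: calibration properties (ANOVA significance, fitted-index monotonicity)
STUDY_MASTER_SEEDS = tuple(range(10))


@pytest.fixture(scope="session")
def typical() -> ga.ModelParameters:
    return ga.ModelParameters.typical_alpha()


@pytest.fixture(scope="session")
def default_study() -> ga.SyntheticStudy:
    """One full default-design cohort (11 x 3 x 10) with ground truth."""
    return ga.generate_study(
        ga.GeneratorSpec(master_seed=0), compute_expected=False
    )


@pytest.fixture(scope="session")
def study_tables(default_study):
    """(ground_truth, power_table) per master seed, default design.

    Master seed 0 reuses the ``default_study`` fixture; recordings of the
    other cohorts are discarded after summarization to bound memory.
    """
    out = []
    for ms in STUDY_MASTER_SEEDS:
        if ms == 0:
            study = default_study
        else:
            study = ga.generate_study(
                ga.GeneratorSpec(master_seed=ms), compute_expected=False
            )
        table = ga.summarize_powers(study.recordings)
        out.append((study.ground_truth, table))
        del study
    return out


@pytest.fixture(scope="session")
def ray_evaluator() -> ga.RayPowerEvaluator:
    """Common-random-number alpha-power profile used by every fit test."""
    return ga.RayPowerEvaluator(
        config=ga.SimulationConfig(duration=30.0, burn_in=2.0),
        seeds=range(10),
    )
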