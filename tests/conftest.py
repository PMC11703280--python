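"""Shared fixtures: small cohorts for module tests, the full-size fixture
cohort and a null cohort for the acceptance suite.

Everything is generated programmatically with fixed seeds; nothing is
stored on disk except what individual tests write to tmp dirs.
"""

import dataclasses

import numpy as np
import pytest

from wgsburden import DEFAULT_FIXTURE_CONFIG, SignalWindow, simulate_cohort


SMALL_CONFIG = dataclasses.replace(
    DEFAULT_FIXTURE_CONFIG,
    n_cases_bd=60,
    n_cases_sz=110,
    n_controls_internal=130,
    n_controls_external=170,
    n_chromosomes=1,
    genome_length_bp=300_000,
    n_variants=4_000,
    artifact_rate_by_category={"SINE": 0.01},
    signal_windows=(SignalWindow("chr1", 100_000, 110_000, -0.05),),
    signal_geneset=(tuple(f"GENE{i:04d}" for i in range(1, 11)), 1.5),
    seed=11,
)

NULL_CONFIG = dataclasses.replace(
    DEFAULT_FIXTURE_CONFIG,
    artifact_rate_by_category={},
    signal_windows=(),
    signal_geneset=None,
    n_variants=25_000,
    seed=777,
)


@pytest.fixture(scope="session")
def small_cohort():
    """~470 samples x 4,000 variants with a strong protective window and
    a SINE calling artifact; the workhorse for module-level tests."""
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_annotation(small_cohort):
    return small_cohort.annotate()


@pytest.fixture(scope="session")
def full_cohort():
    """The canonical fixture conditions (~4,000 samples x 40,000
    variants); used by the acceptance suite."""
    return simulate_cohort(DEFAULT_FIXTURE_CONFIG)


@pytest.fixture(scope="session")
def full_annotation(full_cohort):
    return full_cohort.annotate()


@pytest.fixture(scope="session")
def null_cohort():
    """Same shape as the fixture cohort but with no artifact and no
    implanted signal: the substrate for calibration checks."""
    return simulate_cohort(NULL_CONFIG)


@pytest.fixture(scope="session")
def null_annotation(null_cohort):
    return null_cohort.annotate()


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_115)
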