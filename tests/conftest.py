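import numpy as np
import pytest

from lipidbench.quantitation import fit_calibration, profile_from_peaks
from lipidbench.registry import get_cluster
from lipidbench.synthetic import (
    TABLE_FEMALE_MEAN_SD,
    TABLE_MALE_MEAN_SD,
    SyntheticCohortSpec,
    generate,
)

#: Printed per-sex mean composition columns (percent), as published.
FEMALE_MEANS = {code: m for code, (m, _) in TABLE_FEMALE_MEAN_SD.items()}
MALE_MEANS = {code: m for code, (m, _) in TABLE_MALE_MEAN_SD.items()}


@pytest.fixture(scope="session")
def registry():
    return get_cluster()


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticCohortSpec()


@pytest.fixture(scope="session")
def cohort(default_spec):
    """One default synthetic cohort with raw tables (seed fixed)."""
    return generate(default_spec, seed=7)


@pytest.fixture(scope="session")
def noise_free_cohort(default_spec):
    return generate(default_spec.noise_free(), seed=11)


@pytest.fixture(scope="session")
def quantified(noise_free_cohort):
    """Noise-free cohort pushed back through the quantitation stage."""
    tables = noise_free_cohort.tables
    curves = {code: fit_calibration(pts) for code, pts in tables.standards.items()}
    return [profile_from_peaks(t, curves) for t in tables.peak_tables]


def random_percent_profile(rng: np.random.Generator) -> dict[str, float]:
    """A random closed 10-part composition (strictly positive)."""
    codes = [fa.code for fa in get_cluster()]
    raw = rng.uniform(0.05, 40.0, size=len(codes))
    raw = 100.0 * raw / raw.sum()
    return dict(zip(codes, raw))
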