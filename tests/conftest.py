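import numpy as np
import pytest

from genoerr import CohortCounts, ErrorRates, GenotypeMatrix


@pytest.fixture
def two_site_counts() -> CohortCounts:
    """The recurring small worked example: m=2, N+=N-=100."""
    return CohortCounts(n_cases=100, n_controls=100,
                        case_counts=[4, 2], control_counts=[1, 1])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140401)


def make_matrix(case_dosages, control_dosages) -> GenotypeMatrix:
    """Genotype matrix from per-group dosage row-lists (cases first)."""
    case = np.atleast_2d(np.asarray(case_dosages, dtype=np.int8))
    ctrl = np.atleast_2d(np.asarray(control_dosages, dtype=np.int8))
    dosages = np.vstack([case, ctrl])
    phenotype = np.concatenate([np.ones(case.shape[0], dtype=np.int8),
                                np.zeros(ctrl.shape[0], dtype=np.int8)])
    return GenotypeMatrix(dosages=dosages, phenotype=phenotype)


@pytest.fixture
def no_errors() -> ErrorRates:
    return ErrorRates.none(8)
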