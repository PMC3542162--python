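import warnings

import numpy as np
import pandas as pd
import pytest

from remr import (
    CohortConfig,
    DEFAULT_TERMS,
    LongitudinalDataset,
    ModelSpec,
    generate_cohort,
)

RACE_COEFS = ["race[NHB]", "race[Hispanic]", "race[Other]"]


@pytest.fixture(scope="session")
def gaussian_cohort_200():
    """Default-configuration continuous-outcome cohort, 200 subjects."""
    data, truth = generate_cohort(CohortConfig(n_subjects=200, seed=1))
    return data, truth


@pytest.fixture(scope="session")
def gaussian_spec():
    return ModelSpec(
        family="gaussian", fixed_terms=list(DEFAULT_TERMS), estimation="REML"
    )


@pytest.fixture(scope="session")
def binary_tiny():
    """Small binary-outcome dataset with a clearly positive random intercept."""
    data, truth = generate_cohort(
        CohortConfig(
            n_subjects=40, n_clusters=3, family="binomial",
            sigma_b_binomial=1.5, seed=7,
        )
    )
    return data, truth


@pytest.fixture(scope="session")
def binary_tiny_spec():
    return ModelSpec(family="binomial", fixed_terms=["time"], quadrature_points=25)


@pytest.fixture()
def two_subject_perfect():
    """Two subjects whose trajectories are exactly linear with common slope 1."""
    rows = []
    for sid, start in ((0, 1.0), (1, 2.0)):
        for t in range(3):
            rows.append(
                {
                    "subject_id": sid,
                    "cluster_id": 0,
                    "time": float(t),
                    "outcome": start + t,
                }
            )
    return LongitudinalDataset(pd.DataFrame(rows))


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        yield


def make_estimates(phis, sigmas, ids=None):
    from remr import ClusterEstimate

    ids = ids if ids is not None else range(len(phis))
    sigmas = np.broadcast_to(np.asarray(sigmas, float), (len(phis),))
    return [
        ClusterEstimate(i, float(p), float(s))
        for i, p, s in zip(ids, phis, sigmas)
    ]
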