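from __future__ import annotations

import numpy as np
import pytest

from fcnet import connectome as cn
from fcnet import synthetic as syn


def make_cm(matrix: np.ndarray, names=None) -> cn.ConnectivityMatrix:
    return cn.ConnectivityMatrix(np.asarray(matrix, dtype=float), list(names or []))


def random_connectivity(rng: np.random.Generator, n: int, loc: float = 0.0) -> cn.ConnectivityMatrix:
    """Random symmetric Gaussian edge-weight matrix (null data for NBS)."""
    z = rng.normal(loc, 1.0, size=(n, n))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return cn.ConnectivityMatrix(z)


@pytest.fixture(scope="session")
def small_spec() -> syn.CohortSpec:
    """A reduced cohort used by pipeline-level tests: 18 subjects, full
    90-region anatomy, short scans."""
    return syn.CohortSpec(
        n_per_group={"NC": 6, "SIVCIND": 6, "SIVaD": 6},
        n_timepoints=120,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    series, meta, truth = syn.generate_cohort(small_spec)
    return small_spec, series, meta, truth
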