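"""Shared fixtures: the standard phantom suite and cached pipeline runs.

The suite-level fixtures are session-scoped because the ant-colony runs
are the expensive part of the tests; every test that needs suite-wide
results shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from noduleant import AcoParams, generate_phantom, refined_aco, standard_suite, PhantomSpec
from noduleant.pipeline import RunConfig, run_pipeline

SUITE_SEED = 0


@pytest.fixture(scope="session")
def default_suite():
    """The fixed 10-phantom benchmark (default spec, seeds 0..9)."""
    return standard_suite(10, base_seed=SUITE_SEED)


@pytest.fixture(scope="session")
def small_phantom():
    """One small, quick phantom for unit-level checks."""
    spec = PhantomSpec(height=96, width=96, n_nodules=3, n_lines=1, seed=7)
    return generate_phantom(spec)


def _suite_pipeline(suite, method):
    cfg = RunConfig(method=method, seed=SUITE_SEED)
    return [run_pipeline(cfg, img, truth=truth) for img, truth in suite]


@pytest.fixture(scope="session")
def variant_results(default_suite):
    return _suite_pipeline(default_suite, "variant-aco")


@pytest.fixture(scope="session")
def aco_results(default_suite):
    return _suite_pipeline(default_suite, "aco")


@pytest.fixture(scope="session")
def refined_runs(default_suite):
    params = AcoParams(seed=SUITE_SEED)
    return [
        refined_aco(img, params, max_rounds=4, tol=0.01) for img, _ in default_suite
    ]


def partition_of(labels):
    """Cluster labels -> canonical partition (set of frozensets of indices)."""
    labels = np.asarray(labels)
    return {frozenset(np.flatnonzero(labels == v).tolist()) for v in np.unique(labels)}
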