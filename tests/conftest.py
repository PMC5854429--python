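"""Shared fixtures.

The three expensive validation runs (flooding convergence, WHAM recovery,
mimic parameter recovery) are session-scoped and shared by the module
tests and the acceptance tests; their problem sizes are the package's
benchmark defaults.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from unspool.benchmarks import (
    abmd_flattening_benchmark,
    mimic_pipeline_benchmark,
    wham_recovery_benchmark,
)

SUITE_SEED = 11

logging.getLogger("unspool").setLevel(logging.ERROR)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def wham_bench():
    return wham_recovery_benchmark(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def abmd_bench():
    return abmd_flattening_benchmark(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def mimic_bench(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("mimic_bench")
    return mimic_pipeline_benchmark(seed=SUITE_SEED, outdir=outdir)
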