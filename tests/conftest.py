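"""Shared fixtures: synthetic studies at two scales.

The small study is used by unit/integration tests; the full-scale study
(3 individuals x 3 replicates, 1e5 read pairs per sample, error-free)
backs the end-to-end acceptance checks and is built once per session.
"""
from __future__ import annotations

import numpy as np
import pytest

from hervkmap.report import RunConfig, run_study
from hervkmap.simulate import (
    ProtocolParams,
    default_ltr_library,
    simulate_study,
)


@pytest.fixture(scope="session")
def ltr_lib():
    return default_ltr_library()


@pytest.fixture(scope="session")
def clean_params():
    """Error-free protocol: no sequencing error, no element aging."""
    return ProtocolParams(seq_error_rate=0.0, ltr_mutation_rate_per_mya=0.0)


@pytest.fixture(scope="session")
def small_study(clean_params):
    """Compact 3x3 study with repeat-embedded and planted novel loci."""
    return simulate_study(
        seed=11,
        depth=20_000,
        cassette_groups=2,
        params=clean_params,
        n_solo=12,
        n_provirus=3,
        n_nonref=2,
        n_novel_ref=1,
        n_novel_nonref=1,
    )


@pytest.fixture(scope="session")
def small_result(small_study):
    return run_study(small_study, RunConfig())


@pytest.fixture(scope="session")
def full_study(clean_params):
    """Full-scale error-free study: 3 individuals x 3 replicates at 1e5
    read pairs per sample, with repeat-embedded loci and one planted
    novel locus of each class."""
    return simulate_study(
        seed=101,
        depth=100_000,
        cassette_groups=2,
        params=clean_params,
        n_solo=24,
        n_provirus=6,
        n_nonref=3,
        n_novel_ref=1,
        n_novel_nonref=1,
    )


@pytest.fixture(scope="session")
def full_result(full_study):
    return run_study(full_study, RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
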