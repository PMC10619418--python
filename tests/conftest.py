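"""Shared fixtures: matrices, validated-run pools, small simulation geometry."""

from __future__ import annotations

import numpy as np
import pytest

from rovebold.markov import CONDITIONS, build_transition_matrix
from rovebold.sequences import sample_valid_run
from rovebold.experiment import ExperimentConfig


@pytest.fixture(scope="session")
def matrices():
    return {cid: build_transition_matrix(c) for cid, c in CONDITIONS.items()}


@pytest.fixture(scope="session")
def validated_pool():
    """200 validated 400-trial runs per condition, default tolerances.

    Session-scoped: shared between the sequence statistics tests and the
    acceptance criteria.
    """
    pools = {}
    ss = np.random.SeedSequence(20240901)
    for cid, child in zip(("C1", "C2", "C3"), ss.spawn(3)):
        rng = np.random.default_rng(child)
        pools[cid] = [sample_valid_run(cid, rng=rng) for _ in range(200)]
    return pools


@pytest.fixture()
def small_config():
    return ExperimentConfig.small()


@pytest.fixture()
def tiny_config():
    """Even smaller geometry for per-test simulation loops."""
    cfg = ExperimentConfig.small()
    from rovebold.experiment import SessionLayout

    cfg.layout = SessionLayout(n_runs=1, n_trials=100, n_volumes=125, n_catch=2)
    return cfg
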