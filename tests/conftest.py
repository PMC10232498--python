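"""Shared fixtures: one small design, behavior and pattern set per session."""

import numpy as np
import pytest

from contextval import behavior as B
from contextval import decoding as C
from contextval import design as D
from contextval import neuralsim as N


@pytest.fixture(scope="session")
def design4():
    """Four-block design (the full study layout), few candidates for speed."""
    return D.generate_design(seed=11, n_blocks=4, n_candidates=10)


@pytest.fixture(scope="session")
def design4_timed(design4):
    return D.sample_timings(design4, seed=12)


@pytest.fixture(scope="session")
def behavior_records(design4):
    return B.simulate_behavior(design4.trials, B.BehaviorParams(),
                               n_subjects=12, seed=21)


@pytest.fixture(scope="session")
def strong_patterns(design4, behavior_records):
    """High-SNR graded codes with competition and moderation planted."""
    params = N.NeuralParams(a_ev=2.0, a_back=1.5, a_ctx=1.5, lam=0.8,
                            moderation=1.0, ctx_gain_sd=0.6, noise_sd=0.6,
                            n_voxels=150)
    one_subject = behavior_records[behavior_records["subject"] == 0]
    cb = N.make_codebook(params.n_voxels, rho=params.rho, omega=params.omega, seed=5)
    return N.simulate_patterns(design4.trials, one_subject, cb, params, seed=6)


@pytest.fixture(scope="session")
def null_patterns(design4, behavior_records):
    one_subject = behavior_records[behavior_records["subject"] == 0]
    params = N.NeuralParams.null(n_voxels=150)
    cb = N.make_codebook(params.n_voxels, rho=params.rho, omega=params.omega, seed=5)
    return N.simulate_patterns(design4.trials, one_subject, cb, params, seed=6)


@pytest.fixture(scope="session")
def strong_value_probs(strong_patterns):
    return C.loro_decode(strong_patterns, "value", seed=31)
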