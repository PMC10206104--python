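"""Shared fixtures: expensive simulation artifacts are built once per
session and reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from eitune import (Connectome, SynthSpec, TuningSchedule, gen_connectome,
                    gen_ground_truth_fc, staged_fit)


@pytest.fixture(scope="session")
def connectome30():
    """Default 30-node synthetic connectome."""
    return gen_connectome(SynthSpec(n_nodes=30, seed=3))


@pytest.fixture(scope="session")
def target30(connectome30):
    """Ground-truth target FC and generating weights for the 30-node net."""
    return gen_ground_truth_fc(connectome30, seed=5)


@pytest.fixture(scope="session")
def fit30(connectome30, target30):
    """Full staged E/I tuning of the 30-node ground-truth target
    (6 stages x 20 min biological time), with tuning-free validation."""
    target, _ = target30
    return staged_fit(connectome30, target, TuningSchedule(), seed=11)


@pytest.fixture(scope="session")
def two_node():
    return Connectome.two_node()
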