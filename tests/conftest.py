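"""Shared fixtures: trained network ensembles and simulated trial caches."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gainreset.task import generate_morph_input, train_network
from gainreset.rnn import simulate_trial

ENSEMBLE_SEEDS = tuple(range(12))


@pytest.fixture(scope="session")
def trained_ensemble():
    """Ten networks trained under the standard contract (seeds 0-9)."""
    nets = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in ENSEMBLE_SEEDS:
            net, report = train_network(seed=seed)
            net.meta["report"] = report
            nets.append(net)
    return nets


@pytest.fixture(scope="session")
def trained_network(trained_ensemble):
    return trained_ensemble[0]


@pytest.fixture(scope="session")
def gamma_zero_rates(trained_ensemble):
    """Per-network gamma = 0 firing-rate blocks (both directions, 3 reps)."""
    out = []
    for i, net in enumerate(trained_ensemble):
        blocks = []
        for d in (1, -1):
            trial = generate_morph_input(1000.0, 1.0, d)
            for rep in range(3):
                rec = simulate_trial(
                    net, trial.u, gamma=0.0, seed=1000 * i + rep + (0 if d == 1 else 500)
                )
                blocks.append(rec.r)
        out.append(blocks)
    return out
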