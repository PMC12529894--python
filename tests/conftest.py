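"""Shared fixtures: reference Markov chains and small trained models.

Heavier fixtures are session-scoped so the expensive training runs are
shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from trajgpt import (
    GptConfig,
    MarkovChainSpec,
    make_windows,
    sample_markov_chain,
)
from trajgpt.train import fit

# the four-state metastable reference chain: strong diagonal, mass mostly
# to neighbouring states — a discrete stand-in for a four-well landscape
T4 = np.array(
    [
        [0.97, 0.02, 0.005, 0.005],
        [0.02, 0.96, 0.015, 0.005],
        [0.005, 0.015, 0.96, 0.02],
        [0.005, 0.005, 0.02, 0.97],
    ]
)


@pytest.fixture(scope="session")
def metastable_matrix() -> np.ndarray:
    return T4.copy()


@pytest.fixture(scope="session")
def metastable_traj(metastable_matrix):
    """2e5 frames from the reference chain (the training corpus size)."""
    return sample_markov_chain(MarkovChainSpec(metastable_matrix, seed=11), 200_000)


@pytest.fixture(scope="session")
def small_markov_model(metastable_traj):
    """A compact model trained on the metastable chain.

    Deliberately smaller than the full benchmark configuration (d_x 32,
    window 20, 300 steps) so unit tests that need *a* trained model stay
    fast; the full-scale run lives in the acceptance tests.
    """
    ds = make_windows(metastable_traj, window_length=20, shuffle_seed=3)
    cfg = GptConfig(vocab_size=4, d_x=32, n_blocks=2, n_heads=4,
                    window_length=20, learning_rate=0.001, seed=5)
    model, state = fit(ds, cfg, n_steps=300)
    return model


@pytest.fixture(scope="session")
def copy_task_model():
    """A model trained on an engineered long-range copy task.

    Windows of length 12 over a 6-token alphabet: position 0 carries a
    uniformly drawn token, positions 1..10 are i.i.d. noise, and position
    11 repeats position 0.  Only the distant first token is informative
    for the final prediction, making position 0 causally necessary.
    Returns (model, prompts) where each prompt is the first 11 tokens of
    a held-out window.
    """
    from trajgpt.discretize import WindowDataset

    rng = np.random.default_rng(42)
    n, L, K = 4000, 12, 6
    windows = rng.integers(0, K, (n, L))
    windows[:, -1] = windows[:, 0]
    ds = WindowDataset(windows=windows, window_length=L, stride=1,
                       shuffle_seed=0, span_boundaries=True, n_states=K)
    cfg = GptConfig(vocab_size=K, d_x=32, n_blocks=2, n_heads=4,
                    window_length=L, learning_rate=0.002, seed=7)
    model, state = fit(ds, cfg, n_steps=1500)
    prompts = [w[:-1] for w in rng.integers(0, K, (12, L))]
    return model, prompts


@pytest.fixture(scope="session")
def cycle_model():
    """A model trained to determinism on the 3-state cycle 0->1->2->0."""
    P = np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float)
    traj = sample_markov_chain(MarkovChainSpec(P, seed=0), 3_000)
    ds = make_windows(traj, window_length=9, shuffle_seed=0)
    cfg = GptConfig(vocab_size=3, d_x=16, n_blocks=1, n_heads=2,
                    window_length=9, learning_rate=0.003, seed=2)
    model, state = fit(ds, cfg, n_steps=250)
    return model, state
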