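"""Train the two-pass model on a metastable Markov chain and recover its
kinetics from generated trajectories.

The chain's transition matrix is known, so every kinetic observable has
an exact reference: after training on 1e5 frames and generating 1e5 new
frames, the re-estimated transition matrix, stationary distribution,
slowest implied timescale and mean first-passage times should all land
close to the analytic values.  (A compact configuration is used here so
the example runs in two to three minutes; scripts/acceptance.py runs the
full-size benchmark.)
"""

import numpy as np

from trajgpt import (
    GptConfig,
    MarkovChainSpec,
    count_transitions,
    estimate_T,
    fit,
    generate_ensemble,
    implied_timescales,
    make_windows,
    mfpt,
    sample_markov_chain,
    stationary,
)

T_true = np.array(
    [
        [0.97, 0.02, 0.005, 0.005],
        [0.02, 0.96, 0.015, 0.005],
        [0.005, 0.015, 0.96, 0.02],
        [0.005, 0.005, 0.02, 0.97],
    ]
)

traj = sample_markov_chain(MarkovChainSpec(T_true, seed=1), 100_000)
ds = make_windows(traj, window_length=20, shuffle_seed=0)
cfg = GptConfig(vocab_size=4, d_x=32, n_blocks=2, n_heads=4, window_length=20,
                learning_rate=0.001, seed=0)
model, state = fit(ds, cfg, n_steps=800)
print(f"trained {cfg.n_blocks}-block model, final loss {state.loss_history[-1]:.3f}")

prefixes = [traj.states[i * 900:i * 900 + 20] for i in range(100)]
gen = generate_ensemble(model, prefixes, 980, rng=2)
est = estimate_T(count_transitions(gen, lag=1))

print("\nmax-abs transition-matrix error:",
      round(float(np.abs(est.matrix - T_true).max()), 4))
pi_t, pi_g = stationary(T_true), stationary(est)
print("stationary truth    :", np.round(pi_t, 3))
print("stationary recovered:", np.round(pi_g, 3))
print("slowest ITS truth/recovered: "
      f"{implied_timescales(T_true)[0]:.1f} / {implied_timescales(est)[0]:.1f} frames")
print("MFPT A->D truth/recovered  : "
      f"{mfpt(T_true, 0, 3):.0f} / {mfpt(est, 0, 3):.0f} frames")
# small errors here mean the generative model has internalized both the
# equilibrium and the slow kinetics of the chain
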