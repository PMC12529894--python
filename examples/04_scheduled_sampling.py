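"""The scheduled sampler: from teacher forcing to self-generated context.

The probability of feeding the ground-truth ("golden") token to the
second pass is p(i, t) = eps^(t (1 - k^i)) — 1 everywhere at step 0, and
decaying with both training step i and window position t.  The printed
golden fraction during a short training run follows the schedule.
"""

import numpy as np

from trajgpt import (
    GptConfig,
    MarkovChainSpec,
    fit,
    make_windows,
    sample_markov_chain,
    schedule_probability,
)

eps, k = 0.99, 0.999
print("schedule p(i, t) = eps^(t (1 - k^i)),  eps=0.99, k=0.999")
print("step i \\ position t:      0      10      25      49")
for i in (0, 100, 1000, 10_000):
    row = [schedule_probability(i, t, eps, k) for t in (0, 10, 25, 49)]
    print(f"  i={i:>6}:          " + "  ".join(f"{p:.4f}" for p in row))
# at i=0 every token is golden; as i grows the late positions are
# increasingly replaced by the model's own first-pass samples

traj = sample_markov_chain(
    MarkovChainSpec(np.array([[0.95, 0.05], [0.05, 0.95]]), seed=0), 20_000
)
ds = make_windows(traj, window_length=50, shuffle_seed=0)
cfg = GptConfig(vocab_size=2, d_x=16, n_blocks=1, n_heads=2, window_length=50,
                learning_rate=0.002, seed=1)
model, state = fit(ds, cfg, n_steps=200)
gf = state.golden_fraction_history
print("\nobserved golden fraction while training:")
for s in (0, 50, 100, 199):
    print(f"  step {s:>3}: {gf[s]:.3f}")
# the observed fraction tracks the mean of p(i, t) over the window
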