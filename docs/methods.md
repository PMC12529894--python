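# Methods

## Scope and model

`trajgpt` models discrete conformational-state trajectories — sequences
x_1, x_2, ... of integer state labels sampled at a fixed frame interval
— with a small autoregressive transformer, and evaluates how well the
trained model reproduces the kinetics of the process that produced the
data.  The intended use case is learning long-timescale dynamics from
many short trajectory segments (the regime of molecular-dynamics data),
but every component is exercised here on synthetic systems whose
kinetics are known exactly, so each claim the test suite makes is
checkable against an analytic or brute-force reference.

### Network

The sequence model is a GPT-style decoder.  Tokens are embedded
(learned table, width `d_x`) and summed with learned absolute position
embeddings over a window of `window_length` frames.  Each of `n_blocks`
blocks computes

    A = softmax(Q K^T / sqrt(d_q)) V      (causal, multi-head)
    B = LayerNorm(FFN(H + A))
    H <- H + A + B

i.e. the attention update and the feed-forward update are both added to
the running residual stream.  Heads are concatenated and mixed by a
learned output projection; that projection is not forced by the
single-head algebra above but is the standard way to let heads
interact, and we adopt it.  The decoding head applies one more
nonlinear transform f_dec (FFN + residual + LayerNorm) and a linear map
D with bias, followed by softmax, yielding Q(x_{t+1} | x_{<=t}).

The feed-forward networks are two-layer ReLU MLPs of width
`ffn_mult * d_x` (default 4x).  Parameters are float32 by default
(float64 available via `GptConfig.dtype`); the whole network is plain
NumPy with hand-written backpropagation — at these sizes (d_x <= 128,
2-3 blocks, window ~50) BLAS-backed matmuls train the model on a single
CPU core in minutes, and the package carries no deep-learning framework
dependency.

### Two-pass training with scheduled sampling

Training uses two decoder stacks with separate parameters (a
`share_passes` switch ties them).  The first pass reads the golden
(ground-truth) window and emits per-position next-state distributions.
A sampler then assembles the second pass's input: at window position t
and training step i the golden token is kept with probability

    p(i, t) = eps^(t (1 - k^i)),        eps, k in (0, 1),

otherwise the token is replaced by a multinomial draw from the first
pass's prediction for that position.  p = 1 at i = 0 and at t = 0, is
non-increasing in both arguments, and tends to eps^t: early in training
and early in the window the model sees ground truth; later it
increasingly sees its own samples, shrinking the train/inference
mismatch of teacher forcing.  Replacement draws are multinomial rather
than argmax so transition variability survives in the mixed windows.

The printed form of the schedule is ambiguous about the exponent
grouping; the reading above is the one that satisfies both stated
limits (full teacher forcing at the start, reliance on own outputs
later) and keeps p in (0, 1].

The default constants are eps = 0.999 and k = 0.999: for a 50-frame
window the saturating replacement fraction 1 - eps^t stays below ~5%
even at the far end, so the schedule stays genuinely gradual.  This
default matters.  With a faster decay (eps = 0.99: 39% terminal
replacement) the replaced context tokens decouple positions from their
golden targets often enough to bias the learned conditionals toward
faster mixing, and on benchmark chains the recovered kinetics degrade
monotonically as training proceeds and the schedule engages — the
opposite of what the technique is for.  Both constants are exposed in
the config for experimentation.

The loss is the mean cross-entropy of the next golden token under the
second pass's output, plus an auxiliary identical term on the first
pass (weight `aux_pass1_weight`, default 1.0).  The auxiliary term is
on by default as a design choice: sampling is discrete, so no gradient
reaches the first pass through the second pass's loss, and an untrained
first pass would feed noise — not "initial predictions" — to the
sampler.  Setting the weight to 0 restores a pass-2-only objective.
Optimization is Adam (batch 32) with linear warmup and cosine decay to
10% of the base rate; constant-rate Adam leaves the learned
conditionals jittering at convergence with step-size-proportional
noise, which measurably inflates seed-to-seed variance of downstream
kinetic estimates.  Training is bitwise deterministic given the config
seed.

On long ergodic first-order Markov data the per-token cross-entropy
converges to the path-entropy rate -sum_l P_l sum_m P_ml ln Q_ml with Q
the learned conditionals (time average -> ensemble average), so
minimizing it drives Q toward the chain's transition law; the
acceptance suite checks this identity numerically to 2%.

### Generation

Generation extends a prefix autoregressively: each new token is drawn
from the second pass's conditional given the trailing window (the
second pass produces the model's final output; it is also the stack
used for tracing).  A temperature rescales the conditional, with
temperature 0 meaning argmax.  `generate_ensemble` advances many
prefixes in one batched forward per step; for the final block only the
last position's queries and feed-forward are evaluated (identical
output, roughly 40% cheaper), since only that position feeds the head.

## Kinetic evaluation

Transitions are counted at a lag (never across the joins between
concatenated source trajectories) and row-normalized into a transition
matrix (a detailed-balance variant symmetrizes counts first).  From a
matrix: stationary distribution by eigendecomposition (with an explicit
irreducibility check that names the strongly connected blocks on
failure), free energies F_l = -kT ln pi_l reported with min F = 0,
implied timescales t_i = -tau / ln lambda_i (unit eigenvalue excluded;
complex eigenvalues contribute |lambda| with a warning; non-positive
real eigenvalues carry no timescale at that lag and are dropped with a
warning), and mean first-passage times by the first-step linear system
m_s = 1 + sum_{j != target} T_sj m_j.  The trajectory-based MFPT
estimator averages the first-hit interval over every frame spent in the
source state — any start rule that conditions only on the present state
is unbiased for the Markov hitting time, and per-frame averaging uses
the most data; censored starts (segment ends before the target) are
dropped.  Both estimators are provided and cross-checked in the tests.

Commit-time analysis counts transitions between *committed* visits:
runs of a single state lasting at least `commit_time` frames.  The
run-length encoding is restricted to the queried pair (a, b), committed
visits are kept, and adjacent (a, b) pairs are counted — each passage
that leaves a committed a-visit and next commits to b counts once,
whatever intermediate states were crossed.  The pair restriction is
deliberate: reducing over *all* states would make the count
non-monotone in commit time (dropping a short intermediate visit can
manufacture a new adjacency) and would make the A->D count of a 1-D
continuous walk identically zero (the walk always passes through the
interior states).  Under the pair restriction the count is provably
non-increasing in commit time, and for a high-barrier system the
committed A->D count decays to zero — the qualitative signature of
inefficient sampling.

### Kinetic times from embeddings

The trained model's conditionals admit an embedding-level reading: with
input embeddings X^(l) (token-embedding rows) and output embeddings
Xhat^(m) = M_theta^T D^T e_m, the ansatz

    Q_ml ~ exp(C_m) exp(X^(l) . Xhat^(m))

expresses the one-step conditional as a softmax over embedding dot
products, and

    t_lm = 1 / (P_l Q_ml + P_m Q_lm)

(with P the stationary weights) is the average interconversion time of
the pair — the inverse of the stationary flux between l and m.  The
table is symmetric by construction; pairs with zero flux get infinite
time.

M_theta is obtained by linearizing the single-context decoding map
(embedding -> pre-head output) over the K actual state embeddings with
a least-squares (secant) fit, and C_m is the induced offset plus head
bias.  A pointwise Jacobian — at the mean embedding or at the state
embeddings themselves — was evaluated and rejected: a trained network
is strongly nonlinear across well-separated state embeddings, and its
infinitesimal slope misrepresents the finite differences that the
ansatz actually has to reproduce, to the point of scrambling the
pair ranking.  The secant fit coincides with the Jacobian in the linear
limit, preserves the ansatz form exactly, and becomes a genuine
overdetermined least-squares linearization when the state count exceeds
d_x + 1.  `fit_corrections=False` sets C = 0 (raw dot products) for
ablation.  The quality metric is the Spearman rank correlation between
the embedding-derived and the empirically counted kinetic-time tables.

## Causal tracing

To localize which context positions drive a prediction, the token
embeddings of an input window are corrupted with zero-mean spherical
Gaussian noise (default scale: 3x the elementwise standard deviation of
the embedding table), and the clean activation of one component — the
token embedding, or the attention output A at all blocks jointly (a
per-block entry point exists) — is restored at one position at a time.
The indirect effect is the probability recovered for the clean run's
argmax next state; averaging over prompts and noise draws gives the AIE
profile.  Noise draws are keyed to each prompt's content rather than
its list index, so the average is exactly invariant to prompt order.
Measuring the effect on the model's own argmax (not the golden next
token) isolates the model's decision pathway from data noise.

Two signatures anchor the analysis: a model trained on first-order
Markov data concentrates AIE at the last context position (only the
present state is informative), while a model trained on an engineered
long-range copy task — first token uniform, interior tokens i.i.d.
noise, final token a copy of the first — concentrates AIE at the
distant determining frame.

## Synthetic systems

The Markov generator samples arbitrary user-specified chains by inverse
CDF against a seeded uniform stream; it is the ground-truth source for
all recovery benchmarks.  The benchmark chain is four-state and
metastable (diagonal 0.96-0.97, off-diagonal mass mostly to
neighbours), giving a slowest implied timescale of ~37 frames and
A<->D mean first-passage times of ~129 frames.

The continuous system is a 1-D overdamped Langevin particle,
x <- x - U'(x) dt + sqrt(2 kT dt) xi, integrated by Euler–Maruyama
(kT = 1 by convention; all energies in kT).  The potential is a sum of
Gaussian wells at configurable centers (default -3, -1, 1, 3), Gaussian
barrier bumps at the midpoints, and a steep (x/4)^10 confinement wall —
a closed form whose energies, gradients, and cell-integrated Boltzmann
weights are all exactly computable.  Raising the outer barriers
isolates the terminal wells, reproducing the hallmark regime where
direct committed A->D transitions are vanishingly rare.  Positions are
mapped to states by nearest well center (ties to the lowest index).
Test problem sizes are chosen so barrier crossings are plentiful where
equilibrium statistics are asserted (total barrier ~2.5-3 kT, several
hundred Kramers crossings per 1e6 steps) and rare where the
commit-time decay is asserted (total barrier ~5 kT); the default
high-barrier landscape sits deliberately in the inefficient-sampling
regime and is not expected to equilibrate in short runs.

What the synthetic generators do not emulate: high-dimensional
configuration spaces, non-Markovian memory from projecting out fast
degrees of freedom, state-space discretization error from imperfect
clustering, and the heterogeneous trajectory lengths of real MD
datasets.  Passing the recovery benchmarks therefore demonstrates that
the architecture, training scheme and estimators are correct and
unbiased on exactly-Markov sources, not that the model resolves the
slow modes of any particular molecular system.

## Discretization

k-center clustering uses the Gonzalez farthest-first traversal: the
first center is a seeded uniform draw, each next center is the point
farthest from the current set, and the realized cover radius (max
distance of any training point to its nearest center) is at most twice
the optimal k-center radius — verified against exhaustive search on
small instances.  The metric is pluggable (any callable mapping points
x center to distances; Euclidean built in), which is where RMSD-type
metrics for molecular coordinates attach.  Window construction
concatenates trajectories without separator tokens, enumerates
sliding windows (stride 1 by default, crossing source boundaries by
default, with an opt-out), and shuffles them with a seed; the window
multiset is shuffle-invariant.

## Numerical choices and edge cases

- Cross-entropy floors predicted probabilities at 1e-12; softmax is
  computed with max-subtraction.
- LayerNorm epsilon 1e-5; parameter init N(0, 0.02^2); LN gains start
  at 1, biases at 0.
- `estimate_T` drops never-visited states with a warning and records
  the retained-state mapping; a visited state with no outgoing
  transitions is an error.  Unvisited states in generated trajectories
  are a coverage defect worth reporting, not silently ignoring.
- Ties in nearest-center assignment go to the lowest index,
  everywhere, for determinism.
- All stochastic components (Langevin noise, chain sampling, window
  shuffling, parameter init, schedule sampling, generation, trace
  noise) consume dedicated seeded `numpy` generators; identical seeds
  give bitwise-identical results.
- The 4-state recovery benchmark trains for 900 optimizer steps
  (batch 32, window 50) — past the loss plateau of this problem — and
  generates 2e5 frames as 200 parallel chains of 1000 frames whose
  prefixes are drawn from the training data (approximately stationary
  starts).

## Known limitations

- Scheduled sampling trades a small bias for the teacher-forcing
  mismatch: late window positions see corrupted contexts during
  training, which slightly smooths the learned conditionals at the
  default schedule constants.  The recovery benchmarks quantify the
  net effect.
- Absolute learned position embeddings cap the context at
  `window_length`; generation slides the window, so a key-value cache
  cannot be reused across steps and generation cost scales with
  window length.
- The embedding-kinetics table inherits the accuracy of the model's
  one-step conditionals; for states the model confuses, the table is
  correspondingly off.
- Trajectory-based MFPT drops censored passages, biasing long MFPTs
  slightly downward on short segments; the matrix-based estimator does
  not have this issue.
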