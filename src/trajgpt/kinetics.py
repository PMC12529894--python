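"""Kinetic evaluation of state trajectories and trained sequence models.

Implements the standard Markov-state-model toolbox — transition counting
at a lag time, row-stochastic estimation, stationary (Boltzmann)
distribution, free energy, implied timescales and mean first-passage
times — plus two analyses specific to generative sequence models:

* commit-time transition counting, which reduces a trajectory to
  "committed" visits (dwells of at least a minimum duration) before
  counting transitions, isolating genuine barrier crossings from
  recrossing noise; and
* the kinetic-time-from-embeddings analysis: the trained model's token
  embeddings X^(l) and output embeddings Xhat^(m) define, through the
  ansatz Q_ml = exp(C_m) exp(X^(l).Xhat^(m)) / Z_l, a pairwise
  interconversion probability, whose inverse
  t_lm = 1 / (P_l Q_ml + P_m Q_lm) is the average transition time
  between states l and m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .model import NanoGpt, softmax
from .systems import StateTrajectory

__all__ = [
    "TransitionCounts",
    "TransitionMatrixEst",
    "KineticTimeTable",
    "generate",
    "generate_ensemble",
    "count_transitions",
    "estimate_T",
    "stationary",
    "empirical_distribution",
    "free_energy",
    "implied_timescales",
    "its_vs_lag",
    "mfpt",
    "mfpt_empirical",
    "committed_transitions",
    "kinetic_time_table",
    "kinetic_time_empirical",
    "kinetic_time_from_embeddings",
]


# --------------------------------------------------------------- containers
@dataclass
class TransitionCounts:
    counts: np.ndarray  # (K, K) integer matrix: counts[i, j] = i -> j at lag
    lag: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TransitionMatrixEst:
    matrix: np.ndarray
    lag: int
    estimator: str = "row-normalized"
    retained_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        rows = self.matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-10):
            raise ValueError("rows must sum to 1 within 1e-10")


@dataclass
class KineticTimeTable:
    """Pairwise average transition times t_lm (frames), symmetric."""

    times: np.ndarray
    stationary: np.ndarray
    source: str  # "empirical" | "embedding-ansatz"
    corrections: np.ndarray | None = None  # C_m of the ansatz

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (l < m) times as a flat vector, row-major."""
        iu = np.triu_indices_from(self.times, k=1)
        return self.times[iu]


# --------------------------------------------------------------- generation
def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(probs, axis=-1)
    u = rng.random((probs.shape[0], 1))
    return np.minimum((u > cum).sum(-1), probs.shape[-1] - 1)


def _apply_temperature(probs: np.ndarray, temperature: float) -> np.ndarray:
    if temperature == 1.0:
        return probs
    if temperature <= 0.0:
        out = np.zeros_like(probs)
        out[np.arange(probs.shape[0]), probs.argmax(-1)] = 1.0
        return out
    logits = np.log(np.maximum(probs, 1e-300)) / temperature
    return softmax(logits)


def generate(
    model: NanoGpt,
    prefix: StateTrajectory | np.ndarray,
    n_new: int,
    temperature: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> StateTrajectory:
    """Extend a prefix autoregressively by n_new states.

    Each new state is drawn from the model's conditional given the
    trailing context window; temperature rescales the conditional
    (temperature -> 0 is greedy argmax).  The output begins with the
    prefix, unmodified.
    """
    out = generate_ensemble(model, [prefix], n_new, temperature, rng)
    return StateTrajectory(out.states, frame_interval=out.frame_interval,
                           n_states=out.n_states)


def generate_ensemble(
    model: NanoGpt,
    prefixes,
    n_new: int,
    temperature: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> StateTrajectory:
    """Extend several prefixes in parallel (one batched forward per step).

    Returns the extended trajectories concatenated, with boundaries at the
    joins.  All prefixes must have equal length.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for p in prefixes:
        arr = p.states if isinstance(p, StateTrajectory) else np.asarray(p)
        rows.append(np.asarray(arr, dtype=np.int64))
    if not rows or any(r.size < 1 for r in rows):
        raise ValueError("each prefix must have length >= 1")
    if len({r.size for r in rows}) != 1:
        raise ValueError("ensemble prefixes must share a length")
    ctx = np.stack(rows)
    K = model.config.vocab_size
    if ctx.min() < 0 or ctx.max() >= K:
        raise ValueError("prefix contains out-of-vocabulary state")
    B = ctx.shape[0]
    L = model.config.window_length
    new = np.empty((B, n_new), dtype=np.int64)
    window = ctx[:, -L:]
    for j in range(n_new):
        probs = model.predict_proba(window)
        nxt = _sample_rows(_apply_temperature(probs, temperature), rng)
        new[:, j] = nxt
        window = np.concatenate([window[:, -(L - 1):], nxt[:, None]], axis=1)
    full = np.concatenate([ctx, new], axis=1)
    bounds = np.arange(1, B) * full.shape[1]
    return StateTrajectory(full.ravel(), bounds, n_states=K)


# ---------------------------------------------------------------- counting
def count_transitions(traj: StateTrajectory, lag: int = 1,
                      n_states: int | None = None) -> TransitionCounts:
    """Sliding-window counts of (state at f, state at f+lag) pairs.

    Pairs never span the joins between source trajectories.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    K = n_states or traj.n_states
    counts = np.zeros((K, K), dtype=np.int64)
    any_pairs = False
    for seg in traj.segments():
        if seg.size > lag:
            any_pairs = True
            np.add.at(counts, (seg[:-lag], seg[lag:]), 1)
    if not any_pairs:
        raise ValueError(f"lag {lag} leaves no countable pairs in any segment")
    return TransitionCounts(counts, lag)


def estimate_T(counts: TransitionCounts, reversible: bool = False) -> TransitionMatrixEst:
    """Row-normalize transition counts into a stochastic matrix.

    States never visited (empty rows and columns) are dropped, with the
    retained-state mapping recorded.  ``reversible=True`` symmetrizes the
    counts first (detailed-balance estimator).
    """
    C = counts.counts.astype(float)
    if counts.total == 0:
        raise ValueError("empty counts")
    visited = (C.sum(axis=1) + C.sum(axis=0)) > 0
    if not visited.all():
        dropped = np.flatnonzero(~visited)
        warnings.warn(f"dropping never-visited states {dropped.tolist()}")
    C = C[np.ix_(visited, visited)]
    if (C.sum(axis=1) == 0).any():
        raise ValueError("a visited state has no outgoing transitions")
    tag = "row-normalized"
    if reversible:
        C = 0.5 * (C + C.T)
        tag = "symmetrized-reversible"
    T = C / C.sum(axis=1, keepdims=True)
    return TransitionMatrixEst(T, counts.lag, tag, np.flatnonzero(visited))


# ------------------------------------------------------------- equilibrium
def stationary(T: np.ndarray | TransitionMatrixEst) -> np.ndarray:
    """Stationary distribution pi with pi T = pi, by eigendecomposition."""
    M = T.matrix if isinstance(T, TransitionMatrixEst) else np.asarray(T, float)
    n_comp, labels = connected_components(M > 0, directed=True, connection="strong")
    if n_comp > 1:
        blocks = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(f"chain is reducible; strongly connected blocks: {blocks}")
    vals, vecs = np.linalg.eig(M.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def empirical_distribution(traj: StateTrajectory, n_states: int | None = None) -> np.ndarray:
    """Raw state populations of a trajectory."""
    K = n_states or traj.n_states
    return np.bincount(traj.states, minlength=K) / len(traj)


def free_energy(pi: np.ndarray, kT: float = 1.0) -> np.ndarray:
    """Per-state free energy F_l = -kT ln pi_l, shifted so min(F) = 0.

    Zero-probability states get F = inf (excluded from the shift).
    """
    pi = np.asarray(pi, float)
    F = np.full(pi.shape, np.inf)
    pos = pi > 0
    if not pos.all():
        warnings.warn(
            f"states {np.flatnonzero(~pos).tolist()} have zero probability; "
            "their free energy is reported as inf"
        )
    F[pos] = -kT * np.log(pi[pos])
    return F - F[pos].min()


# ---------------------------------------------------------------- kinetics
def implied_timescales(T: np.ndarray | TransitionMatrixEst,
                       lag: float | None = None) -> np.ndarray:
    """Implied timescales t_i = -lag / ln lambda_i, slowest first.

    The unit eigenvalue is excluded; complex eigenvalues contribute their
    magnitude; real eigenvalues <= 0 carry no timescale at this lag and
    are dropped with a warning.
    """
    if isinstance(T, TransitionMatrixEst):
        lag = lag if lag is not None else T.lag
        M = T.matrix
    else:
        M = np.asarray(T, float)
        lag = 1 if lag is None else lag
    vals = np.linalg.eigvals(M)
    order = np.argsort(-np.abs(vals))
    vals = vals[order]
    mags = []
    seen_unit = 0
    for lam in vals:
        if abs(lam - 1.0) < 1e-12 or abs(lam) >= 1.0 - 1e-14:
            seen_unit += 1
            continue
        if abs(lam.imag) > 1e-12:
            warnings.warn("complex eigenvalue: using |lambda| for the timescale")
            mags.append(abs(lam))
        elif lam.real <= 0.0:
            warnings.warn(
                f"eigenvalue {lam.real:.4g} <= 0: no timescale at this lag "
                "(lag too small)"
            )
        else:
            mags.append(lam.real)
    if seen_unit > 1:
        warnings.warn("multiple unit-magnitude eigenvalues (reducible chain?)")
    ts = np.array([-lag / np.log(m) for m in mags])
    return np.sort(ts)[::-1]


def its_vs_lag(traj: StateTrajectory, lags) -> dict[int, np.ndarray]:
    """Implied-timescale convergence sweep: estimate T at each lag and
    report its timescales (in frames)."""
    out = {}
    for lag in lags:
        T = estimate_T(count_transitions(traj, int(lag)))
        out[int(lag)] = implied_timescales(T)
    return out


def _check_reachable(M: np.ndarray, source: int, target: int) -> None:
    reach = {source}
    frontier = [source]
    adj = [np.flatnonzero(M[i] > 0) for i in range(M.shape[0])]
    while frontier:
        i = frontier.pop()
        for j in adj[i]:
            if j not in reach:
                reach.add(int(j))
                frontier.append(int(j))
    if target not in reach:
        raise ValueError(f"state {target} is unreachable from state {source}")


def mfpt(T: np.ndarray | TransitionMatrixEst, source: int, target: int) -> float:
    """Mean first-passage time (frames) by first-step analysis.

    Solves m_s = 1 + sum_{j != target} T_sj m_j with m_target = 0.
    """
    M = T.matrix if isinstance(T, TransitionMatrixEst) else np.asarray(T, float)
    lag = T.lag if isinstance(T, TransitionMatrixEst) else 1
    if source == target:
        return 0.0
    _check_reachable(M, source, target)
    keep = np.arange(M.shape[0]) != target
    A = np.eye(keep.sum()) - M[np.ix_(keep, keep)]
    m = np.linalg.solve(A, np.ones(keep.sum()))
    full = np.zeros(M.shape[0])
    full[keep] = m
    return float(full[source] * lag)


def mfpt_empirical(traj: StateTrajectory, source: int, target: int) -> float:
    """Trajectory-based MFPT: mean first-hit interval, averaged over every
    frame spent in the source state (each such frame is a valid start of a
    first-passage observation by the Markov property).

    Intervals never cross the joins between source trajectories; frames
    whose segment ends before the target is reached are censored and
    dropped.
    """
    if source == target:
        return 0.0
    total, n_obs = 0.0, 0
    for seg in traj.segments():
        src_idx = np.flatnonzero(seg == source)
        tgt_idx = np.flatnonzero(seg == target)
        if src_idx.size == 0 or tgt_idx.size == 0:
            continue
        nxt = np.searchsorted(tgt_idx, src_idx, side="left")
        ok = nxt < tgt_idx.size
        total += (tgt_idx[nxt[ok]] - src_idx[ok]).sum()
        n_obs += int(ok.sum())
    if n_obs == 0:
        raise ValueError(f"no completed {source}->{target} passages observed")
    return total / n_obs * traj.frame_interval


# ------------------------------------------------------------- commit time
def committed_transitions(traj: StateTrajectory, a: int, b: int,
                          commit_time: int) -> int:
    """Count a -> b transitions between *committed* visits.

    A visit is committed when the system dwells in one state for at least
    ``commit_time`` consecutive frames; shorter excursions are recrossing
    noise and are dropped.  The trajectory's run-length encoding is
    restricted to visits of the pair (a, b), committed visits are kept,
    and the count is the number of consecutive (a, b) pairs in that
    sequence — i.e. each passage that leaves a committed a-visit and next
    commits to b counts once, regardless of which intermediate states
    were crossed on the way.  Under this reduction the count is provably
    non-increasing in ``commit_time``: raising it only removes visits
    from the pair sequence, which never creates a new (a, b) adjacency.
    """
    if a == b:
        raise ValueError("a and b must differ")
    if commit_time < 1:
        raise ValueError("commit_time must be >= 1 frame")
    n = 0
    for seg in traj.segments():
        change = np.flatnonzero(np.diff(seg)) + 1
        starts = np.concatenate([[0], change])
        lengths = np.diff(np.concatenate([starts, [seg.size]]))
        states = seg[starts]
        keep = ((states == a) | (states == b)) & (lengths >= commit_time)
        committed = states[keep]
        if committed.size >= 2:
            n += int(((committed[:-1] == a) & (committed[1:] == b)).sum())
    return n


# ------------------------------------------------- kinetic time from Eq 8-9
def kinetic_time_table(Q: np.ndarray, pi: np.ndarray, source: str,
                       corrections: np.ndarray | None = None) -> KineticTimeTable:
    """Average transition times t_lm = 1 / (P_l Q_ml + P_m Q_lm).

    The denominator is the stationary interconversion flux between l and
    m; the table is symmetric by construction.  Pairs with zero flux get
    t = inf.
    """
    Q = np.asarray(Q, float)
    pi = np.asarray(pi, float)
    flux = pi[:, None] * Q.T + pi[None, :] * Q  # [l, m]: P_l Q_ml + P_m Q_lm
    with np.errstate(divide="ignore"):
        t = np.where(flux > 0, 1.0 / np.where(flux > 0, flux, 1.0), np.inf)
    return KineticTimeTable(t, pi, source, corrections)


def kinetic_time_empirical(traj: StateTrajectory, lag: int = 1) -> KineticTimeTable:
    """Empirical kinetic-time table from counted one-step conditionals and
    raw state populations."""
    est = estimate_T(count_transitions(traj, lag))
    K = traj.n_states
    Q = np.zeros((K, K))
    r = est.retained_states
    Q[np.ix_(r, r)] = est.matrix
    return kinetic_time_table(Q, empirical_distribution(traj), "empirical")


def ansatz_conditionals(X: np.ndarray, Xhat: np.ndarray,
                        C: np.ndarray | None = None) -> np.ndarray:
    """Transition probabilities of the embedding ansatz:

        Q_ml = exp(C_m) exp(X^(l) . Xhat^(m)) / sum_k exp(C_k) exp(X^(l) . Xhat^(k))

    with input embeddings X (rows X^(l)), output embeddings Xhat (rows
    Xhat^(m)) and per-state correction terms C (zero if omitted).
    Returned as a row-stochastic matrix Q[l, m] = Q(m | l).
    """
    scores = np.asarray(X, float) @ np.asarray(Xhat, float).T
    if C is not None:
        scores = scores + np.asarray(C, float)[None, :]
    return softmax(scores)


def _secant_output_map(core) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearize the model's single-context decoding around the state
    embeddings: find M_theta and offset g0 with

        f_dec(H(x)) ~= g0 + (x - xbar) M_theta^T

    by least squares over the K actual token embeddings x = X^(l) (the
    secant analogue of the pointwise Jacobian; an infinitesimal Jacobian
    of the trained, strongly nonlinear map does not represent its
    variation across well-separated state embeddings, whereas the secant
    fit does, and it coincides with the Jacobian in the linear limit).
    Returns (M_theta, g0, xbar).
    """
    K = core.config.vocab_size
    X = core.params["wte"].astype(float)
    logits, cache = core.forward(np.arange(K, dtype=np.int64)[:, None])
    G = cache["G"][:, 0, :].astype(float)  # f_dec outputs per single-token context
    xbar = X.mean(axis=0)
    g0 = G.mean(axis=0)
    Mt, *_ = np.linalg.lstsq(X - xbar, G - g0, rcond=None)  # (d, d) = M_theta^T
    return Mt.T, g0, xbar


def kinetic_time_from_embeddings(
    model: NanoGpt, pi: np.ndarray, fit_corrections: bool = True
) -> KineticTimeTable:
    """Kinetic times derived from the trained model's embeddings.

    The one-step conditional is expressed through the embedding ansatz
    Q_ml ~ exp(C_m) exp(X^(l) . Xhat^(m)) with input embeddings X^(l)
    (token-embedding rows) and output embeddings Xhat^(m) = M_theta^T D^T
    e_m, where M_theta linearizes the decoding transform over the state
    embeddings (secant least-squares fit) and C_m is a per-state
    correction for the time-lag effect.  C has no exact closed form; it
    is fixed by requiring the ansatz to match the model's directly
    decoded single-context conditionals in the least-squares sense
    (``fit_corrections=False`` sets C = 0 for ablation — the softmax of
    raw embedding dot products).  Times are t_lm = 1/(P_l Q_ml + P_m Q_lm).
    """
    core = model.inference_core
    K = model.config.vocab_size
    X = core.params["wte"].astype(float)  # (K, d) input embeddings
    if np.allclose(X.std(axis=0), 0.0):
        warnings.warn("degenerate embeddings (all states identical): "
                      "kinetic times will be near-identical")
    M, g0, xbar = _secant_output_map(core)
    D = core.params["head.D"].astype(float)
    Xhat = D @ M  # row m = M_theta^T D^T e_m
    C = None
    if fit_corrections:
        # absorb the expansion offset and head bias into the correction
        C = core.params["head.b"].astype(float) + (g0 - xbar @ M.T) @ D.T
    Q = ansatz_conditionals(X, Xhat, C)
    return kinetic_time_table(Q, pi, "embedding-ansatz", corrections=C)
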