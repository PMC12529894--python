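"""Synthetic dynamical systems with known ground-truth kinetics.

Two generators are provided as stand-ins for molecular dynamics data:

* a one-dimensional overdamped Langevin particle in a multi-well
  potential (default: four metastable wells separated by high barriers),
  discretized to states by nearest-center assignment; and
* arbitrary discrete-time Markov chains, specified by a row-stochastic
  transition matrix.

Both are seed-deterministic, so every downstream kinetic quantity
(stationary distribution, implied timescales, mean first-passage times)
has an analytic or brute-force reference value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

__all__ = [
    "PotentialSpec",
    "LangevinParams",
    "MarkovChainSpec",
    "StateTrajectory",
    "four_well_potential",
    "simulate_langevin",
    "map_to_states",
    "sample_markov_chain",
    "boltzmann_state_weights",
]


@dataclass(frozen=True)
class PotentialSpec:
    """Closed-form 1-D potential built from Gaussian wells and barrier bumps.

    U(x) = sum_i -d_i exp(-(x-c_i)^2 / 2w^2)
         + sum_j  b_j exp(-(x-m_j)^2 / 2w^2)
         + (x / x_wall)^10

    with well centers ``c_i`` and depths ``d_i`` (kT), barrier bumps of
    height ``b_j`` (kT) placed at the midpoints ``m_j`` between adjacent
    wells, shared Gaussian width ``w``, and a steep polynomial confinement
    wall so U -> inf as |x| -> inf.  Energies are in units of kT.
    """

    well_centers: tuple[float, ...] = (-3.0, -1.0, 1.0, 3.0)
    well_depths: tuple[float, ...] = (4.0, 4.0, 4.0, 4.0)
    barrier_heights: tuple[float, ...] = (5.0, 2.0, 5.0)
    width: float = 0.35
    x_wall: float = 4.0
    functional_form: str = "gaussian-wells"

    def __post_init__(self) -> None:
        if len(self.well_centers) < 2:
            raise ValueError("need at least two wells")
        if len(self.well_depths) != len(self.well_centers):
            raise ValueError("one depth per well center")
        if len(self.barrier_heights) != len(self.well_centers) - 1:
            raise ValueError("one barrier between each pair of adjacent wells")
        if any(b <= 0 for b in self.barrier_heights):
            raise ValueError("barrier heights must be positive")
        if self.width <= 0 or self.x_wall <= 0:
            raise ValueError("width and x_wall must be positive")
        if list(self.well_centers) != sorted(self.well_centers):
            raise ValueError("well centers must be increasing")

    @property
    def barrier_centers(self) -> np.ndarray:
        c = np.asarray(self.well_centers, dtype=float)
        return 0.5 * (c[:-1] + c[1:])

    def energy(self, x):
        """Potential energy U(x) in kT; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        c = np.asarray(self.well_centers)[:, None]
        d = np.asarray(self.well_depths)[:, None]
        m = self.barrier_centers[:, None]
        b = np.asarray(self.barrier_heights)[:, None]
        two_w2 = 2.0 * self.width**2
        xs = np.atleast_1d(x)
        u = (
            -(d * np.exp(-((xs - c) ** 2) / two_w2)).sum(axis=0)
            + (b * np.exp(-((xs - m) ** 2) / two_w2)).sum(axis=0)
            + (xs / self.x_wall) ** 10
        )
        return u if x.ndim else float(u[0])

    def gradient(self, x):
        """dU/dx, analytic."""
        x = np.asarray(x, dtype=float)
        c = np.asarray(self.well_centers)[:, None]
        d = np.asarray(self.well_depths)[:, None]
        m = self.barrier_centers[:, None]
        b = np.asarray(self.barrier_heights)[:, None]
        w2 = self.width**2
        xs = np.atleast_1d(x)
        g = (
            (d * (xs - c) / w2 * np.exp(-((xs - c) ** 2) / (2 * w2))).sum(axis=0)
            - (b * (xs - m) / w2 * np.exp(-((xs - m) ** 2) / (2 * w2))).sum(axis=0)
            + 10.0 * xs**9 / self.x_wall**10
        )
        return g if x.ndim else float(g[0])


def four_well_potential(
    inner_barrier: float = 2.0, outer_barrier: float = 5.0, depth: float = 4.0
) -> PotentialSpec:
    """Symmetric four-well landscape with wells at x = -3, -1, 1, 3.

    ``outer_barrier`` controls the barriers that isolate the two terminal
    states (A at x=-3, D at x=+3); raising it makes direct end-to-end
    transitions rare, the hallmark regime of the four-state benchmark.
    """
    return PotentialSpec(
        well_depths=(depth,) * 4,
        barrier_heights=(outer_barrier, inner_barrier, outer_barrier),
    )


@dataclass(frozen=True)
class LangevinParams:
    """Euler–Maruyama integration settings (dimensionless units, kT-scaled)."""

    timestep: float = 0.005
    kT: float = 1.0
    n_steps: int = 100_000
    x0: float = -3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.kT < 0:
            raise ValueError("kT must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass(frozen=True)
class MarkovChainSpec:
    """A discrete-time Markov chain given by per-step transition probabilities."""

    transition_matrix: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1] or T.shape[0] < 2:
            raise ValueError("transition matrix must be square, K >= 2")
        if (T < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows must sum to 1 within 1e-12")
        object.__setattr__(self, "transition_matrix", T)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass
class StateTrajectory:
    """A sequence of integer state labels, possibly concatenated from
    several source trajectories.

    ``boundaries`` holds the start index of every source trajectory after
    the first, i.e. index i in boundaries means frames [.., i-1] and
    [i, ..] belong to different source trajectories.  ``frame_interval``
    is the physical time per frame in arbitrary units.
    """

    states: np.ndarray
    boundaries: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    frame_interval: float = 1.0
    n_states: int | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.boundaries = np.asarray(self.boundaries, dtype=np.int64)
        if self.states.ndim != 1 or self.states.size < 1:
            raise ValueError("states must be a non-empty 1-D sequence")
        if (self.states < 0).any():
            raise ValueError("state labels must be non-negative")
        if self.boundaries.size:
            if (np.diff(self.boundaries) <= 0).any():
                raise ValueError("boundaries must be strictly increasing")
            if self.boundaries[0] <= 0 or self.boundaries[-1] >= self.states.size:
                raise ValueError("boundaries must lie strictly inside the sequence")
        k = int(self.states.max()) + 1
        if self.n_states is None:
            self.n_states = k
        elif self.n_states < k:
            raise ValueError(f"labels up to {k - 1} exceed n_states={self.n_states}")

    def __len__(self) -> int:
        return self.states.size

    def segments(self) -> list[np.ndarray]:
        """Split back into the source trajectories."""
        return np.split(self.states, self.boundaries)

    @staticmethod
    def concatenate(trajs: list["StateTrajectory"]) -> "StateTrajectory":
        """Append trajectories one after another, recording the joins."""
        if not trajs:
            raise ValueError("nothing to concatenate")
        parts, bounds, offset = [], [], 0
        for t in trajs:
            for seg in t.segments():
                if offset:
                    bounds.append(offset)
                parts.append(seg)
                offset += seg.size
        return StateTrajectory(
            np.concatenate(parts),
            np.asarray(bounds, dtype=int),
            frame_interval=trajs[0].frame_interval,
            n_states=max(t.n_states for t in trajs),
        )


def simulate_langevin(potential: PotentialSpec, params: LangevinParams) -> np.ndarray:
    """Integrate overdamped Langevin dynamics x <- x - U'(x) dt + sqrt(2 kT dt) xi.

    Returns the n_steps visited positions (x0 evolves before being recorded,
    so the trajectory samples the stationary law rather than the start point
    for long runs).  Identical seeds give identical trajectories.
    """
    import math

    dt, kT, n = params.timestep, params.kT, params.n_steps
    rng = np.random.default_rng(params.seed)
    noise = (rng.standard_normal(n) * np.sqrt(2.0 * kT * dt)).tolist()
    if not isinstance(potential, PotentialSpec):
        # any object exposing gradient(x) works (e.g. a harmonic well)
        grad = potential.gradient
        xs = np.empty(n)
        x = float(params.x0)
        for i in range(n):
            g = float(grad(x))
            if not math.isfinite(g):
                raise FloatingPointError(f"non-finite potential gradient at x={x!r}")
            x = x - g * dt + noise[i]
            xs[i] = x
        return xs
    # scalar closure over plain floats: ~10x faster than per-step ndarray math
    gauss = [
        (float(c), float(d))
        for c, d in zip(potential.well_centers, potential.well_depths)
    ] + [(float(m), -float(b)) for m, b in zip(potential.barrier_centers,
                                              potential.barrier_heights)]
    inv_w2 = 1.0 / potential.width**2
    wall = 10.0 / potential.x_wall**10
    xs = np.empty(n)
    x = float(params.x0)
    for i in range(n):
        g = wall * x**9
        for c, d in gauss:
            dx = x - c
            g += d * dx * inv_w2 * math.exp(-0.5 * dx * dx * inv_w2)
        if not math.isfinite(g):
            raise FloatingPointError(f"non-finite potential gradient at x={x!r}")
        x = x - g * dt + noise[i]
        xs[i] = x
    return xs


def map_to_states(xs: np.ndarray, centers) -> StateTrajectory:
    """Assign each frame to the nearest of K predefined state centers.

    Ties are broken in favour of the lowest center index.
    """
    xs = np.asarray(xs, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if xs.size == 0:
        raise ValueError("empty trajectory")
    if centers.size < 2 or np.unique(centers).size != centers.size:
        raise ValueError("need >= 2 distinct centers")
    d = np.abs(xs[:, None] - centers[None, :])
    labels = np.argmin(d, axis=1)  # argmin returns the first (lowest) index on ties
    return StateTrajectory(labels, n_states=centers.size)


def sample_markov_chain(
    spec: MarkovChainSpec, length: int, start_state: int = 0
) -> StateTrajectory:
    """Draw a trajectory from the chain; first frame is ``start_state``."""
    T = spec.transition_matrix
    K = spec.n_states
    if not 0 <= start_state < K:
        raise ValueError("start_state out of range")
    if length < 1:
        raise ValueError("length must be >= 1")
    if (T.sum(axis=1) == 0).any():
        raise ValueError("row with all-zero mass")
    rng = np.random.default_rng(spec.seed)
    # inverse-CDF sampling against a single uniform stream keeps the draw
    # seed-deterministic and fast
    cum = np.cumsum(T, axis=1)
    us = rng.random(length - 1)
    states = np.empty(length, dtype=np.int64)
    states[0] = start_state
    s = start_state
    for i in range(length - 1):
        s = int(np.searchsorted(cum[s], us[i], side="right"))
        s = min(s, K - 1)  # guard against u == 1.0 edge
        states[i + 1] = s
    return StateTrajectory(states, n_states=K)


def boltzmann_state_weights(
    potential: PotentialSpec, centers, kT: float = 1.0
) -> np.ndarray:
    """Boltzmann weight of each state by numerical quadrature over its
    Voronoi cell: pi_i = Z^-1 int_cell exp(-U(x)/kT) dx.

    This is the continuous-space ground truth against which discretized
    Langevin populations are compared.
    """
    centers = np.asarray(centers, dtype=float)
    edges = np.concatenate(
        [[-np.inf], 0.5 * (centers[:-1] + centers[1:]), [np.inf]]
    )
    lo = min(centers.min() - 6.0, -2.0 * potential.x_wall)
    hi = max(centers.max() + 6.0, 2.0 * potential.x_wall)
    w = np.empty(centers.size)
    for i in range(centers.size):
        a = max(edges[i], lo)
        b = min(edges[i + 1], hi)
        w[i], _ = quad(lambda x: np.exp(-potential.energy(x) / kT), a, b, limit=200)
    return w / w.sum()
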