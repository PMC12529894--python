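"""State-space discretization and training-window construction.

Continuous feature trajectories are reduced to discrete conformational
states by k-center clustering (farthest-first traversal, the standard
2-approximation to the optimal epsilon-cover), and discrete state
sequences are cut into fixed-length overlapping windows, shuffled for
training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .systems import StateTrajectory

__all__ = ["ClusterModel", "WindowDataset", "k_center_cluster", "assign",
           "make_windows", "read_features_csv"]

MetricFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _euclidean(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    return np.sqrt(((points - center[None, :]) ** 2).sum(axis=1))


_METRICS: dict[str, MetricFn] = {"euclidean": _euclidean}


def _resolve_metric(metric) -> tuple[str, MetricFn]:
    """A metric is either a registered tag or a callable d(points, center)
    returning the distance of every point to one center (RMSD-like metrics
    plug in here)."""
    if callable(metric):
        return getattr(metric, "__name__", "custom"), metric
    try:
        return metric, _METRICS[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None


@dataclass
class ClusterModel:
    """K cluster centers plus the realized cover radius.

    ``cover_radius`` is the maximum distance of any training point to its
    nearest center; farthest-first traversal guarantees it is at most twice
    the optimal k-center radius on the same points.
    """

    centers: np.ndarray
    metric: str = "euclidean"
    cover_radius: float = 0.0
    _metric_fn: MetricFn | None = None

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def metric_fn(self) -> MetricFn:
        if self._metric_fn is None:
            _, self._metric_fn = _resolve_metric(self.metric)
        return self._metric_fn

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# k-center model; metric={self.metric}; "
                     f"cover_radius={self.cover_radius!r}\n")
            pd.DataFrame(self.centers).to_csv(fh, index=False, header=False)

    @classmethod
    def from_csv(cls, path) -> "ClusterModel":
        with open(path) as fh:
            header = fh.readline()
            centers = pd.read_csv(fh, header=None).to_numpy(dtype=float)
        fields = dict(
            kv.strip().split("=") for kv in header.lstrip("#").split(";")[1:]
        )
        return cls(centers, metric=fields["metric"],
                   cover_radius=float(fields["cover_radius"]))


def k_center_cluster(points, k: int, metric="euclidean", seed: int = 0) -> ClusterModel:
    """Gonzalez farthest-first k-center clustering.

    The first center is a seeded uniform draw from the points; each
    subsequent center is the point farthest from the current center set.
    Centers are always a subset of the input points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n == 0:
        raise ValueError("no points")
    if not np.isfinite(pts).all():
        raise ValueError("non-finite coordinates")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    tag, dist = _resolve_metric(metric)
    rng = np.random.default_rng(seed)
    idx = [int(rng.integers(n))]
    d_near = dist(pts, pts[idx[0]])
    for _ in range(1, k):
        far = int(np.argmax(d_near))
        idx.append(far)
        d_near = np.minimum(d_near, dist(pts, pts[far]))
    model = ClusterModel(pts[idx].copy(), metric=tag,
                         cover_radius=float(d_near.max()), _metric_fn=dist)
    return model


def assign(points, model: ClusterModel) -> StateTrajectory:
    """Nearest-center labels (ties to the lowest center index)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[1] != model.centers.shape[1]:
        raise ValueError(
            f"dimensionality mismatch: points are {pts.shape[1]}-D, "
            f"centers are {model.centers.shape[1]}-D"
        )
    dist = model.metric_fn()
    d = np.column_stack([dist(pts, c) for c in model.centers])
    return StateTrajectory(np.argmin(d, axis=1), n_states=model.k)


@dataclass
class WindowDataset:
    """Fixed-length overlapping windows over concatenated state sequences,
    in seed-shuffled order."""

    windows: np.ndarray  # (n_windows, window_length) int array
    window_length: int
    stride: int
    shuffle_seed: int
    span_boundaries: bool
    n_states: int

    def __len__(self) -> int:
        return self.windows.shape[0]


def make_windows(
    trajs: list[StateTrajectory] | StateTrajectory,
    window_length: int = 50,
    stride: int = 1,
    shuffle_seed: int = 0,
    span_boundaries: bool = True,
) -> WindowDataset:
    """Enumerate sliding windows over the concatenation of ``trajs``.

    With ``span_boundaries`` (default) windows may cross the joins between
    source trajectories — the sequences are appended with no separator
    token, and shuffling is relied upon to keep the model from learning the
    artificial continuity.  With ``span_boundaries=False`` windows are
    enumerated within each source trajectory only.
    """
    if isinstance(trajs, StateTrajectory):
        trajs = [trajs]
    cat = StateTrajectory.concatenate(trajs)
    if window_length < 1 or stride < 1:
        raise ValueError("window_length and stride must be >= 1")
    seq = cat.states
    if span_boundaries:
        segs = [seq]
    else:
        segs = cat.segments()
    wins = []
    for s in segs:
        n = s.size - window_length + 1
        if n > 0:
            sw = np.lib.stride_tricks.sliding_window_view(s, window_length)
            wins.append(sw[::stride])
    if not wins:
        raise ValueError(
            f"window_length {window_length} exceeds every available sequence"
        )
    windows = np.concatenate(wins, axis=0)
    order = np.random.default_rng(shuffle_seed).permutation(windows.shape[0])
    return WindowDataset(
        windows=windows[order].copy(),
        window_length=window_length,
        stride=stride,
        shuffle_seed=shuffle_seed,
        span_boundaries=span_boundaries,
        n_states=cat.n_states,
    )


def read_features_csv(path, traj_id_column: str | None = None):
    """Read a frames-by-features CSV.  Returns (points, boundaries); if
    ``traj_id_column`` is given, boundaries mark where its value changes."""
    df = pd.read_csv(path)
    boundaries = np.array([], dtype=int)
    if traj_id_column is not None:
        ids = df.pop(traj_id_column).to_numpy()
        boundaries = np.flatnonzero(ids[1:] != ids[:-1]) + 1
    return df.to_numpy(dtype=float), boundaries
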