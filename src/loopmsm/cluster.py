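"""K-medoids (PAM) microstate clustering in tICA space.

Distances are Euclidean in the retained tICA components.  Seeding is
k-means++-style over candidate medoids with an explicit RNG seed, then
PAM alternation: assign every point to its nearest medoid (ties broken
by the lowest medoid index), then move each medoid to the member that
minimizes the summed distance to its cluster.  Deterministic given
(data, k, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .tica import ProjectedData

DEFAULT_SEED = 2018
MAX_SWEEPS = 100


@dataclass
class Clustering:
    """Fitted k-medoids microstates."""

    k: int
    medoid_points: np.ndarray       # (k, d)
    medoid_ids: list                # [(trajectory, frame)] per medoid
    labels: list                    # per-trajectory integer label arrays
    total_cost: float               # summed member->medoid Euclidean distance
    seed: int
    n_sweeps: int
    converged: bool

    def labels_flat(self) -> np.ndarray:
        return np.concatenate(self.labels)


def _stack(projected):
    if isinstance(projected, ProjectedData):
        x = projected.stacked()
        ids = [(t, f) for t, arr in enumerate(projected.data)
               for f in range(arr.shape[0])]
        lengths = projected.n_frames
    else:
        x = np.asarray(projected, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
        ids = [(0, f) for f in range(x.shape[0])]
        lengths = [x.shape[0]]
    return x, ids, lengths


def _plus_plus_seed(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    medoids = np.empty(k, dtype=int)
    medoids[0] = rng.integers(n)
    d2 = np.sum((x - x[medoids[0]]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a medoid; pick uniformly
            medoids[i] = rng.integers(n)
        else:
            medoids[i] = rng.choice(n, p=d2 / total)
        d2 = np.minimum(d2, np.sum((x - x[medoids[i]]) ** 2, axis=1))
    return medoids


def _medoid_of(members: np.ndarray, x: np.ndarray) -> int:
    """Index (into x) of the member minimizing summed distance; earliest wins ties."""
    pts = x[members]
    d = cdist(pts, pts)
    sums = d.sum(axis=1)
    return int(members[np.argmin(sums)])


def kmedoids(projected, k: int, seed: int = DEFAULT_SEED,
             max_sweeps: int = MAX_SWEEPS) -> Clustering:
    """PAM k-medoids clustering of projected frames."""
    x, ids, lengths = _stack(projected)
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of frames n={n}")
    rng = np.random.default_rng(seed)
    medoids = _plus_plus_seed(x, k, rng)
    # canonical order so labels are stable across equivalent seedings
    medoids = np.sort(medoids)

    labels = None
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        d = cdist(x, x[medoids])
        new_labels = np.argmin(d, axis=1)         # first-occurrence tie-break
        if labels is not None and np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size:
                new_medoids[c] = _medoid_of(members, x)
        if np.array_equal(new_medoids, medoids):
            converged = True
            break
        medoids = new_medoids

    d = cdist(x, x[medoids])
    labels = np.argmin(d, axis=1)
    cost = float(d[np.arange(n), labels].sum())

    per_traj = []
    start = 0
    for ln in lengths:
        per_traj.append(labels[start:start + ln].astype(np.int64))
        start += ln
    return Clustering(
        k=k,
        medoid_points=x[medoids].copy(),
        medoid_ids=[ids[m] for m in medoids],
        labels=per_traj,
        total_cost=cost,
        seed=seed,
        n_sweeps=sweeps,
        converged=converged,
    )


def assign(clustering: Clustering, points) -> list:
    """Nearest-medoid labels for new points (lowest-index medoid on ties).

    Returns per-trajectory label arrays when given ProjectedData, else a
    single label array.
    """
    if isinstance(points, ProjectedData):
        return [assign(clustering, arr) for arr in points.data]
    x = np.asarray(points, dtype=np.float64)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    labels = np.argmin(cdist(x, clustering.medoid_points), axis=1).astype(np.int64)
    return labels[0] if squeeze else labels


def labels_to_dataframe(labels: list):
    """Label export: (trajectory, frame, microstate)."""
    import pandas as pd

    rows = []
    for t, arr in enumerate(labels):
        rows.append(pd.DataFrame({
            "trajectory": t,
            "frame": np.arange(len(arr)),
            "microstate": arr,
        }))
    return pd.concat(rows, ignore_index=True)
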