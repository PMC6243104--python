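"""PCCA+ coarse-graining of a microstate model into metastable macrostates.

The membership matrix is obtained with the inner-simplex algorithm on
the dominant right eigenvectors of the reversible microstate transition
matrix: the most spread-out eigenvector rows are taken as simplex
vertices, every microstate is expressed in barycentric coordinates of
those vertices, and negative coordinates are clipped and renormalized.
Crisp assignment is the row argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist

from .errors import EstimationError, NumericalError
from .msm import CountMatrix, MSMModel, mle_transition_matrix, count_transitions, \
    largest_connected_set

GAP_CONFIDENCE_RATIO = 2.0


@dataclass
class MacrostateCountChoice:
    m: int
    gap_ratio: float
    gap_index: int                  # gap after this many slow timescales
    confident: bool


def choose_macrostate_count(timescales, floor: float = 1.0) -> MacrostateCountChoice:
    """Pick m = 1 + (number of timescales before the largest relative gap).

    ``timescales`` is a descending array of implied timescales (frames or
    ns).  NaN entries (undefined processes) and anything below ``floor``
    — processes faster than the model can resolve, typically the lag —
    are clipped to ``floor`` so gaps among unresolved noise processes
    never outrank the metastable gap.  A largest gap below a factor of 2
    yields a low-confidence flag.
    """
    t = np.asarray(timescales, dtype=float)
    t = np.where(np.isfinite(t), t, floor)
    t = np.maximum(t, floor)
    if len(t) < 2:
        raise ValueError("need at least 2 timescales to find a spectral gap")
    ratios = t[:-1] / t[1:]
    g = int(np.argmax(ratios))
    ratio = float(ratios[g])
    return MacrostateCountChoice(
        m=g + 2,
        gap_ratio=ratio,
        gap_index=g + 1,
        confident=ratio >= GAP_CONFIDENCE_RATIO,
    )


@dataclass
class MacrostateModel:
    """PCCA+ memberships plus the coarse kinetic model."""

    m: int
    memberships: np.ndarray         # (k_micro, m), rows sum to 1
    crisp_map: np.ndarray           # micro index -> macro label
    micro_model: MSMModel
    coarse_model: MSMModel | None = None
    coarse_pi_membership: np.ndarray | None = None  # chi^T pi_micro
    centroids: list = field(default_factory=list)   # per-macrostate (traj, frame)

    @property
    def metastability(self) -> float | None:
        if self.coarse_model is None:
            return None
        return float(np.trace(self.coarse_model.transition_matrix))

    def jump_probabilities(self) -> np.ndarray | None:
        """Off-diagonal entries of the coarse transition matrix."""
        if self.coarse_model is None:
            return None
        t = self.coarse_model.transition_matrix.copy()
        np.fill_diagonal(t, 0.0)
        return t


def _right_eigenvectors(model: MSMModel, m: int):
    """First m right eigenvectors of a reversible T, via pi-symmetrization."""
    t = model.transition_matrix
    pi = model.stationary
    sq = np.sqrt(pi)
    s = (sq[:, None] * t) / sq[None, :]
    lam, phi = scipy.linalg.eigh(0.5 * (s + s.T))
    order = np.argsort(lam)[::-1]
    lam, phi = lam[order], phi[:, order]
    psi = phi / sq[:, None]
    # fix the stationary eigenvector to the constant 1 (skip if the
    # eigenvalue-1 eigenspace is degenerate and the entry is ~0)
    if abs(psi[0, 0]) > 1e-12:
        psi[:, 0] = psi[:, 0] / psi[0, 0]
    return lam, psi[:, :m], lam[:m]


def pcca_plus(model: MSMModel, m: int) -> MacrostateModel:
    """Fuzzy partition of microstates into m metastable macrostates."""
    if not model.reversible:
        raise EstimationError("PCCA+ requires a reversible microstate model")
    k = model.n_states
    if m < 2 or m > k:
        raise ValueError(f"m={m} must be in [2, n_states={k}]")
    lam_all, psi, lam = _right_eigenvectors(model, m)
    if lam[-1] <= 0:
        raise ValueError(
            f"m={m} exceeds the positive part of the spectrum "
            f"(eigenvalue {lam[-1]:.3g})"
        )
    if m < k and abs(lam_all[m - 1] - lam_all[m]) < 1e-10:
        raise NumericalError(
            f"degenerate eigenvalues at the spectral cut (lambda_{m}≈lambda_{m+1}); "
            "choose a different number of macrostates"
        )

    # inner simplex vertex search: maximally spread rows of psi
    vertices = np.zeros(m, dtype=int)
    work = psi.copy()
    vertices[0] = int(np.argmax(np.linalg.norm(work - work.mean(axis=0), axis=1)))
    work = work - work[vertices[0]]
    for j in range(1, m):
        norms = np.linalg.norm(work, axis=1)
        vertices[j] = int(np.argmax(norms))
        v = work[vertices[j]]
        nv = norms[vertices[j]]
        if nv == 0:
            raise NumericalError("degenerate eigenvector geometry in PCCA+")
        work = work - np.outer(work @ v, v) / nv**2

    a = np.linalg.inv(psi[vertices])
    chi = psi @ a
    chi = np.clip(chi, 0.0, None)
    rows = chi.sum(axis=1)
    if np.any(rows <= 0):
        raise NumericalError("PCCA+ produced an all-zero membership row")
    chi = chi / rows[:, None]
    crisp = np.argmax(chi, axis=1)

    # relabel macrostates by first microstate occurrence for determinism
    order = []
    for c in crisp:
        if c not in order:
            order.append(int(c))
    for c in range(m):
        if c not in order:
            order.append(c)
    perm = np.argsort(np.array(order))  # old label -> new label
    chi = chi[:, np.array(order)]
    crisp = perm[crisp]

    if len(np.unique(crisp)) < m:
        raise EstimationError(
            f"PCCA+ crisp assignment left an empty macrostate (m={m}); "
            "choose a different m"
        )
    return MacrostateModel(m=m, memberships=chi, crisp_map=crisp, micro_model=model)


def map_micro_labels(
    micro_labels, crisp_map: np.ndarray, active_states: np.ndarray
) -> list:
    """Map microstate label sequences to macrostate sequences.

    Frames whose microstate was ergodically trimmed map to -1 and are
    skipped by transition counting.
    """
    n_all = int(max(int(np.max(s)) for s in micro_labels if len(s))) + 1
    n_all = max(n_all, int(active_states.max()) + 1)
    lookup = np.full(n_all, -1, dtype=np.int64)
    lookup[active_states] = crisp_map
    return [lookup[np.asarray(s)] for s in micro_labels]


def macrostate_msm(
    macro: MacrostateModel,
    micro_labels,
    lag: int,
    frame_interval: float = 1.0,
    reversible: bool = True,
) -> MacrostateModel:
    """Estimate the coarse transition matrix at the macro lag (frames).

    Fills ``coarse_model`` (MLE on mapped macro label sequences) and the
    membership-weighted population estimate chi^T pi_micro.
    """
    seqs = map_micro_labels(micro_labels, macro.crisp_map,
                            macro.micro_model.active_states)
    cm = count_transitions(seqs, lag, n_states=macro.m)
    _, trimmed = largest_connected_set(cm)
    if trimmed.n_states < macro.m:
        raise EstimationError(
            "macrostate chain is not connected at the chosen macro lag"
        )
    coarse = mle_transition_matrix(trimmed, reversible=reversible,
                                   frame_interval=frame_interval)
    macro.coarse_model = coarse
    macro.coarse_pi_membership = macro.memberships.T @ macro.micro_model.stationary
    return macro


def cluster_centroid(points: np.ndarray, ids=None, max_members: int | None = None):
    """Member minimizing summed Euclidean distance to all other members.

    Ties break to the earliest (trajectory, frame) identity — with the
    default sequential ids, the lowest index.  ``max_members`` caps the
    exact O(n^2) scan by deterministic striding (candidates and
    reference set both strided), for large states.
    """
    x = np.asarray(points, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty member set")
    if ids is None:
        ids = list(range(n))
    if max_members is not None and n > max_members:
        stride = int(np.ceil(n / max_members))
        keep = np.arange(0, n, stride)
        sums = cdist(x[keep], x[keep]).sum(axis=1)
        best = keep[int(np.argmin(sums))]
        return ids[best]
    sums = cdist(x, x).sum(axis=1)
    return ids[int(np.argmin(sums))]
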