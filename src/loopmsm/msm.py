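"""Microstate Markov model estimation.

Transition counting uses a sliding window (every frame is a window
start) strictly within trajectories.  The maximum-likelihood transition
matrix is row-normalized counts in the non-reversible case, and the
detailed-balance-constrained maximizer via the standard fixed-point
iteration in the reversible case (the default: equilibrium populations
from eigenvalue analysis presuppose a real spectrum).  Counts are
restricted to the largest strongly connected set before estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg

from .errors import EstimationError, NumericalError

logger = logging.getLogger(__name__)

REV_TOL = 1e-12
REV_MAX_ITER = 1_000_000


@dataclass
class CountMatrix:
    """Lagged transition counts over microstate labels."""

    counts: np.ndarray              # (k, k) nonnegative
    lag_frames: int
    lag_ns: float
    n_states: int
    states: np.ndarray = None       # original state ids of rows (after trimming)

    def __post_init__(self):
        if self.states is None:
            self.states = np.arange(self.n_states)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class MSMModel:
    """Estimated Markov state model at one lag."""

    lag_frames: int
    lag_ns: float
    transition_matrix: np.ndarray   # row-stochastic
    stationary: np.ndarray          # pi, sums to 1
    eigenvalues: np.ndarray         # sorted by descending modulus, real part kept
    active_states: np.ndarray       # original state ids (ergodic trimming)
    reversible: bool
    counts: CountMatrix | None = None

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def implied_timescales_frames(self, n_timescales: int | None = None) -> np.ndarray:
        """t_i = -tau/ln(lambda_i) for the non-stationary eigenvalues.

        Non-positive eigenvalues yield NaN (flagged undefined, not fatal).
        """
        lam = self.eigenvalues[1:]
        if n_timescales is not None:
            lam = lam[:n_timescales]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -self.lag_frames / np.log(np.abs(lam))
        t = np.where(lam > 0, t, np.nan)
        t = np.where(np.abs(lam) >= 1, np.nan, t)
        return t


def _label_list(labels):
    if isinstance(labels, np.ndarray) and labels.ndim == 1:
        return [labels]
    return list(labels)


def count_transitions(labels, lag: int, n_states: int | None = None) -> CountMatrix:
    """Sliding-window transition counts at the given lag (frames).

    Frames with negative labels (e.g. ergodically trimmed) break the
    window: pairs touching them are skipped.
    """
    seqs = _label_list(labels)
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    if n_states is None:
        n_states = int(max((s.max() for s in seqs if len(s)), default=-1)) + 1
    c = np.zeros((n_states, n_states), dtype=np.float64)
    any_pairs = False
    for s in seqs:
        s = np.asarray(s)
        if len(s) <= lag:
            continue
        a, b = s[:-lag], s[lag:]
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            any_pairs = True
            np.add.at(c, (a[ok], b[ok]), 1.0)
    if not any_pairs:
        raise EstimationError(f"no trajectory longer than lag={lag} frames")
    return CountMatrix(counts=c, lag_frames=lag, lag_ns=float(lag), n_states=n_states)


def largest_connected_set(cm: CountMatrix) -> tuple[np.ndarray, CountMatrix]:
    """Restrict counts to the largest strongly connected component.

    Returns (active original-state ids, trimmed CountMatrix).  The
    trimmed count fraction is logged.
    """
    c = cm.counts
    g = nx.DiGraph()
    g.add_nodes_from(np.flatnonzero(c.sum(axis=0) + c.sum(axis=1) > 0))
    rows, cols = np.nonzero(c)
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    if g.number_of_nodes() == 0:
        raise EstimationError("count matrix is empty")
    comps = list(nx.strongly_connected_components(g))
    # largest by size, ties by total counts, then lowest state id
    def score(comp):
        idx = np.array(sorted(comp))
        return (len(comp), c[np.ix_(idx, idx)].sum(), -idx[0])
    best = max(comps, key=score)
    active = np.array(sorted(best), dtype=int)
    sub = c[np.ix_(active, active)].copy()
    lost = 1.0 - sub.sum() / max(c.sum(), 1.0)
    if lost > 0:
        logger.info("ergodic trimming removed %.2f%% of transition counts", 100 * lost)
    trimmed = CountMatrix(
        counts=sub,
        lag_frames=cm.lag_frames,
        lag_ns=cm.lag_ns,
        n_states=len(active),
        states=cm.states[active],
    )
    return trimmed.states, trimmed


def _reversible_mle(c: np.ndarray, tol: float = REV_TOL,
                    max_iter: int = REV_MAX_ITER) -> np.ndarray:
    """Detailed-balance-constrained MLE via the standard fixed-point.

    Iterates x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j) on the symmetric
    unnormalized flux matrix x, starting from c + c^T.
    """
    csym = c + c.T
    c_row = c.sum(axis=1)
    x = csym / max(csym.sum(), 1.0)
    for it in range(max_iter):
        x_row = x.sum(axis=1)
        q = c_row / x_row
        x_new = csym / (q[:, None] + q[None, :])
        x_new /= x_new.sum()
        delta = np.max(np.abs(x_new - x))
        x = x_new
        if delta < tol:
            break
    else:
        raise NumericalError(
            f"reversible MLE did not converge in {max_iter} iterations "
            f"(residual {delta:.3e})"
        )
    t = x / x.sum(axis=1)[:, None]
    return t


def _eig_sorted(t: np.ndarray, reversible: bool):
    if reversible:
        # symmetrize with pi for a guaranteed-real spectrum
        pi = stationary_from_matrix(t)
        sq = np.sqrt(pi)
        s = (sq[:, None] * t) / sq[None, :]
        lam = scipy.linalg.eigvalsh(0.5 * (s + s.T))
        lam = lam[np.argsort(np.abs(lam))[::-1]]
        return lam
    lam = scipy.linalg.eigvals(t)
    if np.max(np.abs(lam.imag)) > 1e-10:
        logger.warning("complex eigenvalues in non-reversible model; reporting moduli")
    order = np.argsort(np.abs(lam))[::-1]
    return np.abs(lam[order]) * np.sign(lam[order].real)


def stationary_from_matrix(t: np.ndarray) -> np.ndarray:
    """Left eigenvector of T at eigenvalue 1, normalized to sum 1."""
    lam, vec = scipy.linalg.eig(t.T)
    close = np.flatnonzero(np.abs(lam - 1.0) < 1e-8)
    if close.size == 0:
        raise NumericalError("no eigenvalue 1 found; T is not stochastic?")
    if close.size > 1:
        raise EstimationError(
            "eigenvalue 1 has multiplicity > 1: transition matrix is reducible"
        )
    v = vec[:, close[0]].real
    v = np.abs(v)
    return v / v.sum()


def mle_transition_matrix(
    cm: CountMatrix,
    reversible: bool = True,
    frame_interval: float = 1.0,
) -> MSMModel:
    """Maximum-likelihood transition matrix from (irreducible) counts."""
    c = cm.counts
    if np.any(c.sum(axis=1) == 0):
        raise EstimationError("a retained row has zero counts; trim first")
    if reversible:
        t = _reversible_mle(c)
    else:
        t = c / c.sum(axis=1)[:, None]
    pi = stationary_from_matrix(t)
    lam = _eig_sorted(t, reversible)
    return MSMModel(
        lag_frames=cm.lag_frames,
        lag_ns=cm.lag_frames * frame_interval,
        transition_matrix=t,
        stationary=pi,
        eigenvalues=lam,
        active_states=cm.states.copy(),
        reversible=reversible,
        counts=cm,
    )


def model_from_transition_matrix(
    t: np.ndarray,
    lag_frames: int = 1,
    frame_interval: float = 1.0,
    reversible: bool = True,
    pi: np.ndarray | None = None,
) -> MSMModel:
    """Wrap a given row-stochastic matrix as an MSMModel.

    For a reducible T (eigenvalue-1 multiplicity > 1, e.g. an exactly
    block-diagonal chain) the stationary distribution is not unique; the
    power-iteration limit from a uniform start is used, which weights
    each closed block by its share of initial mass.
    """
    t = np.asarray(t, dtype=np.float64)
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("rows of T must sum to 1")
    if pi is None:
        try:
            pi = stationary_from_matrix(t)
        except EstimationError:
            p = np.full(t.shape[0], 1.0 / t.shape[0])
            m = t.copy()
            for _ in range(60):  # T^(2^60): far beyond any mixing time
                m = m @ m
                m /= m.sum(axis=1)[:, None]
            pi = p @ m
            pi = pi / pi.sum()
    pi = np.asarray(pi, dtype=np.float64)
    if reversible and np.all(pi > 0):
        sq = np.sqrt(pi)
        s = (sq[:, None] * t) / sq[None, :]
        lam = scipy.linalg.eigvalsh(0.5 * (s + s.T))
        lam = lam[np.argsort(np.abs(lam))[::-1]]
    else:
        lam = _eig_sorted(t, reversible=False)
    return MSMModel(
        lag_frames=lag_frames,
        lag_ns=lag_frames * frame_interval,
        transition_matrix=t,
        stationary=np.asarray(pi, dtype=np.float64),
        eigenvalues=lam,
        active_states=np.arange(t.shape[0]),
        reversible=reversible,
    )


def estimate_msm(
    labels,
    lag: int,
    reversible: bool = True,
    frame_interval: float = 1.0,
    n_states: int | None = None,
) -> MSMModel:
    """Count, trim to the largest connected set, and estimate the MLE model."""
    cm = count_transitions(labels, lag, n_states=n_states)
    _, trimmed = largest_connected_set(cm)
    return mle_transition_matrix(trimmed, reversible=reversible,
                                 frame_interval=frame_interval)


def stationary_distribution(model: MSMModel) -> np.ndarray:
    """Equilibrium populations by eigenvalue analysis of T."""
    return stationary_from_matrix(model.transition_matrix)


@dataclass
class ITSTable:
    """Implied timescales across a lag grid."""

    lags_frames: np.ndarray
    timescales_frames: np.ndarray   # (n_lags, n_timescales), NaN = undefined
    frame_interval: float
    n_timescales: int
    models: list = field(default_factory=list, repr=False)

    @property
    def lags_ns(self) -> np.ndarray:
        return self.lags_frames * self.frame_interval

    @property
    def timescales_ns(self) -> np.ndarray:
        return self.timescales_frames * self.frame_interval

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, lag in enumerate(self.lags_frames):
            for j in range(self.n_timescales):
                t = self.timescales_frames[i, j]
                rows.append({
                    "lag_frames": int(lag),
                    "lag_ns": lag * self.frame_interval,
                    "timescale_index": j + 1,
                    "timescale_ns": t * self.frame_interval if np.isfinite(t) else np.nan,
                    "defined": bool(np.isfinite(t)),
                })
        return pd.DataFrame(rows)


def implied_timescales(
    labels,
    lags,
    n_timescales: int = 3,
    reversible: bool = True,
    frame_interval: float = 1.0,
) -> ITSTable:
    """Implied timescales t_i(tau) = -tau/ln(lambda_i) across lags."""
    lags = np.asarray(sorted(int(l) for l in lags))
    table = np.full((len(lags), n_timescales), np.nan)
    models = []
    for i, lag in enumerate(lags):
        model = estimate_msm(labels, int(lag), reversible=reversible,
                             frame_interval=frame_interval)
        its = model.implied_timescales_frames(n_timescales)
        table[i, :len(its)] = its
        models.append(model)
    return ITSTable(
        lags_frames=lags,
        timescales_frames=table,
        frame_interval=frame_interval,
        n_timescales=n_timescales,
        models=models,
    )


@dataclass
class LagSelection:
    converged: bool
    lag_frames: int | None
    lag_ns: float | None
    status: str


def select_lag(its: ITSTable, tolerance: float = 0.10,
               n_slowest: int = 3) -> LagSelection:
    """Smallest lag after which the slowest timescales are stable.

    Convergence at lag index i means: for every successive lag pair from
    i onward, each of the ``n_slowest`` defined timescales changes by
    less than ``tolerance`` (relative).  Undefined (NaN) entries count as
    not converged.  Non-convergence is a reported status, not an error.
    """
    if len(its.lags_frames) < 3:
        raise ValueError("need at least 3 lags to assess convergence")
    t = its.timescales_frames[:, :n_slowest]
    n_lags = t.shape[0]
    rel = np.full((n_lags - 1, t.shape[1]), np.inf)
    for i in range(n_lags - 1):
        a, b = t[i], t[i + 1]
        ok = np.isfinite(a) & np.isfinite(b) & (a > 0)
        rel[i, ok] = np.abs(b[ok] - a[ok]) / a[ok]
    stable = np.all(rel < tolerance, axis=1)
    for i in range(n_lags - 1):
        if stable[i:].all():
            lag = int(its.lags_frames[i])
            return LagSelection(
                converged=True,
                lag_frames=lag,
                lag_ns=lag * its.frame_interval,
                status=f"converged at lag {lag} frames (tolerance {tolerance})",
            )
    return LagSelection(
        converged=False, lag_frames=None, lag_ns=None,
        status="not converged: slowest timescales do not stabilize over the lag grid",
    )
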