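"""Time-lagged independent component analysis (tICA).

Estimates the generalized eigenproblem C_tau v = lambda C0 v from
mean-centered instantaneous and time-lagged covariances, accumulated
over sliding (t, t+tau) pairs strictly within trajectory boundaries.
C_tau is symmetrized and C0 receives a small diagonal shrinkage so the
spectrum is real and the problem well-posed; both steps are standard
estimator hygiene rather than data-derived choices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import EstimationError, NumericalError, ProjectionError
from .featurize import FeatureMatrix

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 16
DEFAULT_SHRINKAGE = 1e-6


@dataclass
class TICAModel:
    """Fitted tICA decomposition.

    ``eigenvectors`` columns are C0-orthonormal (v^T C0 v = 1), sorted by
    descending eigenvalue; projecting data is ``(x - mean) @ eigenvectors``.
    """

    lag_ns: float
    lag_frames: int
    mean: np.ndarray
    c0: np.ndarray                  # instantaneous covariance, after shrinkage
    ctau: np.ndarray                # symmetrized time-lagged covariance
    eigenvalues: np.ndarray         # descending
    eigenvectors: np.ndarray        # (n_features, n_features) columns
    n_components: int
    feature_names: list

    @property
    def timescales_frames(self) -> np.ndarray:
        """Implied timescales -tau/ln(lambda) for eigenvalues in (0, 1)."""
        lam = self.eigenvalues
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -self.lag_frames / np.log(lam)
        t[(lam <= 0) | (lam >= 1)] = np.nan
        return t

    def cumulative_eigenvalue_fraction(self) -> np.ndarray:
        lam = np.clip(self.eigenvalues, 0.0, None)
        tot = lam.sum()
        return np.cumsum(lam) / tot if tot > 0 else np.zeros_like(lam)

    def save(self, path: str) -> None:
        """Archive mean, covariances, eigenpairs, lag, feature names (npz)."""
        np.savez(
            path,
            lag_ns=self.lag_ns,
            lag_frames=self.lag_frames,
            mean=self.mean,
            c0=self.c0,
            ctau=self.ctau,
            eigenvalues=self.eigenvalues,
            eigenvectors=self.eigenvectors,
            n_components=self.n_components,
            feature_names=np.array(self.feature_names, dtype=str),
        )

    @classmethod
    def load(cls, path: str) -> "TICAModel":
        z = np.load(path)
        return cls(
            lag_ns=float(z["lag_ns"]),
            lag_frames=int(z["lag_frames"]),
            mean=z["mean"],
            c0=z["c0"],
            ctau=z["ctau"],
            eigenvalues=z["eigenvalues"],
            eigenvectors=z["eigenvectors"],
            n_components=int(z["n_components"]),
            feature_names=z["feature_names"].tolist(),
        )


@dataclass
class ProjectedData:
    """Per-trajectory coordinates in tICA space."""

    data: list                      # per-trajectory (n_frames, k)
    n_components: int
    frame_interval: float
    lag_ns: float                   # provenance: the model's lag

    @property
    def n_frames(self) -> list:
        return [x.shape[0] for x in self.data]

    def stacked(self) -> np.ndarray:
        return np.concatenate(self.data, axis=0)


def lag_to_frames(lag_ns: float, frame_interval: float) -> int:
    """Convert a lag in ns to frames, warning when not exactly divisible."""
    exact = lag_ns / frame_interval
    frames = int(round(exact))
    if abs(exact - frames) > 1e-9:
        logger.warning(
            "lag %.4g ns is not a multiple of the frame interval %.4g ns; "
            "rounded to %d frames", lag_ns, frame_interval, frames,
        )
    if frames < 1:
        raise EstimationError(
            f"lag {lag_ns} ns is below one frame interval ({frame_interval} ns)"
        )
    return frames


def estimate_tica(
    features: FeatureMatrix,
    lag: float,
    frame_interval: float | None = None,
    n_components: int = DEFAULT_N_COMPONENTS,
    shrinkage: float = DEFAULT_SHRINKAGE,
) -> TICAModel:
    """Fit a tICA model at the given lag (ns).

    The mean and both covariances are estimated symmetrically over all
    sliding (t, t+tau) pairs within each trajectory; pairs never span a
    trajectory boundary.
    """
    dt = features.frame_interval if frame_interval is None else frame_interval
    tau = lag_to_frames(lag, dt)
    shortest = min(features.n_frames)
    if tau >= shortest:
        raise EstimationError(
            f"lag of {tau} frames >= shortest trajectory ({shortest} frames)"
        )

    d = features.n_features
    s = np.zeros(d)
    n_pairs = 0
    for x in features.data:
        a, b = x[:-tau], x[tau:]
        s += a.sum(axis=0) + b.sum(axis=0)
        n_pairs += a.shape[0]
    mean = s / (2 * n_pairs)

    c0 = np.zeros((d, d))
    ctau = np.zeros((d, d))
    for x in features.data:
        a = x[:-tau] - mean
        b = x[tau:] - mean
        c0 += a.T @ a + b.T @ b
        ctau += a.T @ b
    c0 /= 2 * n_pairs
    ctau /= n_pairs
    ctau = 0.5 * (ctau + ctau.T)

    delta = shrinkage * np.trace(c0) / d
    c0_reg = c0 + delta * np.eye(d)

    try:
        lam, vec = scipy.linalg.eigh(ctau, c0_reg)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"singular C0 after regularization: {exc}") from exc
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]

    k = min(n_components, d)
    return TICAModel(
        lag_ns=float(lag),
        lag_frames=tau,
        mean=mean,
        c0=c0_reg,
        ctau=ctau,
        eigenvalues=lam,
        eigenvectors=vec,
        n_components=k,
        feature_names=list(features.feature_names),
    )


def project(
    model: TICAModel, features: FeatureMatrix, k: int | None = None
) -> ProjectedData:
    """Project trajectory features onto the first k tICA components."""
    k = model.n_components if k is None else k
    if k > model.eigenvectors.shape[1]:
        raise ProjectionError(f"k={k} exceeds available components")
    if features.n_features != len(model.feature_names):
        raise ProjectionError(
            f"feature dimension {features.n_features} does not match model "
            f"({len(model.feature_names)})"
        )
    w = model.eigenvectors[:, :k]
    return ProjectedData(
        data=[(x - model.mean) @ w for x in features.data],
        n_components=k,
        frame_interval=features.frame_interval,
        lag_ns=model.lag_ns,
    )


def project_external(
    model: TICAModel, features, k: int | None = None
) -> np.ndarray:
    """Project an external conformation's feature vector(s) onto the model.

    ``features`` may be a FeatureMatrix (feature names are checked against
    the model) or a bare array of shape (n_features,) or (n, n_features).
    Returns an array of tICA coordinates, shape (n, k) or (k,).
    """
    k = model.n_components if k is None else k
    if isinstance(features, FeatureMatrix):
        if features.feature_names != model.feature_names:
            ours = set(model.feature_names)
            theirs = set(features.feature_names)
            raise ProjectionError(
                "external feature set does not match the model; missing="
                f"{sorted(ours - theirs)} extra={sorted(theirs - ours)}"
            )
        x = features.stacked()
    else:
        x = np.asarray(features, dtype=np.float64)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != len(model.feature_names):
        raise ProjectionError(
            f"feature dimension {x.shape[1]} does not match model "
            f"({len(model.feature_names)})"
        )
    y = (x - model.mean) @ model.eigenvectors[:, :k]
    return y[0] if squeeze else y
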