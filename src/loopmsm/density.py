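"""Kernel density estimates of projected data and mode detection.

Gaussian-kernel KDE with Scott's-Rule bandwidth (factor n^(-1/(d+4))
scaling the sample covariance), evaluated on a regular grid spanning the
data range plus a fixed number of bandwidths.  Local maxima of the grid
serve as the machine-checkable analogue of visually identified
metastable islands.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import gaussian_kde

from .errors import DegenerateDataError
from .tica import ProjectedData

DEFAULT_GRID_SIZE = 128
DEFAULT_PAD_BANDWIDTHS = 3.0
DEFAULT_MODE_PROMINENCE = 0.05


@dataclass
class DensityGrid:
    """KDE evaluated on a regular 1-D or 2-D grid."""

    axes: list                      # one array of grid-node coordinates per dim
    values: np.ndarray              # shape (n1,) or (n1, n2)
    bandwidth_factor: float         # Scott factor n^(-1/(d+4))
    bandwidth_cov: np.ndarray       # full kernel covariance (factor^2 * data cov)
    n_samples: int
    dims: tuple                     # which projected components were used

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def integral(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        if self.ndim == 1:
            return float(np.trapezoid(self.values, self.axes[0]))
        inner = np.trapezoid(self.values, self.axes[1], axis=1)
        return float(np.trapezoid(inner, self.axes[0]))

    def export(self, prefix: str) -> list:
        """Write the grid as plain-text matrix + axis files; return paths."""
        prefix = str(prefix)
        paths = []
        for i, ax in enumerate(self.axes):
            p = f"{prefix}.axis{i}.txt"
            np.savetxt(p, ax)
            paths.append(p)
        p = f"{prefix}.density.txt"
        np.savetxt(p, self.values)
        paths.append(p)
        return [str(Path(p)) for p in paths]


def _as_samples(projected, dims):
    if isinstance(projected, ProjectedData):
        x = projected.stacked()
    else:
        x = np.asarray(projected, dtype=np.float64)
        if x.ndim == 1:
            x = x[:, None]
    return x[:, list(dims)]


def kde(
    projected,
    dims=(0, 1),
    grid_size: int = DEFAULT_GRID_SIZE,
    pad_bandwidths: float = DEFAULT_PAD_BANDWIDTHS,
    stride: int = 1,
) -> DensityGrid:
    """Gaussian KDE of selected tICA components on a regular grid.

    ``stride`` subsamples frames before estimation (bandwidth then reflects
    the subsample size).  Deterministic given data and grid parameters.
    """
    dims = tuple(int(d) for d in (dims if np.iterable(dims) else (dims,)))
    x = _as_samples(projected, dims)[::stride]
    n, d = x.shape
    if n < 2:
        raise DegenerateDataError("KDE needs at least 2 samples")
    try:
        estimator = gaussian_kde(x.T, bw_method="scott")
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"singular data covariance: {exc}") from exc
    if not np.all(np.isfinite(estimator.covariance)):
        raise DegenerateDataError("non-finite kernel covariance")

    bw_sigma = np.sqrt(np.diag(estimator.covariance))
    axes = []
    for j in range(d):
        lo = x[:, j].min() - pad_bandwidths * bw_sigma[j]
        hi = x[:, j].max() + pad_bandwidths * bw_sigma[j]
        axes.append(np.linspace(lo, hi, grid_size))

    if d == 1:
        values = estimator(axes[0][None, :])
    else:
        gx, gy = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.vstack([gx.ravel(), gy.ravel()])
        values = estimator(pts).reshape(grid_size, grid_size)

    return DensityGrid(
        axes=axes,
        values=values,
        bandwidth_factor=float(estimator.factor),
        bandwidth_cov=np.atleast_2d(estimator.covariance).copy(),
        n_samples=n,
        dims=dims,
    )


def find_modes(
    grid: DensityGrid, min_prominence: float = DEFAULT_MODE_PROMINENCE
) -> list:
    """Strict local maxima of the density grid above a prominence floor.

    A node qualifies when its density strictly exceeds every neighbour
    (8-neighbourhood in 2-D, 2-neighbourhood in 1-D) and is at least
    ``min_prominence`` times the global maximum.  Returns a list of
    (coordinates tuple, density) sorted by descending density.
    """
    v = grid.values
    floor = min_prominence * v.max()
    modes = []
    if grid.ndim == 1:
        for i in range(len(v)):
            left = v[i - 1] if i > 0 else -np.inf
            right = v[i + 1] if i < len(v) - 1 else -np.inf
            if v[i] > left and v[i] > right and v[i] >= floor:
                modes.append(((float(grid.axes[0][i]),), float(v[i])))
    else:
        padded = np.full((v.shape[0] + 2, v.shape[1] + 2), -np.inf)
        padded[1:-1, 1:-1] = v
        center = padded[1:-1, 1:-1]
        is_max = np.ones_like(v, dtype=bool)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                neigh = padded[1 + di:padded.shape[0] - 1 + di,
                               1 + dj:padded.shape[1] - 1 + dj]
                is_max &= center > neigh
        is_max &= v >= floor
        for i, j in zip(*np.nonzero(is_max)):
            coords = (float(grid.axes[0][i]), float(grid.axes[1][j]))
            modes.append((coords, float(v[i, j])))
    modes.sort(key=lambda m: -m[1])
    return modes
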