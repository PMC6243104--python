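"""Backbone phi/psi featurization of a loop and circular embedding.

Angles are kept in radians on (-pi, pi] internally; degrees appear only
in rendered report tables.  The default pipeline embeds each angle as
(sin, cos) before any linear covariance analysis, because raw circular
angles have a branch cut at +-pi that makes covariances ill-defined for
states straddling it.  Raw-angle features remain available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FeaturizationError
from .trajio import LoopSelection, TrajectoryEnsemble


def dihedral(p0, p1, p2, p3):
    """Signed dihedral angle (radians, (-pi, pi]) for points of shape (..., 3).

    IUPAC sign convention: looking down the p1->p2 bond, clockwise rotation
    of the far bond is positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
    ang = np.arctan2(y, x)
    # fold -pi onto +pi so the range is half-open
    return np.where(ang <= -np.pi, np.pi, ang)


@dataclass
class DihedralSeries:
    """Per-trajectory phi/psi time series for one loop."""

    angles: list                    # per-trajectory (n_frames, n_angles) radians
    angle_labels: list              # e.g. "phi:A:SER 93"
    frame_interval: float = 1.0     # ns
    omitted: list = field(default_factory=list)  # undefinable termini angles

    def __post_init__(self):
        for i, a in enumerate(self.angles):
            if a.ndim != 2 or a.shape[1] != len(self.angle_labels):
                raise ValueError(f"trajectory {i}: angle array shape {a.shape}")

    @property
    def n_angles(self) -> int:
        return len(self.angle_labels)

    @property
    def n_frames(self) -> list:
        return [a.shape[0] for a in self.angles]


@dataclass
class FeatureMatrix:
    """Per-trajectory feature vectors fed to tICA."""

    data: list                      # per-trajectory (n_frames, n_features)
    feature_names: list
    frame_interval: float = 1.0

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_frames(self) -> list:
        return [x.shape[0] for x in self.data]

    def stacked(self) -> np.ndarray:
        """All trajectories concatenated (for order-free statistics only)."""
        return np.concatenate(self.data, axis=0)


def _atom_index(universe, resindex: int, name: str):
    res = universe.residues[resindex]
    hit = res.atoms.ix[res.atoms.names == name]
    return int(hit[0]) if hit.size else None


def backbone_dihedrals(
    ensemble: TrajectoryEnsemble, selection: LoopSelection
) -> DihedralSeries:
    """Compute phi/psi for every selected residue where definable.

    phi(i) needs C(i-1); psi(i) needs N(i+1).  Angles whose flanking
    residue is absent from the topology (chain termini) are omitted and
    recorded; a present flanking residue with a missing backbone atom is
    an error naming the residue and angle.
    """
    u = ensemble.universe
    quads = []       # (label, i0, i1, i2, i3)
    omitted = []

    all_resix = set(u.residues.resindices.tolist())
    for ri in selection.resindices:
        res = u.residues[ri]
        label = f"{res.segid}:{res.resname} {res.resid}"
        n = _atom_index(u, ri, "N")
        ca = _atom_index(u, ri, "CA")
        c = _atom_index(u, ri, "C")
        if n is None or ca is None or c is None:
            missing = [nm for nm, ix in (("N", n), ("CA", ca), ("C", c)) if ix is None]
            raise FeaturizationError(f"residue {label}: missing backbone atom(s) {missing}")

        prev_ri = ri - 1
        if prev_ri in all_resix and u.residues[prev_ri].segid == res.segid:
            c_prev = _atom_index(u, prev_ri, "C")
            if c_prev is None:
                raise FeaturizationError(f"residue {label}: phi needs C of preceding residue")
            quads.append((f"phi:{label}", c_prev, n, ca, c))
        else:
            omitted.append(f"phi:{label}")

        next_ri = ri + 1
        if next_ri in all_resix and u.residues[next_ri].segid == res.segid:
            n_next = _atom_index(u, next_ri, "N")
            if n_next is None:
                raise FeaturizationError(f"residue {label}: psi needs N of following residue")
            quads.append((f"psi:{label}", n, ca, c, n_next))
        else:
            omitted.append(f"psi:{label}")

    if not quads:
        raise FeaturizationError("no definable phi/psi angles in selection")

    labels = [q[0] for q in quads]
    idx = np.array([q[1:] for q in quads], dtype=int)     # (n_angles, 4)
    series = []
    for xyz in ensemble.coordinates:
        p = xyz[:, idx, :]                                # (frames, n_angles, 4, 3)
        series.append(dihedral(p[:, :, 0], p[:, :, 1], p[:, :, 2], p[:, :, 3]))
    return DihedralSeries(
        angles=series,
        angle_labels=labels,
        frame_interval=ensemble.frame_interval,
        omitted=omitted,
    )


def circular_embed(series: DihedralSeries) -> FeatureMatrix:
    """Map each angle theta to the pair (sin theta, cos theta)."""
    if not series.angles:
        raise ValueError("empty dihedral series")
    names = []
    for lab in series.angle_labels:
        names.extend([f"sin({lab})", f"cos({lab})"])
    data = []
    for a in series.angles:
        feat = np.empty((a.shape[0], 2 * a.shape[1]))
        feat[:, 0::2] = np.sin(a)
        feat[:, 1::2] = np.cos(a)
        data.append(feat)
    return FeatureMatrix(data=data, feature_names=names,
                         frame_interval=series.frame_interval)


def raw_features(series: DihedralSeries) -> FeatureMatrix:
    """Use raw angles directly as features (config alternative)."""
    if not series.angles:
        raise ValueError("empty dihedral series")
    return FeatureMatrix(
        data=[a.copy() for a in series.angles],
        feature_names=list(series.angle_labels),
        frame_interval=series.frame_interval,
    )


def series_to_dataframe(series: DihedralSeries) -> pd.DataFrame:
    """Long-format export: trajectory, frame, angle_name, value_deg."""
    rows = []
    for t, a in enumerate(series.angles):
        deg = np.degrees(a)
        for j, lab in enumerate(series.angle_labels):
            rows.append(pd.DataFrame({
                "trajectory": t,
                "frame": np.arange(a.shape[0]),
                "angle_name": lab,
                "value_deg": deg[:, j],
            }))
    return pd.concat(rows, ignore_index=True)
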