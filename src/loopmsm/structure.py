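"""Per-state structural characterization.

Hydrogen bonds use the VMD-style geometric criterion: donor--acceptor
distance <= 3.2 A and deviation of the D-H...A angle from linearity
<= 20 degrees.  SASA is Shrake-Rupley with Bondi radii and a fixed
960-point golden-section sphere (seedless, deterministic); absolute
values therefore differ from VMD's internal radii by a few percent.
Superposition is closed-form Kabsch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import MappingError, SelectionError
from .featurize import backbone_dihedrals
from .trajio import LoopSelection, TrajectoryEnsemble

HBOND_DIST_CUTOFF = 3.2     # A, donor-acceptor
HBOND_ANGLE_CUTOFF = 20.0   # deg, deviation of D-H...A from 180
SASA_PROBE_RADIUS = 1.4     # A
SASA_N_POINTS = 960

#: Bondi van der Waals radii (A)
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

# sidechain donor heavy atoms / acceptor atoms by residue; backbone N
# (donor, with its amide H) and backbone O (acceptor) apply to all residues
_SIDECHAIN_DONOR_NAMES = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",), "TRP": ("NE1",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "HSD": ("ND1",), "HSE": ("NE2",), "HIE": ("NE2",), "HID": ("ND1",),
}
_SIDECHAIN_ACCEPTOR_NAMES = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"), "HSD": ("NE2",), "HSE": ("ND1",),
    "HIE": ("ND1",), "HID": ("NE2",), "MET": ("SD",),
}
_H_BOND_MAX = 1.25  # A, covalent D-H attachment distance


@dataclass(frozen=True)
class HBond:
    donor: int          # heavy-atom index
    hydrogen: int
    acceptor: int
    distance: float     # donor-acceptor, A
    deviation: float    # 180 - angle(D,H,A), deg


def derive_donors_acceptors(universe, atom_indices, positions=None):
    """N/O(/S) rule-table donor and acceptor typing for a selection.

    Donors are (heavy, hydrogen) pairs: backbone N plus sidechain atoms
    from the residue table, with hydrogens attached by covalent distance
    (< 1.25 A, same residue) in the supplied reference positions (the
    topology coordinates by default).  Raises when the selection
    contains no hydrogens: the heavy-atom-only fallback is deliberately
    not enabled by default.
    """
    atoms = universe.atoms[np.asarray(atom_indices)]
    if positions is None:
        positions = universe.atoms.positions
    elements = np.array([a.name.strip()[0].upper() for a in atoms])
    if not np.any(elements == "H"):
        raise SelectionError(
            "selection contains no hydrogens; H-bond detection requires an "
            "all-atom topology"
        )

    donors = []
    acceptors = []
    for res in atoms.residues:
        ratoms = res.atoms[np.isin(res.atoms.ix, atoms.ix)]
        names = {a.name: int(a.ix) for a in ratoms}
        hydrogens = [int(a.ix) for a in ratoms if a.name.strip()[0].upper() == "H"]
        donor_heavies = []
        if "N" in names:
            donor_heavies.append(names["N"])
        for nm in _SIDECHAIN_DONOR_NAMES.get(res.resname, ()):
            if nm in names:
                donor_heavies.append(names[nm])
        for d in donor_heavies:
            for h in hydrogens:
                if np.linalg.norm(positions[d] - positions[h]) < _H_BOND_MAX:
                    donors.append((d, h))
        if "O" in names:
            acceptors.append(names["O"])
        if "OXT" in names:
            acceptors.append(names["OXT"])
        for nm in _SIDECHAIN_ACCEPTOR_NAMES.get(res.resname, ()):
            if nm in names:
                acceptors.append(names[nm])
    return donors, np.array(sorted(set(acceptors)), dtype=int)


def find_hbonds(
    positions: np.ndarray,
    donors,
    acceptors,
    dist_cutoff: float = HBOND_DIST_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> list:
    """Geometric hydrogen bonds in one frame.

    ``donors`` is a list of (donor_heavy, hydrogen) atom-index pairs;
    ``acceptors`` an index array.  A bond is reported when the D-A
    distance is within ``dist_cutoff`` and the D-H...A angle deviates
    from linear by at most ``angle_cutoff`` degrees.
    """
    positions = np.asarray(positions, dtype=np.float64)
    acceptors = np.asarray(acceptors, dtype=int)
    bonds = []
    for d, h in donors:
        acc = acceptors[(acceptors != d) & (acceptors != h)]
        if acc.size == 0:
            continue
        da = np.linalg.norm(positions[acc] - positions[d], axis=1)
        close = acc[da <= dist_cutoff]
        for a, dist in zip(close, da[da <= dist_cutoff]):
            hd = positions[d] - positions[h]
            ha = positions[a] - positions[h]
            cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            deviation = 180.0 - ang
            if deviation <= angle_cutoff:
                bonds.append(HBond(int(d), int(h), int(a), float(dist),
                                   float(deviation)))
    return bonds


def hbond_occupancy(per_frame_bonds, labels, pair) -> dict:
    """Fraction of frames per state containing a donor-acceptor pair.

    ``per_frame_bonds`` is a flat sequence of per-frame HBond lists,
    aligned with the flat ``labels`` sequence of state assignments.
    Empty states yield NaN (flagged, not fatal).
    """
    labels = np.asarray(labels)
    if len(per_frame_bonds) != len(labels):
        raise ValueError("per-frame bond lists and labels differ in length")
    d_want, a_want = pair
    present = np.array([
        any(b.donor == d_want and b.acceptor == a_want for b in bonds)
        for bonds in per_frame_bonds
    ])
    out = {}
    for state in np.unique(labels[labels >= 0]):
        mask = labels == state
        out[int(state)] = float(present[mask].mean()) if mask.any() else float("nan")
    return out


def golden_section_sphere(n_points: int = SASA_N_POINTS) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n_points) + 0.5
    z = 1.0 - 2.0 * i / n_points
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atomic_radii(universe, atom_indices) -> np.ndarray:
    """Bondi radii for a selection; unknown elements are an error."""
    atoms = universe.atoms[np.asarray(atom_indices)]
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        try:
            elem = a.element.upper() if a.element else ""
        except Exception:  # noqa: BLE001 - no element column
            elem = ""
        if not elem:
            elem = a.name.strip()[0].upper()
            if elem not in BONDI_RADII and a.name.strip()[:2].upper() in BONDI_RADII:
                elem = a.name.strip()[:2].upper()
        if elem not in BONDI_RADII:
            raise SelectionError(f"no Bondi radius for element {elem!r} (atom {a.name})")
        radii[i] = BONDI_RADII[elem]
    return radii


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = SASA_PROBE_RADIUS,
    n_points: int = SASA_N_POINTS,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2).

    Only the supplied atoms occlude each other: callers restrict the
    coordinate set to the atoms that should participate (the loop-only
    convention of the per-state summaries).
    """
    coords = np.asarray(coords, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    n = coords.shape[0]
    sphere = golden_section_sphere(n_points)
    expanded = radii + probe
    areas = np.empty(n)
    d = cdist(coords, coords)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        neighbors = np.flatnonzero((d[i] < expanded[i] + expanded) & (np.arange(n) != i))
        if neighbors.size == 0:
            exposed = n_points
        else:
            pd_ = cdist(pts, coords[neighbors])
            buried = (pd_ < expanded[neighbors][None, :]).any(axis=1)
            exposed = int((~buried).sum())
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed / n_points
    return areas


def sasa(
    ensemble: TrajectoryEnsemble,
    traj_index: int,
    frame_index: int,
    selection: LoopSelection,
    probe: float = SASA_PROBE_RADIUS,
    n_points: int = SASA_N_POINTS,
) -> float:
    """Total SASA (A^2) of the loop selection in one frame, loop-only."""
    idx = selection.atoms_all
    coords = ensemble.coordinates[traj_index][frame_index][idx]
    radii = atomic_radii(ensemble.universe, idx)
    return float(shrake_rupley(coords, radii, probe=probe, n_points=n_points).sum())


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation R, translation t, rmsd) with the convention
    ``mobile @ R.T + t ~= target``.
    """
    p = np.asarray(mobile, dtype=np.float64)
    q = np.asarray(target, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("point sets must have identical shape")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - pc @ r.T
    moved = p @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return r, t, rmsd


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _match_atoms(ref_universe, ref_indices, ens_universe):
    """Pair reference atoms with ensemble atoms by (segid, resid, name)."""
    ens_key = {}
    for a in ens_universe.atoms:
        ens_key[(a.segid, int(a.resid), a.name)] = int(a.ix)
        ens_key.setdefault((int(a.resid), a.name), int(a.ix))
    pairs = []
    unmatched = []
    for a in ref_universe.atoms[np.asarray(ref_indices)]:
        key3 = (a.segid, int(a.resid), a.name)
        key2 = (int(a.resid), a.name)
        if key3 in ens_key:
            pairs.append((int(a.ix), ens_key[key3]))
        elif key2 in ens_key:
            pairs.append((int(a.ix), ens_key[key2]))
        else:
            unmatched.append(f"{a.segid}:{a.resid}:{a.name}")
    if unmatched:
        raise MappingError(f"unmatched reference atoms: {', '.join(unmatched)}")
    return np.array(pairs, dtype=int)


def nearest_frame_by_rmsd(
    ensemble: TrajectoryEnsemble,
    reference: TrajectoryEnsemble,
    align_indices_ref: np.ndarray,
    rmsd_indices_ref: np.ndarray,
):
    """Closest ensemble frame to a reference conformation.

    Every frame is Kabsch-aligned to the reference on the alignment
    selection (e.g. the variable-domain backbone); the RMSD is then
    evaluated on the scoring selection (e.g. loop C-alphas).  Atom
    correspondence is resolved by (segid, resid, atom name).  Returns
    (trajectory, frame, rmsd_A).
    """
    align_pairs = _match_atoms(reference.universe, align_indices_ref, ensemble.universe)
    score_pairs = _match_atoms(reference.universe, rmsd_indices_ref, ensemble.universe)
    ref_xyz = reference.coordinates[0][0]
    ref_align = ref_xyz[align_pairs[:, 0]]
    ref_score = ref_xyz[score_pairs[:, 0]]

    best = (None, None, np.inf)
    for t, xyz in enumerate(ensemble.coordinates):
        for f in range(xyz.shape[0]):
            r, tr, _ = kabsch(xyz[f][align_pairs[:, 1]], ref_align)
            moved = xyz[f][score_pairs[:, 1]] @ r.T + tr
            val = rmsd(moved, ref_score)
            if val < best[2]:
                best = (t, f, val)
    return best


def centroid_dihedral_table(
    ensemble: TrajectoryEnsemble,
    centroid_ids,
    selection: LoopSelection,
    state_names=None,
) -> pd.DataFrame:
    """Per-state phi/psi table (degrees) at the centroid frames.

    Undefined termini angles are reported as NaN, never fabricated.
    """
    series = backbone_dihedrals(ensemble, selection)
    rows = []
    for s, (t, f) in enumerate(centroid_ids):
        name = state_names[s] if state_names else f"state {s + 1}"
        vals = np.degrees(series.angles[t][f])
        for lab, v in zip(series.angle_labels, vals):
            angle, res = lab.split(":", 1)
            rows.append({"state": name, "residue": res, "angle": angle,
                         "value_deg": float(v)})
        for lab in series.omitted:
            angle, res = lab.split(":", 1)
            rows.append({"state": name, "residue": res, "angle": angle,
                         "value_deg": float("nan")})
    return pd.DataFrame(rows)
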