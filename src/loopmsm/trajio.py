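"""Trajectory ensemble I/O and loop-residue selection.

Coordinates are handled in Angstrom throughout; frame indices are 0-based
and ranges half-open.  Trajectory boundaries are preserved: downstream
time-lagged statistics must never pair frames across two trajectories,
so the ensemble stores one coordinate array per input file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import MDAnalysis as mda

from .errors import FormatError, SelectionError, TopologyError

_BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass
class TrajectoryEnsemble:
    """A multi-trajectory coordinate set sharing one topology.

    Attributes
    ----------
    universe : MDAnalysis.Universe
        Topology carrier (atom/residue/segment tables).
    coordinates : list of ndarray, each (n_frames, n_atoms, 3)
        Per-trajectory Cartesian coordinates in Angstrom.
    frame_interval : float
        Time between saved frames in nanoseconds.
    labels : list of str
        Per-trajectory names.
    """

    universe: mda.Universe
    coordinates: list = field(default_factory=list)
    frame_interval: float = 1.0
    labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0 ns")
        n_atoms = len(self.universe.atoms)
        for i, xyz in enumerate(self.coordinates):
            if xyz.ndim != 3 or xyz.shape[1] != n_atoms or xyz.shape[2] != 3:
                raise TopologyError(
                    f"trajectory {i}: coordinate shape {xyz.shape} inconsistent "
                    f"with topology of {n_atoms} atoms"
                )
            if not np.isfinite(xyz).all():
                raise ValueError(f"trajectory {i}: non-finite coordinates")
        if not self.labels:
            self.labels = [f"traj{i}" for i in range(len(self.coordinates))]

    @property
    def n_trajectories(self) -> int:
        return len(self.coordinates)

    @property
    def n_frames(self) -> list:
        """Per-trajectory frame counts (boundaries are never merged)."""
        return [xyz.shape[0] for xyz in self.coordinates]

    @property
    def n_atoms(self) -> int:
        return len(self.universe.atoms)


@dataclass
class LoopSelection:
    """Resolved loop residues and derived atom index sets."""

    spec: str
    resindices: np.ndarray          # topology residue indices, ordered
    residue_labels: list            # "SEGID:RESNAME RESID" strings
    atoms_all: np.ndarray           # all atoms of selected residues
    atoms_backbone: np.ndarray      # N/CA/C/O
    atoms_heavy: np.ndarray         # non-hydrogen
    atoms_ca: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.resindices)


def load_ensemble(
    paths: Sequence[str],
    topology: str,
    frame_interval: float,
    labels: Sequence[str] | None = None,
) -> TrajectoryEnsemble:
    """Read one or more trajectory files against a PDB topology.

    Parameters
    ----------
    paths : sequence of str
        Trajectory files (DCD, XTC, Amber NetCDF, or multi-model PDB).
    topology : str
        PDB file defining the atom table all trajectories must match.
    frame_interval : float
        Time between saved frames, in ns (required; not read from files).
    """
    topology = str(topology)
    if not Path(topology).exists():
        raise FormatError(f"topology file not found: {topology}")
    try:
        top_u = mda.Universe(topology)
    except Exception as exc:  # noqa: BLE001 - normalize reader errors
        raise FormatError(f"could not parse topology {topology}: {exc}") from exc
    n_atoms = len(top_u.atoms)

    coords = []
    for p in paths:
        p = str(p)
        if not Path(p).exists():
            raise FormatError(f"trajectory file not found: {p}")
        try:
            u = mda.Universe(topology, p)
        except (ValueError, IOError) as exc:
            msg = str(exc)
            if "atom" in msg.lower() and ("match" in msg.lower() or "number" in msg.lower()):
                raise TopologyError(
                    f"trajectory {p} atom count inconsistent with topology "
                    f"({n_atoms} atoms): {msg}"
                ) from exc
            raise FormatError(f"could not read trajectory {p}: {msg}") from exc
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"could not read trajectory {p}: {exc}") from exc
        if len(u.atoms) != n_atoms:
            raise TopologyError(
                f"trajectory {p} has {len(u.atoms)} atoms, topology has {n_atoms}"
            )
        xyz = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=np.float64)
        coords.append(xyz)

    lab = list(labels) if labels else [Path(p).stem for p in paths]
    return TrajectoryEnsemble(
        universe=top_u, coordinates=coords, frame_interval=frame_interval, labels=lab
    )


def load_structure(path: str) -> TrajectoryEnsemble:
    """Read a single external conformation (PDB) as a 1-frame ensemble."""
    path = str(path)
    if not Path(path).exists():
        raise FormatError(f"structure file not found: {path}")
    try:
        u = mda.Universe(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"could not parse structure {path}: {exc}") from exc
    xyz = u.atoms.positions.copy()[None, :, :].astype(np.float64)
    return TrajectoryEnsemble(
        universe=u, coordinates=[xyz], frame_interval=1.0, labels=[Path(path).stem]
    )


_RANGE_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?(?P<lo>-?\d+)(?:-(?P<hi>-?\d+))?$")


def _parse_ranges(spec: str):
    tokens = [t.strip() for t in spec.split(",") if t.strip()]
    if not tokens:
        raise SelectionError(f"empty residue-range specification: {spec!r}")
    out = []
    for tok in tokens:
        m = _RANGE_RE.match(tok)
        if not m:
            raise SelectionError(f"could not parse residue range token {tok!r}")
        lo = int(m.group("lo"))
        hi = int(m.group("hi")) if m.group("hi") is not None else lo
        if hi < lo:
            raise SelectionError(f"inverted residue range {tok!r}")
        out.append((m.group("chain"), lo, hi))
    return out


def select_loop(source, spec: str) -> LoopSelection:
    """Resolve a residue-range text to loop atoms.

    ``spec`` is a comma-separated list of inclusive residue ranges, each
    optionally chain-qualified: ``"92-97,205-210"`` or ``"A:92-97,B:2-8"``.
    Unqualified ranges assume contiguous serial numbering across chains
    (resids unique in the topology).  Missing residues raise
    :class:`SelectionError` naming the residue.
    """
    universe = source.universe if isinstance(source, TrajectoryEnsemble) else source
    ranges = _parse_ranges(spec)

    residues = universe.residues
    resids = residues.resids
    try:
        segids = residues.segids
    except AttributeError:
        segids = np.array([""] * len(residues))

    picked = []
    for chain, lo, hi in ranges:
        for resid in range(lo, hi + 1):
            mask = resids == resid
            if chain is not None:
                mask &= segids == chain
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                where = f"chain {chain} " if chain else ""
                raise SelectionError(f"residue {where}{resid} not found in topology")
            # contiguous-numbering mode requires a unique match
            if chain is None and idx.size > 1:
                raise SelectionError(
                    f"residue {resid} is ambiguous across chains; qualify with 'CHAIN:'"
                )
            picked.extend(residues.resindices[idx])

    resindices = np.array(sorted(set(picked)), dtype=int)
    sel_res = universe.residues[np.isin(universe.residues.resindices, resindices)]
    atoms = sel_res.atoms
    if len(atoms) == 0:
        raise SelectionError(f"selection {spec!r} matched residues but no atoms")

    names = atoms.names
    try:
        elements = np.array([a.element if a.element else _guess_element(a.name)
                             for a in atoms])
    except mda.exceptions.NoDataError:
        elements = np.array([_guess_element(n) for n in names])

    backbone = atoms.ix[np.isin(names, _BACKBONE_NAMES)]
    heavy = atoms.ix[elements != "H"]
    ca = atoms.ix[names == "CA"]

    labels = [f"{r.segid}:{r.resname} {r.resid}" for r in sel_res]
    return LoopSelection(
        spec=spec,
        resindices=resindices,
        residue_labels=labels,
        atoms_all=atoms.ix.copy(),
        atoms_backbone=backbone,
        atoms_heavy=heavy,
        atoms_ca=ca,
    )


def _guess_element(name: str) -> str:
    """PDB-style element guess from an atom name."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H" or (len(name) < 4 and name[0] in "123" and "H" in name):
        return "H"
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA") and len(name.strip()) > 1:
        # only treat as two-letter element when PDB columns say so; atom names
        # like "CA"/"CB" are carbon -- callers pass stripped names, so default C
        pass
    return stripped[0].upper()


def write_frame(
    ensemble: TrajectoryEnsemble,
    traj_index: int,
    frame_index: int,
    path: str,
    atom_indices: np.ndarray | None = None,
) -> None:
    """Write one frame (optionally a sub-selection) to a PDB file."""
    u = ensemble.universe
    xyz = ensemble.coordinates[traj_index][frame_index]
    group = u.atoms if atom_indices is None else u.atoms[atom_indices]
    u.atoms.positions = xyz
    group.write(str(path))
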