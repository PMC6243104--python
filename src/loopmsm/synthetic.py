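"""Synthetic dihedral trajectories with known metastable structure.

A hidden Markov chain over K states emits per-frame phi/psi angles from
independent von Mises distributions around state-specific means.  The
chain is Markov at the frame level, so implied timescales of a correct
downstream model are lag-flat by construction — which is what makes lag
selection testable.  The module also writes small PDB fixtures (ideal
dihedral quads, D-H...A triads, sphere pairs, rigid-transformed
peptides) so the structural operators are testable without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .featurize import DihedralSeries, dihedral
from .msm import model_from_transition_matrix

# ---------------------------------------------------------------------------
# hidden-Markov dihedral generator

#: Documented 4-state generator chain (unit frame lag).  Slow implied
#: timescales 99.4 / 73.3 / 51.0 frames — fast enough to mix well within
#: a 30,000-frame trajectory yet far above the emission-noise processes;
#: stationary distribution (0.1384, 0.1515, 0.4245, 0.2856) — state 3
#: dominant, state 2 a weakly metastable low-population hub.
DEFAULT_T_TRUE = np.array([
    [0.9910, 0.0040, 0.0037, 0.0013],
    [0.0026, 0.9835, 0.0082, 0.0057],
    [0.0012, 0.0027, 0.9921, 0.0040],
    [0.0012, 0.0028, 0.0056, 0.9904],
])

#: Documented per-state mean dihedrals (radians), 4 states x 12 angles
#: (6 residues x phi/psi), drawn once from Ramachandran-like basins and
#: frozen.  Minimum pairwise separation in (sin, cos) embedding: 3.2.
DEFAULT_STATE_MEANS = np.array([
    [-1.209, 2.164, -1.478, 2.982, -1.536, 1.838,
     -0.774, 2.005, -0.788, 2.668, -1.705, 1.924],
    [-1.157, -0.508, -1.561, -1.186, -0.773, -1.010,
     -0.733, -1.262, -0.569, -1.381, -1.519, -1.311],
    [1.212, 1.370, 0.498, 0.776, 1.446, 0.372,
     0.814, 0.777, 0.878, 1.412, 1.389, 1.489],
    [-2.942, 2.526, -2.137, 2.826, -1.877, 2.651,
     -2.807, 2.435, -2.799, 2.094, -1.851, 2.605],
])

DEFAULT_KAPPA = 25.0


@dataclass
class SyntheticSpec:
    """Parameters of the hidden-Markov dihedral generator."""

    transition_matrix: np.ndarray   # (K, K), row-stochastic at unit frame lag
    means: np.ndarray               # (K, n_angles) radians in (-pi, pi]
    kappas: np.ndarray              # (K,) von Mises concentrations
    n_trajectories: int = 10
    n_frames: int = 30_000
    frame_interval: float = 1.0     # ns
    seed: int = 2018
    angle_labels: list = field(default_factory=list)

    def __post_init__(self):
        t = np.asarray(self.transition_matrix, dtype=np.float64)
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must be nonnegative and sum to 1")
        self.transition_matrix = t
        self.means = np.asarray(self.means, dtype=np.float64)
        if self.means.shape[0] != t.shape[0]:
            raise ValueError("means must have one row per hidden state")
        if np.any(self.means <= -np.pi) or np.any(self.means > np.pi):
            raise ValueError("means must lie in (-pi, pi]")
        self.kappas = np.broadcast_to(
            np.asarray(self.kappas, dtype=np.float64), (t.shape[0],)
        ).copy()
        if np.any(self.kappas <= 0):
            raise ValueError("kappa must be > 0")
        if not self.angle_labels:
            n_angles = self.means.shape[1]
            if n_angles % 2 == 0:
                self.angle_labels = [
                    f"{kind}:SYN:GLY {i + 1}"
                    for i in range(n_angles // 2) for kind in ("phi", "psi")
                ]
            else:
                self.angle_labels = [f"angle:{j}" for j in range(n_angles)]

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_angles(self) -> int:
        return self.means.shape[1]

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the generator chain."""
        model = model_from_transition_matrix(self.transition_matrix)
        return model.stationary

    def implied_timescales_frames(self) -> np.ndarray:
        model = model_from_transition_matrix(self.transition_matrix)
        return model.implied_timescales_frames()

    def to_dict(self) -> dict:
        return {
            "transition_matrix": self.transition_matrix.tolist(),
            "means": self.means.tolist(),
            "kappas": self.kappas.tolist(),
            "n_trajectories": self.n_trajectories,
            "n_frames": self.n_frames,
            "frame_interval": self.frame_interval,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        return cls(
            transition_matrix=np.array(d["transition_matrix"]),
            means=np.array(d["means"]),
            kappas=np.array(d["kappas"]),
            n_trajectories=int(d.get("n_trajectories", 10)),
            n_frames=int(d.get("n_frames", 30_000)),
            frame_interval=float(d.get("frame_interval", 1.0)),
            seed=int(d.get("seed", 2018)),
        )


def default_4state_spec(
    seed: int = 2018,
    n_trajectories: int = 10,
    n_frames: int = 30_000,
    frame_interval: float = 1.0,
) -> SyntheticSpec:
    """The documented 4-state benchmark generator (see module constants)."""
    return SyntheticSpec(
        transition_matrix=DEFAULT_T_TRUE.copy(),
        means=DEFAULT_STATE_MEANS.copy(),
        kappas=np.full(4, DEFAULT_KAPPA),
        n_trajectories=n_trajectories,
        n_frames=n_frames,
        frame_interval=frame_interval,
        seed=seed,
    )


def _sample_chain(t_cum, start_probs, n, rng):
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(len(start_probs), p=start_probs)
    u = rng.random(n)
    for i in range(1, n):
        states[i] = np.searchsorted(t_cum[states[i - 1]], u[i], side="right")
    return states


def generate_hmm_trajectories(spec: SyntheticSpec):
    """Sample dihedral trajectories plus their true hidden labels.

    The hidden chain starts from its stationary distribution; angles are
    drawn von Mises around the hidden state's means and wrapped to
    (-pi, pi].  Fully reproducible from spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    pi = spec.stationary()
    t_cum = np.cumsum(spec.transition_matrix, axis=1)
    t_cum[:, -1] = 1.0  # guard against rounding

    angle_arrays = []
    labels = []
    for _ in range(spec.n_trajectories):
        states = _sample_chain(t_cum, pi, spec.n_frames, rng)
        ang = rng.vonmises(spec.means[states], spec.kappas[states][:, None])
        ang = np.where(ang <= -np.pi, np.pi, ang)
        angle_arrays.append(ang)
        labels.append(states)
    series = DihedralSeries(
        angles=angle_arrays,
        angle_labels=list(spec.angle_labels),
        frame_interval=spec.frame_interval,
    )
    return series, labels


# ---------------------------------------------------------------------------
# toy Cartesian structures for the structural operators

def place_atom(a, b, c, bond_length, bond_angle, dihedral_angle):
    """NeRF placement: position d bonded to c with given internal coordinates.

    ``bond_angle`` is the b-c-d angle and ``dihedral_angle`` the a-b-c-d
    torsion, both in radians.
    """
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond_length * np.cos(bond_angle),
        bond_length * np.sin(bond_angle) * np.cos(dihedral_angle),
        bond_length * np.sin(bond_angle) * np.sin(dihedral_angle),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral_quad(angle_rad: float) -> np.ndarray:
    """Four points whose torsion is exactly ``angle_rad`` (by inverse NeRF)."""
    a = np.array([0.0, 1.0, 0.0])
    b = np.array([0.0, 0.0, 0.0])
    c = np.array([1.5, 0.0, 0.0])
    d = place_atom(a, b, c, 1.5, np.radians(109.5), angle_rad)
    quad = np.array([a, b, c, d])
    # construction check: the standard formula must return the request
    assert abs(float(dihedral(*quad)) - float(np.arctan2(np.sin(angle_rad),
               np.cos(angle_rad)))) < 1e-9
    return quad


def hbond_triad(da_distance: float, deviation_deg: float) -> np.ndarray:
    """Donor/H/acceptor coordinates at a given D-A distance and linearity
    deviation (degrees).  Rows: donor N, hydrogen, acceptor O."""
    delta = np.radians(deviation_deg)
    d = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    cosd = np.cos(delta)
    # |(1 + L cos, L sin)| = da_distance  ->  L^2 + 2 L cos + 1 - da^2 = 0
    ell = -cosd + np.sqrt(cosd**2 - 1.0 + da_distance**2)
    a = h + ell * np.array([np.cos(delta), np.sin(delta), 0.0])
    return np.array([d, h, a])


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{resname:>3s} {chain:1s}{resid:4d}"
    "{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          "
    "{element:>2s}\n"
)


def write_pdb(path, atoms) -> None:
    """Minimal PDB writer.

    ``atoms`` is an iterable of dicts with keys name, resname, chain,
    resid, xyz and optional element.
    """
    with open(path, "w") as fh:
        for i, at in enumerate(atoms, start=1):
            name = at["name"]
            pdb_name = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = at["xyz"]
            fh.write(_PDB_ATOM.format(
                serial=i, name=pdb_name, alt=" ", resname=at["resname"],
                chain=at.get("chain", "A"), resid=at["resid"], icode=" ",
                x=x, y=y, z=z, occ=1.0, b=0.0,
                element=at.get("element", name.strip()[0]),
            ))
        fh.write("END\n")


# idealized backbone internal coordinates (A / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8


def build_peptide(phis, psis, with_hydrogens: bool = True, resname: str = "GLY",
                  chain: str = "A", first_resid: int = 1):
    """Idealized backbone coordinates for a peptide with given phi/psi.

    ``phis[i]``/``psis[i]`` (degrees) set the torsions of residue i; the
    first phi and last psi are unused (undefined at termini, matching
    the featurizer's omission rule).  Returns a list of atom dicts
    suitable for :func:`write_pdb`.
    """
    n_res = len(phis)
    if len(psis) != n_res:
        raise ValueError("phis and psis must have equal length")
    rad = np.radians
    coords = {}
    # residue 0 backbone in the xy-plane
    coords[(0, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(0, "CA")] = np.array([_B_N_CA, 0.0, 0.0])
    coords[(0, "C")] = place_atom(
        np.array([0.0, 1.0, 0.0]), coords[(0, "N")], coords[(0, "CA")],
        _B_CA_C, rad(_A_N_CA_C), rad(150.0),
    )
    for i in range(1, n_res):
        coords[(i, "N")] = place_atom(
            coords[(i - 1, "N")], coords[(i - 1, "CA")], coords[(i - 1, "C")],
            _B_C_N, rad(_A_CA_C_N), rad(psis[i - 1]),
        )
        coords[(i, "CA")] = place_atom(
            coords[(i - 1, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
            _B_N_CA, rad(_A_C_N_CA), rad(180.0),   # omega trans
        )
        coords[(i, "C")] = place_atom(
            coords[(i - 1, "C")], coords[(i, "N")], coords[(i, "CA")],
            _B_CA_C, rad(_A_N_CA_C), rad(phis[i]),
        )
    for i in range(n_res):
        # carbonyl O anti to the next N (psi + 180); last residue uses psi too
        psi_eff = psis[i] if i < n_res - 1 else 140.0
        coords[(i, "O")] = place_atom(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            _B_C_O, rad(_A_CA_C_O), rad(psi_eff + 180.0),
        )
        if with_hydrogens and i > 0:
            coords[(i, "H")] = place_atom(
                coords[(i, "CA")], coords[(i - 1, "C")], coords[(i, "N")],
                _B_N_H, rad(119.0), rad(180.0),
            )

    atoms = []
    order = ["N", "H", "CA", "C", "O"] if with_hydrogens else ["N", "CA", "C", "O"]
    for i in range(n_res):
        for nm in order:
            if (i, nm) not in coords:
                continue
            atoms.append({
                "name": nm, "resname": resname, "chain": chain,
                "resid": first_resid + i, "xyz": coords[(i, nm)],
                "element": nm[0],
            })
    return atoms


def rigid_transform(atoms, rotation=None, translation=(5.0, -3.0, 2.0),
                    angle_deg: float = 37.0, axis=(1.0, 2.0, 3.0)):
    """Rotated + translated copy of an atom list (for RMSD fixtures)."""
    if rotation is None:
        ax = np.asarray(axis, dtype=np.float64)
        ax /= np.linalg.norm(ax)
        th = np.radians(angle_deg)
        k = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]], [-ax[1], ax[0], 0]])
        rotation = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
    out = []
    for at in atoms:
        new = dict(at)
        new["xyz"] = rotation @ np.asarray(at["xyz"]) + np.asarray(translation)
        out.append(new)
    return out


def make_toy_structures(outdir) -> dict:
    """Write the PDB fixtures used by the structural-operator tests.

    Returns a dict of fixture name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    quad = dihedral_quad(np.radians(60.0))
    atoms = [
        {"name": nm, "resname": "DIH", "chain": "A", "resid": 1,
         "xyz": xyz, "element": "C"}
        for nm, xyz in zip(["C1", "C2", "C3", "C4"], quad)
    ]
    paths["dihedral_60"] = outdir / "dihedral_60.pdb"
    write_pdb(paths["dihedral_60"], atoms)

    for name, (dist, dev) in {
        "hbond_good": (2.9, 5.0), "hbond_bent": (2.9, 25.0),
        "hbond_far": (3.3, 0.0),
    }.items():
        tri = hbond_triad(dist, dev)
        atoms = [
            {"name": "N", "resname": "DON", "chain": "A", "resid": 1,
             "xyz": tri[0], "element": "N"},
            {"name": "H", "resname": "DON", "chain": "A", "resid": 1,
             "xyz": tri[1], "element": "H"},
            {"name": "O", "resname": "ACC", "chain": "A", "resid": 2,
             "xyz": tri[2], "element": "O"},
        ]
        paths[name] = outdir / f"{name}.pdb"
        write_pdb(paths[name], atoms)

    paths["sphere_one"] = outdir / "sphere_one.pdb"
    write_pdb(paths["sphere_one"], [
        {"name": "C1", "resname": "SPH", "chain": "A", "resid": 1,
         "xyz": (0.0, 0.0, 0.0), "element": "C"},
    ])
    paths["sphere_two"] = outdir / "sphere_two.pdb"
    write_pdb(paths["sphere_two"], [
        {"name": "C1", "resname": "SPH", "chain": "A", "resid": 1,
         "xyz": (0.0, 0.0, 0.0), "element": "C"},
        {"name": "C2", "resname": "SPH", "chain": "A", "resid": 2,
         "xyz": (3.0, 0.0, 0.0), "element": "C"},
    ])

    pep = build_peptide(phis=[0, -65, -120, -70, 0],
                        psis=[0, -40, 130, 150, 0])
    paths["peptide"] = outdir / "peptide.pdb"
    write_pdb(paths["peptide"], pep)
    paths["peptide_moved"] = outdir / "peptide_moved.pdb"
    write_pdb(paths["peptide_moved"], rigid_transform(pep))

    return paths
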