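import numpy as np
import pytest
import MDAnalysis as mda

from loopmsm import synthetic, trajio


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Session directory of generated PDB fixtures."""
    d = tmp_path_factory.mktemp("fixtures")
    paths = synthetic.make_toy_structures(d)
    return paths


def make_peptide_ensemble(n_frames=5, n_res=6, first_resid=1, chain="A",
                          frame_interval=0.5, seed=0, tmp_path=None,
                          with_hydrogens=True):
    """In-memory ensemble of an idealized peptide with per-frame phi/psi.

    Frame f uses angles drawn deterministically from ``seed``; frame 0
    defines the topology (written to PDB and re-read through MDAnalysis).
    Returns (ensemble, per-frame angle table (n_frames, n_res, 2) deg).
    """
    import tempfile
    from pathlib import Path

    rng = np.random.default_rng(seed)
    angle_sets = rng.uniform(-170, 170, size=(n_frames, n_res, 2))
    frames = []
    for f in range(n_frames):
        atoms = synthetic.build_peptide(
            phis=angle_sets[f, :, 0], psis=angle_sets[f, :, 1],
            first_resid=first_resid, chain=chain,
            with_hydrogens=with_hydrogens)
        frames.append(np.array([a["xyz"] for a in atoms]))
        if f == 0:
            topo_atoms = atoms
    d = Path(tempfile.mkdtemp()) if tmp_path is None else Path(tmp_path)
    d.mkdir(parents=True, exist_ok=True)
    topo = d / "peptide_topo.pdb"
    synthetic.write_pdb(topo, topo_atoms)
    u = mda.Universe(str(topo))
    ens = trajio.TrajectoryEnsemble(
        universe=u,
        coordinates=[np.stack(frames)],
        frame_interval=frame_interval,
    )
    return ens, angle_sets


@pytest.fixture()
def peptide_ensemble(tmp_path):
    return make_peptide_ensemble(tmp_path=tmp_path)
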