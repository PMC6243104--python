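# loopmsm

Markov state model analysis of protein loop dihedral dynamics, as a
tested, reusable pipeline:

1. **Featurization** — backbone φ/ψ time series for a chain-qualified
   loop residue selection, with (sin, cos) circular embedding.
2. **tICA** — time-lagged independent component analysis (default lag
   5 ns, 16 retained components) via the generalized eigenproblem
   between instantaneous and time-lagged covariances, with Cτ
   symmetrization and C0 shrinkage; projection of trajectory frames
   and of external single conformations (e.g. bound crystal structures).
3. **Density** — Gaussian KDE (Scott's Rule bandwidth) of the projected
   data, 1-D marginals and 2-D maps, with local-maximum (metastable
   island) detection.
4. **Microstates** — PAM k-medoids clustering in tICA space
   (deterministic, seeded; defaults 16/32 clusters).
5. **Markov models** — sliding-window transition counting, ergodic
   trimming, reversible maximum-likelihood transition matrices,
   implied timescales across a lag grid, and automatic lag selection
   by timescale convergence (non-convergence is a reported status).
6. **Macrostates** — PCCA+ (inner simplex) coarse-graining, macrostate
   MSM at an independent lag (default 115 ns), equilibrium populations
   by eigenvalue analysis and by membership weighting, jump
   probabilities, tICA-space centroids.
7. **Structure** — geometric hydrogen bonds (3.2 Å / 20° defaults),
   per-state H-bond occupancy, Shrake–Rupley SASA (Bondi radii, 1.4 Å
   probe, 960 deterministic sphere points), Kabsch superposition and
   nearest-frame-by-RMSD lookup, per-centroid φ/ψ tables.
8. **Synthetic** — a hidden-Markov von Mises dihedral generator with a
   documented 4-state benchmark chain, plus programmatic PDB fixtures
   (dihedral quads, D–H···A triads, sphere pairs, rigid-transformed
   peptides), so the entire pipeline is testable with no external data.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (estimator
oracles, synthetic 4-state recovery at 10 × 30,000 frames, structural
operator checks, byte-level determinism); the rest are per-module unit
and property tests.

## CLI

Generate a synthetic benchmark config plus toy PDB fixtures, run the
pipeline, render figures:

```bash
loopmsm synth --outdir work --seed 2018
loopmsm run --config work/synthetic_config.yaml --outdir work/run
loopmsm report --outdir work/run
```

Stage subcommands (`featurize`, `tica`, `cluster`, `msm`, `macro`,
`structure`) run the pipeline up to that stage. For MD input, set in
the YAML config `mode: files`, a PDB `topology:`, a `trajectories:`
list (DCD/XTC/NetCDF), the save interval `frame_interval:` in ns, and a
`loop:` residue-range text such as `"92-97,205-210"` (optionally
chain-qualified, `"A:92-97"`). External PDB conformations listed under
`external_structures:` are projected onto the fitted tICA model.

All artifacts are written to the run directory with a
machine-readable `manifest.json`; figures are re-creatable from the
persisted tables alone. One config seed governs every stochastic stage;
identical config + seed gives byte-identical numeric tables.

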