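"""End-to-end orchestration: config, run directory, reports.

A single config drives featurize -> tICA -> project -> KDE/modes ->
k-medoids -> ITS scan -> lag selection -> micro MSM -> PCCA+ -> macro
MSM -> centroids -> structural summaries -> external projections.  One
seed governs every stochastic stage.  All lags are given in ns and
converted once through the frame interval.  Every artifact is a view of
persisted data listed in a machine-readable manifest, so figures can be
re-created from the run directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import density, featurize, macrostates, msm, structure, synthetic, tica, trajio

logger = logging.getLogger(__name__)

# fixed analysis defaults
DEFAULT_TICA_LAG_NS = 5.0
DEFAULT_N_COMPONENTS = 16
DEFAULT_N_CLUSTERS_ALPHA = 16
DEFAULT_N_CLUSTERS_BETA = 32
DEFAULT_MICRO_LAG_NS = 8.0
DEFAULT_MACRO_LAG_NS = 115.0

STAGES = ("featurize", "tica", "density", "cluster", "msm", "macro",
          "structure", "external")


@dataclass
class AnalysisConfig:
    """Complete parameterization of one pipeline run."""

    # inputs: either trajectory files or a synthetic generator spec
    mode: str = "files"                      # "files" | "synthetic"
    topology: str | None = None
    trajectories: list = field(default_factory=list)
    frame_interval: float | None = None      # ns; required for file inputs
    loop: str = "92-97,205-210"              # residue-range text
    synthetic: dict | None = None            # SyntheticSpec.to_dict()

    # featurization
    feature_type: str = "sincos"             # "sincos" | "raw"

    # tICA
    tica_lag_ns: float = DEFAULT_TICA_LAG_NS
    n_components: int = DEFAULT_N_COMPONENTS

    # microstate clustering
    n_clusters: int = DEFAULT_N_CLUSTERS_BETA
    max_fit_frames: int = 50_000             # k-medoids fit subsample cap

    # density
    kde_stride: int = 1
    mode_prominence: float = density.DEFAULT_MODE_PROMINENCE

    # Markov models
    its_lags_ns: list = field(default_factory=list)   # empty -> derived grid
    its_n_timescales: int = 5
    lag_tolerance: float = 0.10
    micro_lag_ns: float = DEFAULT_MICRO_LAG_NS        # fallback if ITS converged lag absent
    micro_lag_mode: str = "auto"             # "auto" (select_lag) | "fixed"
    macro_lag_ns: float = DEFAULT_MACRO_LAG_NS
    n_macrostates: int | str = "auto"
    reversible: bool = True

    # structural summaries
    hbond_distance_cutoff: float = structure.HBOND_DIST_CUTOFF
    hbond_angle_cutoff: float = structure.HBOND_ANGLE_CUTOFF
    sasa_probe_radius: float = structure.SASA_PROBE_RADIUS
    sasa_n_points: int = structure.SASA_N_POINTS
    centroid_max_members: int = 4000

    # external conformations to project (PDB paths)
    external_structures: list = field(default_factory=list)

    seed: int = 2018

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _frame_interval(config: AnalysisConfig) -> float:
    if config.mode == "synthetic":
        syn = config.synthetic or {}
        return float(syn.get("frame_interval", 1.0))
    if config.frame_interval is None:
        raise ValueError("frame_interval (ns) is required for file inputs")
    return float(config.frame_interval)


def _write_csv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return str(path)


def run_pipeline(config: AnalysisConfig, outdir, until: str | None = None) -> dict:
    """Execute the analysis and write all artifacts under ``outdir``.

    Returns the manifest (also written as ``manifest.json``).  Stages
    that do not apply (structural summaries on synthetic dihedral data,
    a non-converged lag selection) are reported as skipped with a
    status, mirroring the non-convergence path of a real loop whose
    slow process is under-sampled.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dt = _frame_interval(config)
    manifest = {
        "seed": config.seed,
        "frame_interval_ns": dt,
        "config": asdict(config),
        "stages": {},
        "artifacts": [],
        "results": {},
    }
    art = manifest["artifacts"]
    config.to_yaml(outdir / "config.yaml")
    art.append(str(outdir / "config.yaml"))

    def done(stage, status="ok", **extra):
        manifest["stages"][stage] = {"status": status, **extra}
        logger.info("stage %-10s %s", stage, status)
        if until is not None and stage == until:
            _finish(manifest, outdir)
            return True
        return False

    # ---------------- featurize ----------------
    ensemble = selection = None
    true_labels = None
    if config.mode == "synthetic":
        spec = synthetic.SyntheticSpec.from_dict(config.synthetic or {})
        spec.seed = config.seed
        series, true_labels = synthetic.generate_hmm_trajectories(spec)
        np.savetxt(outdir / "true_hidden_labels.txt",
                   np.concatenate(true_labels), fmt="%d")
        art.append(str(outdir / "true_hidden_labels.txt"))
    elif config.mode == "files":
        ensemble = trajio.load_ensemble(
            config.trajectories, config.topology, dt)
        selection = trajio.select_loop(ensemble, config.loop)
        series = featurize.backbone_dihedrals(ensemble, selection)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    embed = featurize.circular_embed if config.feature_type == "sincos" \
        else featurize.raw_features
    feats = embed(series)
    if done("featurize", n_trajectories=len(feats.data),
            n_frames=feats.n_frames, n_features=feats.n_features,
            omitted_angles=series.omitted):
        return manifest

    # ---------------- tICA ----------------
    model = tica.estimate_tica(feats, lag=config.tica_lag_ns,
                               n_components=config.n_components)
    proj = tica.project(model, feats)
    model.save(outdir / "tica_model.npz")
    art.append(str(outdir / "tica_model.npz"))
    eig_df = pd.DataFrame({
        "component": np.arange(1, len(model.eigenvalues) + 1),
        "eigenvalue": model.eigenvalues,
        "cumulative_fraction": model.cumulative_eigenvalue_fraction(),
    })
    art.append(_write_csv(eig_df, outdir / "tica_eigenvalues.csv"))
    manifest["results"]["tica_eigenvalues"] = model.eigenvalues[:8].tolist()
    if done("tica", lag_frames=model.lag_frames):
        return manifest

    # ---------------- density ----------------
    grid2 = density.kde(proj, dims=(0, 1), stride=config.kde_stride)
    art.extend(grid2.export(outdir / "kde_tic1_tic2"))
    modes = density.find_modes(grid2, config.mode_prominence)
    modes_df = pd.DataFrame(
        [{"tic1": m[0][0], "tic2": m[0][1], "density": m[1]} for m in modes]
    )
    art.append(_write_csv(modes_df, outdir / "density_modes.csv"))
    manifest["results"]["n_density_modes"] = len(modes)
    marginals = {}
    for d in range(min(8, proj.n_components)):
        g1 = density.kde(proj, dims=(d,), stride=config.kde_stride)
        marginals[d] = g1
        art.extend(g1.export(outdir / f"kde_tic{d + 1}"))
    if done("density", n_modes=len(modes)):
        return manifest

    # ---------------- microstate clustering ----------------
    stacked = proj.stacked()
    n_total = stacked.shape[0]
    fit_stride = max(1, int(np.ceil(n_total / config.max_fit_frames)))
    fitted = cluster_mod.kmedoids(stacked[::fit_stride], config.n_clusters,
                                  seed=config.seed)
    labels_flat = cluster_mod.assign(fitted, stacked)
    labels = []
    start = 0
    for ln in proj.n_frames:
        labels.append(labels_flat[start:start + ln])
        start += ln
    art.append(_write_csv(cluster_mod.labels_to_dataframe(labels),
                          outdir / "microstate_labels.csv"))
    if done("cluster", k=config.n_clusters, fit_stride=fit_stride,
            cost=fitted.total_cost):
        return manifest

    # ---------------- microstate MSM ----------------
    if config.its_lags_ns:
        lags_frames = sorted({tica.lag_to_frames(l, dt) for l in config.its_lags_ns})
    else:
        shortest = min(proj.n_frames)
        base = [1, 2, 3, 5, 8, 12, 18, 27, 40]
        lags_frames = [l for l in base if l < shortest // 10]
    its = msm.implied_timescales(labels, lags_frames,
                                 n_timescales=config.its_n_timescales,
                                 reversible=config.reversible,
                                 frame_interval=dt)
    art.append(_write_csv(its.to_dataframe(), outdir / "implied_timescales.csv"))
    sel = msm.select_lag(its, tolerance=config.lag_tolerance)
    manifest["results"]["lag_selection"] = {
        "converged": sel.converged, "lag_frames": sel.lag_frames,
        "lag_ns": sel.lag_ns, "status": sel.status,
    }
    if config.micro_lag_mode == "fixed":
        micro_lag = tica.lag_to_frames(config.micro_lag_ns, dt)
    elif sel.converged:
        micro_lag = sel.lag_frames
    else:
        micro_lag = None
    if micro_lag is None:
        done("msm", status="not converged",
             detail="implied timescales do not converge over the lag grid; "
                    "no microstate model built")
        done("macro", status="skipped", detail="no converged microstate model")
        done("structure", status="skipped")
        done("external", status="skipped")
        _finish(manifest, outdir)
        return manifest
    micro = msm.estimate_msm(labels, micro_lag, reversible=config.reversible,
                             frame_interval=dt)
    pop_df = pd.DataFrame({
        "microstate": micro.active_states,
        "population": micro.stationary,
    })
    art.append(_write_csv(pop_df, outdir / "microstate_populations.csv"))
    if done("msm", lag_frames=micro_lag, n_active=micro.n_states):
        return manifest

    # ---------------- macrostates ----------------
    micro_its = micro.implied_timescales_frames(
        min(micro.n_states - 1, max(config.its_n_timescales, 5)))
    slowest = np.nanmax(micro_its) if np.any(np.isfinite(micro_its)) else np.nan
    if not np.isfinite(slowest) or slowest <= micro_lag:
        # every relaxation process is faster than the model's own lag:
        # nothing metastable to coarse-grain
        done("macro", status="skipped",
             detail="no slow process: all implied timescales at or below the "
                    "model lag")
        done("structure", status="skipped")
        done("external", status="skipped")
        _finish(manifest, outdir)
        return manifest
    if config.n_macrostates == "auto":
        choice = macrostates.choose_macrostate_count(micro_its,
                                                     floor=float(micro_lag))
        m = choice.m
        manifest["results"]["macrostate_count_choice"] = {
            "m": m, "gap_ratio": (None if not np.isfinite(choice.gap_ratio)
                                  else choice.gap_ratio),
            "confident": choice.confident,
        }
    else:
        m = int(config.n_macrostates)
    macro = macrostates.pcca_plus(micro, m)
    macro_lag = tica.lag_to_frames(config.macro_lag_ns, dt)
    macro = macrostates.macrostate_msm(macro, labels, macro_lag,
                                       frame_interval=dt,
                                       reversible=config.reversible)
    coarse = macro.coarse_model

    # centroids in tICA space, per crisp macrostate
    macro_seqs = macrostates.map_micro_labels(labels, macro.crisp_map,
                                              micro.active_states)
    macro_flat = np.concatenate(macro_seqs)
    ids = [(t, f) for t, ln in enumerate(proj.n_frames) for f in range(ln)]
    centroids = []
    for s in range(m):
        members = np.flatnonzero(macro_flat == s)
        cid = macrostates.cluster_centroid(
            stacked[members], [ids[i] for i in members],
            max_members=config.centroid_max_members)
        centroids.append(cid)
    macro.centroids = centroids

    report = {
        "m": m,
        "populations_eigen": coarse.stationary.tolist(),
        "populations_membership": macro.coarse_pi_membership.tolist(),
        "transition_matrix": coarse.transition_matrix.tolist(),
        "jump_probabilities": macro.jump_probabilities().tolist(),
        "macro_lag_frames": macro_lag,
        "macro_lag_ns": macro_lag * dt,
        "metastability": macro.metastability,
        "centroid_frames": [list(map(int, c)) for c in centroids],
    }
    with open(outdir / "macrostates.json", "w") as fh:
        json.dump(report, fh, indent=2)
    art.append(str(outdir / "macrostates.json"))
    art.append(_write_csv(
        pd.DataFrame(coarse.transition_matrix,
                     columns=[f"to_state_{j + 1}" for j in range(m)]),
        outdir / "macro_transition_matrix.csv"))
    art.append(_write_csv(
        pd.DataFrame({"state": np.arange(1, m + 1),
                      "population_eigen": coarse.stationary,
                      "population_membership": macro.coarse_pi_membership}),
        outdir / "macro_populations.csv"))
    macro_labels_df = pd.DataFrame({
        "trajectory": np.repeat(np.arange(len(macro_seqs)),
                                [len(s) for s in macro_seqs]),
        "frame": np.concatenate([np.arange(len(s)) for s in macro_seqs]),
        "macrostate": macro_flat,
    })
    art.append(_write_csv(macro_labels_df, outdir / "macrostate_labels.csv"))
    manifest["results"]["n_macrostates"] = m
    if true_labels is not None:
        from sklearn.metrics import adjusted_rand_score
        mask = macro_flat >= 0
        ari = adjusted_rand_score(np.concatenate(true_labels)[mask],
                                  macro_flat[mask])
        manifest["results"]["ari_vs_true_hidden"] = float(ari)
    if done("macro", m=m):
        return manifest

    # ---------------- structural summaries ----------------
    if ensemble is None:
        if done("structure", status="skipped",
                detail="synthetic dihedral input carries no Cartesian coordinates"):
            return manifest
    else:
        rows = []
        for s, (t, f) in enumerate(centroids):
            trajio.write_frame(ensemble, t, f,
                               outdir / f"centroid_state{s + 1}.pdb",
                               atom_indices=selection.atoms_all)
            art.append(str(outdir / f"centroid_state{s + 1}.pdb"))
            rows.append({
                "state": s + 1, "trajectory": t, "frame": f,
                "sasa_A2": structure.sasa(
                    ensemble, t, f, selection,
                    probe=config.sasa_probe_radius,
                    n_points=config.sasa_n_points),
            })
        art.append(_write_csv(pd.DataFrame(rows), outdir / "state_sasa.csv"))
        table = structure.centroid_dihedral_table(ensemble, centroids, selection)
        art.append(_write_csv(table, outdir / "centroid_dihedrals.csv"))
        if done("structure"):
            return manifest

    # ---------------- external projections ----------------
    if config.external_structures and ensemble is not None:
        rows = []
        for path in config.external_structures:
            ext = trajio.load_structure(path)
            ext_sel = trajio.select_loop(ext, config.loop)
            ext_series = featurize.backbone_dihedrals(ext, ext_sel)
            ext_feats = embed(ext_series)
            coords = tica.project_external(model, ext_feats.stacked())
            rows.append({"structure": Path(path).stem,
                         **{f"tic{j + 1}": float(c)
                            for j, c in enumerate(coords[0][:8])}})
        art.append(_write_csv(pd.DataFrame(rows),
                              outdir / "external_projections.csv"))
        done("external", n=len(rows))
    else:
        done("external", status="skipped",
             detail="no external structures configured" if ensemble is not None
             else "synthetic input")

    _finish(manifest, outdir)
    return manifest


def _finish(manifest: dict, outdir: Path) -> None:
    target = str(outdir / "manifest.json")
    if target not in manifest["artifacts"]:
        manifest["artifacts"].append(target)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def render_reports(outdir) -> list:
    """Render figures from a completed run directory.

    Figures are views of the persisted artifacts only.  Missing
    artifacts are listed and skipped.  Each figure gets a sidecar JSON
    with the numbers it displays.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    made, skipped = [], []

    def sidecar(path, payload):
        side = path.with_suffix(".json")
        with open(side, "w") as fh:
            json.dump(payload, fh, indent=2)
        made.append(str(side))

    # 1-D marginal densities of the first tICs
    marg = sorted(outdir.glob("kde_tic[0-9].density.txt"))
    if marg:
        fig, axes = plt.subplots(2, 4, figsize=(14, 6))
        for ax, p in zip(axes.ravel(), marg):
            name = p.name.split(".")[0]
            axis = np.loadtxt(outdir / f"{name}.axis0.txt")
            dens = np.loadtxt(p)
            ax.plot(axis, dens)
            ax.set_xlabel(name.replace("kde_", ""))
            ax.set_ylabel("density")
        for ax in axes.ravel()[len(marg):]:
            ax.axis("off")
        fig.tight_layout()
        p = outdir / "fig_tic_marginals.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(str(p))
    else:
        skipped.append("fig_tic_marginals: no 1-D KDE artifacts")

    # 2-D density with centroid / external overlays
    dens2 = outdir / "kde_tic1_tic2.density.txt"
    if dens2.exists():
        x = np.loadtxt(outdir / "kde_tic1_tic2.axis0.txt")
        y = np.loadtxt(outdir / "kde_tic1_tic2.axis1.txt")
        z = np.loadtxt(dens2)
        fig, ax = plt.subplots(figsize=(7, 6))
        cs = ax.contourf(x, y, z.T, levels=30, cmap="viridis")
        fig.colorbar(cs, ax=ax, label="density")
        payload = {"n_modes": None, "centroids": [], "external": []}
        modes_csv = outdir / "density_modes.csv"
        if modes_csv.exists():
            md = pd.read_csv(modes_csv)
            payload["n_modes"] = len(md)
            ax.plot(md["tic1"], md["tic2"], "w+", ms=10, label="modes")
        macro_json = outdir / "macrostates.json"
        if macro_json.exists():
            rep = json.loads(macro_json.read_text())
            payload["centroids"] = rep["centroid_frames"]
        ext_csv = outdir / "external_projections.csv"
        if ext_csv.exists():
            ed = pd.read_csv(ext_csv)
            ax.plot(ed["tic1"], ed["tic2"], "r*", ms=14, label="external")
            payload["external"] = ed.to_dict(orient="records")
            ax.legend()
        ax.set_xlabel("tIC 1")
        ax.set_ylabel("tIC 2")
        p = outdir / "fig_tic1_tic2_density.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(str(p))
        sidecar(p, payload)
    else:
        skipped.append("fig_tic1_tic2_density: no 2-D KDE artifact")

    # macrostate jump-probability graph
    macro_json = outdir / "macrostates.json"
    if macro_json.exists():
        import networkx as nx

        rep = json.loads(macro_json.read_text())
        jump = np.array(rep["jump_probabilities"])
        m = rep["m"]
        g = nx.DiGraph()
        for i in range(m):
            g.add_node(i + 1, population=rep["populations_eigen"][i])
        arrows = []
        for i in range(m):
            for j in range(m):
                if i != j and jump[i, j] > 0:
                    g.add_edge(i + 1, j + 1, weight=jump[i, j])
                    arrows.append({"from": i + 1, "to": j + 1,
                                   "jump_probability": float(jump[i, j]),
                                   "arrow_width": float(12.0 * jump[i, j])})
        pos = nx.circular_layout(g)
        fig, ax = plt.subplots(figsize=(6, 6))
        sizes = 4000 * np.array(rep["populations_eigen"])
        nx.draw_networkx_nodes(g, pos, node_size=sizes, ax=ax,
                               node_color="lightsteelblue")
        nx.draw_networkx_labels(g, pos, ax=ax)
        for a in arrows:
            nx.draw_networkx_edges(
                g, pos, edgelist=[(a["from"], a["to"])],
                width=a["arrow_width"], ax=ax,
                connectionstyle="arc3,rad=0.15", arrows=True)
        ax.axis("off")
        p = outdir / "fig_macrostate_graph.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(str(p))
        sidecar(p, {"arrow_width_per_probability": 12.0, "arrows": arrows})
    else:
        skipped.append("fig_macrostate_graph: no macrostate artifact")

    # per-centroid phi/psi chart
    dtab = outdir / "centroid_dihedrals.csv"
    if dtab.exists():
        df = pd.read_csv(dtab)
        fig, axes = plt.subplots(1, 2, figsize=(14, 5), sharey=True)
        for ax, angle in zip(axes, ("phi", "psi")):
            sub = df[df["angle"] == angle]
            for state, grp in sub.groupby("state"):
                ax.plot(grp["residue"], grp["value_deg"], "o-", label=state)
            ax.set_title(angle)
            ax.set_ylabel("degrees")
            ax.tick_params(axis="x", rotation=60)
        axes[0].legend()
        fig.tight_layout()
        p = outdir / "fig_centroid_dihedrals.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        made.append(str(p))
    else:
        skipped.append("fig_centroid_dihedrals: no centroid dihedral table")

    if skipped:
        logger.info("skipped figures: %s", "; ".join(skipped))
    return made
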