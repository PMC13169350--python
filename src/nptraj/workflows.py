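"""Workflow orchestration: the three report bundles.

Each workflow reads its inputs, runs the relevant stages, writes tidy TSV
reports into an output directory, and finishes by atomically writing a run
manifest (config snapshot, package version, input/output checksums, seeds,
warnings). Deterministic stages regenerate byte-identical outputs from the
same manifest inputs; stochastic stages are seed-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import (ContactConfig, average_contact_ratios,
                       rank_binding_motifs, replicate_contacts)
from .errors import ConfigError, NptrajError
from .hbond import (HBondConfig, count_distribution_bootstrap,
                    hbond_count_series, occupancy_table)
from .md_io import (RegionScheme, Selection, read_pdb_trajectory,
                    write_bfactor_projection, read_xvg_series)
from .pulling import (PullTrace, detachment_distance, profile_over_distance,
                      work_integral)
from .traj_metrics import (com_distance_series, contact_count_series,
                           moving_average, phase_statistics, rmsd_series,
                           rmsf_profile, sasa_series, pca_project)
from .wham import (WhamConfig, block_convergence, bootstrap_pmf,
                   extract_binding_energy, overlap_histograms,
                   read_window_manifest, wham_solve)

__all__ = [
    "RunConfig",
    "load_config",
    "run_conformation_workflow",
    "run_interface_workflow",
    "run_free_energy_workflow",
]


@dataclass
class RunConfig:
    """Materialized configuration of one workflow run."""

    workflow: str
    inputs: dict
    params: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "nptraj_out"

    def effective(self, defaults: dict) -> dict:
        """Defaults overlaid with user parameters; echoed into the manifest
        so no default can change silently."""
        merged = dict(defaults)
        merged.update(self.params)
        return merged


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "workflow" not in raw:
        raise ConfigError(f"{path}: config must be a mapping with a 'workflow' key")
    cfg = RunConfig(
        workflow=raw["workflow"],
        inputs=raw.get("inputs", {}),
        params=raw.get("params", {}),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir", "nptraj_out"),
    )
    for key, val in cfg.inputs.items():
        for p in (val if isinstance(val, list) else [val]):
            if isinstance(p, str) and not Path(p).exists():
                raise ConfigError(f"input file {p} (inputs.{key}) does not exist")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, effective_params: dict,
                    inputs: list[str], outputs: list[Path],
                    warnings_list: list[str]) -> Path:
    manifest = {
        "workflow": cfg.workflow,
        "nptraj_version": __version__,
        "seed": cfg.seed,
        "config": {"inputs": cfg.inputs, "params": effective_params,
                   "out_dir": str(cfg.out_dir)},
        "input_checksums": {str(p): _sha256(Path(p)) for p in inputs
                            if Path(p).is_file()},
        "output_checksums": {p.name: _sha256(p) for p in outputs},
        "warnings": warnings_list,
    }
    path = out / "manifest.json"
    tmp = out / ".manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, path)
    return path


def _series_frame(entries: list[tuple[str, object, object]]) -> pd.DataFrame:
    rows = []
    for replicate, raw, smoothed in entries:
        for t, v, s in zip(raw.times, raw.values, smoothed.values):
            rows.append({"replicate": replicate, "time_ns": t,
                         "metric": raw.label, "value": v, "smoothed_value": s})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Conformation workflow
# ---------------------------------------------------------------------------

CONFORMATION_DEFAULTS = {
    "smoothing_window_ns": 200.0,
    "phase_boundaries_ns": [[0.0, 750.0], [750.0, 2000.0]],
    "contact_cutoff_nm": 0.45,
    "region_core": [39, 130],
    "region_dangling": [131, 191],
    "chains": ["A", "B"],
    "n_boot": 1000,
    "hbond_pairs": [],
    "run_sasa": False,
    "run_pca": False,
}


def run_conformation_workflow(cfg: RunConfig) -> Path:
    """Fig-1-style conformational report: RMSD/COM/contacts (+ optional SASA
    and PCA), phase statistics, H-bond count distribution with bootstrap
    errors, and an H-bond occupancy table when pairs are configured."""
    p = cfg.effective(CONFORMATION_DEFAULTS)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warn: list[str] = []

    paths = cfg.inputs.get("trajectories", [])
    if not paths:
        raise ConfigError("conformation workflow needs inputs.trajectories")
    trajs = [read_pdb_trajectory(p_) for p_ in paths]
    scheme = RegionScheme(tuple(p["region_core"]), tuple(p["region_dangling"]))
    chains = p["chains"]
    dang_a = scheme.dangling_selection([chains[0]])
    dang_b = scheme.dangling_selection([chains[1]]) if len(chains) > 1 else dang_a
    dangling = scheme.dangling_selection(chains)
    core = scheme.core_selection(chains)
    window = float(p["smoothing_window_ns"])

    entries, per_metric = [], {}
    for i, traj in enumerate(trajs):
        rep = f"rep{i + 1}"
        ref = traj.coords[-1]
        series = [
            rmsd_series(traj, ref, dangling, dangling, label="rmsd_dangling"),
            com_distance_series(traj, dang_a, dang_b, label="com_distance"),
            contact_count_series(traj, dang_a, dang_b,
                                 p["contact_cutoff_nm"], label="arm_contacts"),
        ]
        if p["run_sasa"]:
            series.append(sasa_series(traj, Selection.protein(), label="sasa"))
        for s in series:
            entries.append((rep, s, moving_average(s, window)))
            per_metric.setdefault(s.label, []).append(s)

    _series_frame(entries).to_csv(out / "metrics.tsv", sep="\t", index=False)

    boundaries = [tuple(b) for b in p["phase_boundaries_ns"]]
    summary = phase_statistics(per_metric, boundaries)
    rows = []
    for label, stats in summary.stats.items():
        for (lo, hi), (m, sd) in zip(boundaries, stats):
            rows.append({"metric": label, "phase_start_ns": lo,
                         "phase_end_ns": hi, "mean": m, "sd": sd})
    pd.DataFrame(rows).to_csv(out / "phase_statistics.tsv", sep="\t",
                              index=False)

    rmsf_rows = []
    for i, traj in enumerate(trajs):
        try:
            prof = rmsf_profile(traj, core, Selection.protein())
        except NptrajError as exc:
            raise type(exc)(f"rmsf stage: {exc}") from exc
        for (chain, rid), v in prof.items():
            rmsf_rows.append({"replicate": f"rep{i + 1}", "chain": chain,
                              "residue_id": rid, "rmsf_nm": v})
    pd.DataFrame(rmsf_rows).to_csv(out / "rmsf.tsv", sep="\t", index=False)

    hb_series = [hbond_count_series(t, dang_a, dang_b) for t in trajs]
    dist = count_distribution_bootstrap(hb_series, boundaries,
                                        n_boot=int(p["n_boot"]), seed=cfg.seed)
    drows = []
    for (lo, hi), df in dist.items():
        for _, r in df.iterrows():
            drows.append({"state_start_ns": lo, "state_end_ns": hi,
                          "count": int(r["count"]),
                          "percentage": r["percentage"],
                          "bootstrap_sd": r["bootstrap_sd"]})
    pd.DataFrame(drows).to_csv(out / "hbond_distribution.tsv", sep="\t",
                               index=False)

    outputs = [out / "metrics.tsv", out / "phase_statistics.tsv",
               out / "rmsf.tsv", out / "hbond_distribution.tsv"]

    if p["hbond_pairs"]:
        pairs = [((d[0], int(d[1])), (a[0], int(a[1])))
                 for d, a in p["hbond_pairs"]]
        occ = occupancy_table(trajs, pairs, HBondConfig())
        occ.to_csv(out / "hbond_occupancy.tsv", sep="\t", index=False)
        outputs.append(out / "hbond_occupancy.tsv")

    if p["run_pca"]:
        projs, explained = pca_project(trajs, Selection.protein())
        prow = []
        for i, pr in enumerate(projs):
            for f in range(pr.shape[0]):
                prow.append({"replicate": f"rep{i + 1}", "frame": f,
                             "pc1": pr[f, 0], "pc2": pr[f, 1]})
        df = pd.DataFrame(prow)
        df.attrs["explained_variance"] = explained.tolist()
        df.to_csv(out / "pca_projection.tsv", sep="\t", index=False)
        outputs.append(out / "pca_projection.tsv")

    _write_manifest(out, cfg, p, paths, outputs, warn)
    return out


# ---------------------------------------------------------------------------
# Interface workflow
# ---------------------------------------------------------------------------

INTERFACE_DEFAULTS = {
    "contact_cutoff_nm": 0.45,
    "motif_min_len": 3,
    "motif_threshold": 0.5,
    "project_structure": True,
}


def run_interface_workflow(cfg: RunConfig) -> Path:
    """Nanoparticle-interface report: per-replicate and averaged conditional
    contact ratios, ranked binding motifs, and a contact-ratio-coloured
    structure projection."""
    p = cfg.effective(INTERFACE_DEFAULTS)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warn: list[str] = []

    paths = cfg.inputs.get("replicates", [])
    if not paths:
        raise ConfigError("interface workflow needs inputs.replicates")
    ccfg = ContactConfig(cutoff_nm=float(p["contact_cutoff_nm"]))
    trajs = [read_pdb_trajectory(p_) for p_ in paths]
    for i, t in enumerate(trajs):
        if ccfg.nanoparticle_selection.resolve(t.topology).size == 0:
            raise ConfigError(f"replicate {paths[i]} contains no Au atoms")

    reps = [replicate_contacts(t, ccfg) for t in trajs]
    for i, r in enumerate(reps):
        if r.no_contact:
            warn.append(f"replicate {i + 1} never contacts the nanoparticle; "
                        "excluded from the average")
    per_rows = []
    for i, r in enumerate(reps):
        df = r.to_frame()
        df.insert(0, "replicate", f"rep{i + 1}")
        per_rows.append(df)
    pd.concat(per_rows).to_csv(out / "contact_ratio_per_replicate.tsv",
                               sep="\t", index=False)

    table = average_contact_ratios(reps)
    table.to_frame().to_csv(out / "contact_ratio_averaged.tsv", sep="\t",
                            index=False)

    motifs, sites = rank_binding_motifs(table, int(p["motif_min_len"]),
                                        float(p["motif_threshold"]))
    mrows = [{"kind": "motif", "chain": m.chain,
              "residues": "-".join(map(str, m.residue_ids)),
              "sequence": m.sequence, "mean_ratio": m.mean_ratio}
             for m in motifs]
    mrows += [{"kind": "site", "chain": m.chain,
               "residues": "-".join(map(str, m.residue_ids)),
               "sequence": m.sequence, "mean_ratio": m.mean_ratio}
              for m in sites]
    pd.DataFrame(mrows, columns=["kind", "chain", "residues", "sequence",
                                 "mean_ratio"]
                 ).to_csv(out / "binding_motifs.tsv", sep="\t", index=False)

    outputs = [out / "contact_ratio_per_replicate.tsv",
               out / "contact_ratio_averaged.tsv", out / "binding_motifs.tsv"]
    if p["project_structure"]:
        traj = trajs[0]
        write_bfactor_projection(traj.topology, traj.coords[-1],
                                 table.as_dict(),
                                 out / "contact_ratio_projection.pdb")
        outputs.append(out / "contact_ratio_projection.pdb")

    _write_manifest(out, cfg, p, paths, outputs, warn)
    return out


# ---------------------------------------------------------------------------
# Free-energy workflow
# ---------------------------------------------------------------------------

FREE_ENERGY_DEFAULTS = {
    "temperature_k": 310.0,
    "bias_convention": "full",
    "n_bins": 200,
    "n_boot": 20,
    "block_ends_ps": [],
    "pull_rate_nm_per_ps": 0.0008,
    "spring_k": 1000.0,
    "grid_step_nm": 0.05,
    "drop_fraction": 0.1,
}


def run_free_energy_workflow(cfg: RunConfig) -> Path:
    """Umbrella-sampling report: WHAM PMF with bootstrap band, window
    overlap diagnostics, optional block-convergence profiles and binding
    energy; plus SMD force profile, detachment distance and pulling work
    when force traces are supplied."""
    p = cfg.effective(FREE_ENERGY_DEFAULTS)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warn: list[str] = []

    manifest_path = cfg.inputs.get("window_manifest")
    if not manifest_path:
        raise ConfigError("free-energy workflow needs inputs.window_manifest")
    windows = read_window_manifest(manifest_path)
    wcfg = WhamConfig(temperature_k=float(p["temperature_k"]),
                      n_bins=int(p["n_bins"]),
                      bias_convention=p["bias_convention"])
    pmf = wham_solve(windows, wcfg)
    pmf.bootstrap_sd = bootstrap_pmf(windows, wcfg, n_boot=int(p["n_boot"]),
                                     seed=cfg.seed)
    pmf.to_frame().to_csv(out / "pmf.tsv", sep="\t", index=False)
    pd.DataFrame({
        "window_id": [w.window_id for w in windows],
        "r_nm": [w.r_nm for w in windows],
        "f_kj_mol": pmf.window_free_energies_kj,
    }).to_csv(out / "window_free_energies.tsv", sep="\t", index=False)

    edges = np.linspace(min(w.samples.min() for w in windows),
                        max(w.samples.max() for w in windows),
                        int(p["n_bins"]) + 1)
    _, overlaps = overlap_histograms(windows, edges)
    overlaps.to_csv(out / "window_overlaps.tsv", sep="\t", index=False)
    outputs = [out / "pmf.tsv", out / "window_free_energies.tsv",
               out / "window_overlaps.tsv"]

    try:
        est = extract_binding_energy(pmf)
        pd.DataFrame([{
            "delta_g": est.delta_g, "unit": est.unit,
            "minimum_nm": est.minimum_nm,
            "plateau_start_nm": est.plateau_interval_nm[0],
            "plateau_end_nm": est.plateau_interval_nm[1],
            "criterion": est.criterion,
            "bias_convention": pmf.bias_convention,
        }]).to_csv(out / "binding_energy.tsv", sep="\t", index=False)
        outputs.append(out / "binding_energy.tsv")
    except NptrajError as exc:
        warn.append(f"binding-energy stage: {exc}")

    if p["block_ends_ps"]:
        profiles, deltas, dropped = block_convergence(
            windows, [float(b) for b in p["block_ends_ps"]], wcfg)
        rows = []
        for t_end, prof in zip(p["block_ends_ps"], profiles):
            for x, g in zip(prof.bin_centers_nm, prof.free_energy):
                rows.append({"block_end_ps": t_end, "bin_center_nm": x,
                             "G": g})
        pd.DataFrame(rows).to_csv(out / "block_profiles.tsv", sep="\t",
                                  index=False)
        outputs.append(out / "block_profiles.tsv")
        for blk, dr in zip(p["block_ends_ps"], dropped):
            if dr:
                warn.append(f"block {blk} ps: dropped empty windows {dr}")

    force_files = cfg.inputs.get("force_traces", [])
    if force_files:
        traces = []
        for fpath in force_files:
            t, f = read_xvg_series(fpath)
            traces.append(PullTrace(t, f,
                                    pull_rate=float(p["pull_rate_nm_per_ps"]),
                                    spring_k=float(p["spring_k"])))
        profile = profile_over_distance(traces, float(p["grid_step_nm"]))
        profile.to_frame().to_csv(out / "force_profile.tsv", sep="\t",
                                  index=False)
        det, unruptured = detachment_distance(profile,
                                              float(p["drop_fraction"]))
        pd.DataFrame([{
            "replicate": f"rep{i + 1}",
            "peak_force": tr.force.max(),
            "peak_distance_nm": tr.pull_distance[int(np.argmax(tr.force))],
            "work_kj_mol": work_integral(tr),
        } for i, tr in enumerate(traces)] + [{
            "replicate": "profile",
            "peak_force": profile.mean_force.max(),
            "peak_distance_nm": det,
            "work_kj_mol": float("nan"),
        }]).to_csv(out / "pulling_summary.tsv", sep="\t", index=False)
        if unruptured:
            warn.append("force profile never drops below threshold; "
                        "detachment flagged as unruptured")
        outputs += [out / "force_profile.tsv", out / "pulling_summary.tsv"]

    inputs = [manifest_path] + list(force_files)
    _write_manifest(out, cfg, p, inputs, outputs, warn)
    return out
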