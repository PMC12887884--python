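"""End-to-end orchestration: build structures, run BD, analyze, report.

A single YAML config drives the whole chain: synthetic fibril + glycan
construction, the BD ensemble, the binding-site table, pose filtering and
clustering with a rigid-body refinement stand-in, contact statistics, and
the sulfur density map.  Re-running with the same config and seed produces
byte-identical tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bd_engine import BDParams, run_ensemble
from .contact_analysis import (ContactParams, contacts_from_outcomes,
                               frequency_map, median_bound)
from .density_maps import accumulate, grid_for_fibril, write_dx
from .electrostatics import SolventParams, force_torque_on_glycan
from .model_builder import (build_cross_section, build_fibril, build_glycan,
                            tau_core_template, write_glycan_pdb, write_pdb)
from .pose_analysis import filter_and_cluster
from .site_statistics import site_table

log = logging.getLogger("gagbind")

DEFAULT_CONFIG = {
    "seed": 0,
    "structure": {
        "template": "tau_core",       # or explicit "sequence"
        "sequence": None,
        "start_number": 1,
        "layout": "C_shape",
        "buried": [],
        "n_layers": 10,
        "rise": 4.8,
        "twist_deg": 0.0,
        "n_protofilaments": 1,
        "glycan_length": 8,
        "sulfation_pattern": "full",
        "repeat_rise": 8.7,
    },
    "bd": {
        "temperature": 310.15,
        "dielectric": 78.0,
        "relative_viscosity": 1.0,
        "ionic_strength": 0.150,
        "dt_far": 1.0,
        "dt_near": 0.01,
        "near_shell": 15.0,
        "reaction_distance": 7.5,
        "reaction_min_contacts": 3,
        "b_radius": None,
        "q_radius": None,
        "max_steps": 10_000_000,
        "hydrodynamic_radius": 8.0,
        "n_fibril_conformations": 1,
        "n_glycan_conformations": 1,
        "n_per_pair": 1000,
    },
    "analysis": {
        "cutoff": 4.5,
        "k_clusters": 10,
        "angle_threshold": 45.0,
        "site_groups": {},
        "refine_iterations": 50,
    },
    "output": {
        "density_spacing": 1.0,
        "density_padding": 15.0,
        "write_structures": True,
    },
}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for block, values in user.items():
        if isinstance(values, dict):
            cfg.setdefault(block, {}).update(values)
        else:
            cfg[block] = values
    return cfg


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def build_structures(cfg: dict):
    s = cfg["structure"]
    if s.get("sequence"):
        template = build_cross_section(
            s["sequence"], start_number=s.get("start_number", 1),
            layout=s["layout"], buried=frozenset(s.get("buried", [])))
    elif s["template"] == "tau_core":
        template = tau_core_template(layout=s["layout"])
    else:
        raise ValueError(f"unknown template {s['template']!r}")
    fibril = build_fibril(template, n_layers=s["n_layers"], rise=s["rise"],
                          twist_deg=s.get("twist_deg", 0.0),
                          n_protofilaments=s.get("n_protofilaments", 1))
    glycan = build_glycan(s["glycan_length"], s["sulfation_pattern"],
                          s["repeat_rise"])
    return fibril, glycan


def bd_params_from_config(cfg: dict) -> BDParams:
    b = cfg["bd"]
    solvent = SolventParams(
        temperature=b["temperature"], dielectric=b["dielectric"],
        relative_viscosity=b["relative_viscosity"],
        ionic_strength=b["ionic_strength"])
    return BDParams(
        solvent=solvent, dt_far=b["dt_far"], dt_near=b["dt_near"],
        near_shell=b["near_shell"], reaction_distance=b["reaction_distance"],
        reaction_min_contacts=b["reaction_min_contacts"],
        b_radius=b["b_radius"], q_radius=b["q_radius"],
        max_steps=b["max_steps"],
        hydrodynamic_radius=b["hydrodynamic_radius"], seed=cfg["seed"])


def refine_pose(fibril, glycan, pose, solvent, n_iter: int = 50,
                translation_step: float = 0.05, rotation_step: float = 0.002):
    """Rigid-body steepest-descent refinement of a bound pose.

    A deliberately simple local minimizer of the screened-Coulomb +
    soft-wall energy (fixed small steps along force and torque, fixed
    iteration cap).  This is a desk-scale stand-in for all-atom refinement
    of bound poses, not molecular dynamics.
    """
    from .geometry import Pose, rotation_from_rotvec
    current = pose.copy()
    _, _, energy = force_torque_on_glycan(fibril, glycan, current, solvent)
    for _ in range(n_iter):
        force, torque, _ = force_torque_on_glycan(fibril, glycan, current,
                                                  solvent)
        fn = np.linalg.norm(force)
        tn = np.linalg.norm(torque)
        if fn < 1e-9 and tn < 1e-9:
            break
        dr = translation_step * force / max(fn, 1e-9)
        dw = rotation_step * torque / max(tn, 1e-9)
        trial = Pose(rotation_from_rotvec(dw) @ current.rotation,
                     current.translation + dr)
        _, _, e_trial = force_torque_on_glycan(fibril, glycan, trial, solvent)
        if e_trial >= energy:
            break
        current, energy = trial, e_trial
    return current, energy


def outcomes_to_frame(outcomes) -> pd.DataFrame:
    return pd.DataFrame([
        {"status": o.status,
         "site": -1 if o.site is None else o.site,
         "n_steps": o.n_steps,
         "stream_id": ":".join(str(x) for x in o.stream_id)}
        for o in outcomes])


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run every stage and write tables, maps, logs, and a manifest.

    Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}
    manifest = {
        "package": "gagbind",
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": config_hash(cfg),
        "outputs": [],
        "status": "running",
    }

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                log.info("stage %s finished in %.2f s", name, timings[name])
        return _T()

    try:
        with stage("build"):
            fibril, glycan = build_structures(cfg)
            if cfg["output"].get("write_structures", True):
                write_pdb(fibril, outdir / "fibril.pdb")
                write_glycan_pdb(glycan, outdir / "glycan.pdb")
                manifest["outputs"] += ["fibril.pdb", "glycan.pdb"]

        params = bd_params_from_config(cfg)
        b = cfg["bd"]
        with stage("bd_ensemble"):
            fibrils = [fibril] * b["n_fibril_conformations"]
            glycans = [glycan] * b["n_glycan_conformations"]
            outcomes = run_ensemble(fibrils, glycans, b["n_per_pair"], params)
            df = outcomes_to_frame(outcomes)
            df.to_csv(outdir / "outcomes.tsv", sep="\t", index=False)
            manifest["outputs"].append("outcomes.tsv")
            manifest["n_trajectories"] = len(outcomes)
            manifest["n_reacted"] = int((df["status"] == "reacted").sum())
            manifest["n_escaped"] = int((df["status"] == "escaped").sum())
            manifest["n_max_steps"] = int((df["status"] == "max_steps").sum())

        a = cfg["analysis"]
        with stage("site_table"):
            table = site_table(outcomes, site_groups=a.get("site_groups"),
                               sites=fibril.site_list)
            table.to_csv(outdir / "site_table.tsv", sep="\t", index=False,
                         float_format="%.6g")
            manifest["outputs"].append("site_table.tsv")

        with stage("pose_analysis"):
            solvent = params.solvent
            reacted_sites = [o.site for o in outcomes if o.status == "reacted"]
            pose_rows = []
            cluster_report = {}
            refined_poses = []
            if reacted_sites:
                top_site = max(set(reacted_sites), key=reacted_sites.count)
                records, clusters = filter_and_cluster(
                    outcomes, fibril, glycan, [top_site],
                    k=a["k_clusters"], angle_threshold=a["angle_threshold"])
                for idx, rec in enumerate(records):
                    lab = int(clusters.labels[idx]) if clusters else 0
                    is_medoid = bool(clusters is not None
                                     and idx in clusters.medoid_indices)
                    pose_rows.append({"pose": idx, "site": rec.bound_site,
                                      "angle": round(rec.angle_to_axis, 4),
                                      "cluster": lab, "is_medoid": is_medoid})
                cluster_report["site"] = int(top_site)
                cluster_report["n_aligned_poses"] = len(records)
                if clusters is not None:
                    cluster_report["k"] = int(clusters.k)
                    cluster_report["medoids"] = [
                        int(m) for m in clusters.medoid_indices]
                    refined_poses, refined = [], []
                    for m in clusters.medoid_indices:
                        rp, e = refine_pose(fibril, glycan, records[m].pose,
                                            solvent,
                                            n_iter=a["refine_iterations"])
                        refined_poses.append(rp)
                        refined.append(round(float(e), 6))
                    cluster_report["refined_medoid_energies_kcal_mol"] = refined
            pd.DataFrame(pose_rows, columns=["pose", "site", "angle",
                                             "cluster", "is_medoid"]).to_csv(
                outdir / "pose_table.tsv", sep="\t", index=False)
            with open(outdir / "clusters.json", "w") as fh:
                json.dump(cluster_report, fh, indent=1, sort_keys=True)
            manifest["outputs"] += ["pose_table.tsv", "clusters.json"]

        with stage("contacts"):
            # contact statistics are computed on the refined bound poses
            # when refinement ran; otherwise on raw reacted BD endpoints
            cparams = ContactParams(a["cutoff"])
            if refined_poses:
                from .contact_analysis import ContactSeries, detect_contacts
                series = ContactSeries()
                for rp in refined_poses:
                    series.append(detect_contacts(rp, fibril, glycan, cparams))
            else:
                series = contacts_from_outcomes(outcomes, fibril, glycan,
                                                cparams)
            medians = {}
            if len(series):
                for which in ("residues", "hcgs"):
                    med, dist = median_bound(series, which)
                    medians[which] = {"median": med, "distribution": {
                        str(k): round(v, 6) for k, v in dist.items()}}
                fmap = frequency_map(series, glycan, fibril)
                fmap.to_csv(outdir / "frequency_map.tsv", sep="\t",
                            float_format="%.6g")
                manifest["outputs"].append("frequency_map.tsv")
            with open(outdir / "contact_medians.json", "w") as fh:
                json.dump(medians, fh, indent=1, sort_keys=True)
            manifest["outputs"].append("contact_medians.json")

        with stage("density"):
            grid = grid_for_fibril(fibril, cfg["output"]["density_spacing"],
                                   cfg["output"]["density_padding"])
            accumulate(outcomes, glycan, grid)
            write_dx(grid, outdir / "sulfur_density.dx")
            manifest["outputs"].append("sulfur_density.dx")
            manifest["density_in_grid"] = float(grid.counts.sum())
            manifest["density_overflow"] = float(grid.overflow)

        manifest["status"] = "ok"
    except Exception as exc:          # record failures in the manifest
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(outdir / "timings.log", "w") as fh:
        for name, dt in timings.items():
            fh.write(f"{name}\t{dt:.3f}s\n")
    return manifest
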