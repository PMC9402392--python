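"""Configuration-driven orchestration: structures → contacts → model →
dynamics/scan → analysis, with full provenance.

A run is described by a single YAML/dict document.  Every defaulted
field is resolved explicitly before anything executes and the resolved
document is written as ``provenance.yaml`` next to the outputs, together
with the package version, seeds and contact class counts — re-running
from the provenance file reproduces the run exactly.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cg_dynamics import IntegratorParams, run_dynamics, write_energy_log, write_trajectory
from .contact_map import build_contact_map, class_counts, write_contact_map
from .sbm_builder import ModelParams, build_topology, export_topology
from .structure_io import read_structure, build_monomer_os_cth, write_structure
from .synthetic_data import ToySpec, make_two_state_toy
from .transition_analysis import (
    TuningError,
    pmf,
    rc_series,
    transition_stats,
    tune_epsilon_cs,
)

__all__ = ["DEFAULT_CONFIG", "resolve_config", "run_pipeline"]

log = logging.getLogger("twostate_sbm")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": {
        # kind: "toy" (generator) or "files" (PDB paths, optional graft)
        "kind": "toy",
        "toy": {"n_lobe1": 14, "n_lobe2": 14, "n_tail": 6,
                "hinge_angle": 100.0},
        "open_pdb": None,
        "closed_pdb": None,
        "graft": None,  # {"dimer_pdb":..., "chain_a":"A", "chain_b":"B",
                        #  "range": [212, 225]}
    },
    "contacts": {
        "mode": "all_atom",  # toy runs override to ca_cutoff
        "cutoff": 0.45,
        "min_seq_sep": 4,
        "ratio": 1.5,
        "cth_range": None,
    },
    "model": {
        "eps_os": 1.0,
        "eps_cs": None,  # None → run the scan block
        "eps_dg": 1.0,
        "eps_ev": 1.0,
        "sigma_nc": 0.4,
        "gauss_width": 0.05,
        "cth_scale": 1.0,
    },
    "scan": {
        "grid": [0.6, 0.9, 1.2, 1.5],
        "min_transitions": 2,
        "population_window": [0.2, 0.8],
        "n_steps": 2_000_000,
    },
    "simulate": {
        "n_steps": 5_000_000,
        "dt": 0.0005,
        "temperature": 100.0,
        "friction": 1.0,
        "save_every": 2000,
    },
    "analysis": {
        "rc_pair": None,  # default: toy suggestion, or [56, 143] for files
        "open_threshold": None,  # default: planted native distances ± 25 %
        "closed_threshold": None,
        "pmf_bins": 50,
    },
}


def _deep_update(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key not in out:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(value, dict) and isinstance(out[key], dict):
            out[key] = _deep_update(out[key], value)
        else:
            out[key] = value
    return out


def resolve_config(config: dict | str | Path | None) -> dict:
    """Merge a user config (dict or YAML path) over the defaults."""
    if config is None:
        config = {}
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    return _deep_update(DEFAULT_CONFIG, config)


def run_pipeline(config: dict | str | Path | None, outdir: str | Path) -> Path:
    """Execute the full workflow into ``outdir`` and return that path.

    Stages: input structures (toy generator, or PDB files with optional
    tail-helix grafting) → contact classification → dual-basin model →
    ε_CS scan (when ``model.eps_cs`` is null) → Langevin dynamics →
    reaction-coordinate/PMF/transition analysis.  Aborts with the stage
    name on failure; outputs of completed stages are preserved.
    """
    cfg = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "structures"
        open_s, closed_s, cfg = _stage_structures(cfg, outdir)

        stage = "contacts"
        cm = build_contact_map(
            open_s, closed_s,
            mode=cfg["contacts"]["mode"],
            cutoff=cfg["contacts"]["cutoff"],
            min_seq_sep=cfg["contacts"]["min_seq_sep"],
            ratio=cfg["contacts"]["ratio"],
            cth_range=tuple(cfg["contacts"]["cth_range"])
            if cfg["contacts"]["cth_range"] else None,
        )
        write_contact_map(cm, outdir / "contacts.tsv")
        counts = class_counts(cm)
        log.info("contacts: %s", counts)

        stage = "model"
        mp = ModelParams(
            eps_os=cfg["model"]["eps_os"],
            eps_cs=cfg["model"]["eps_cs"] or 1.0,
            eps_dg=cfg["model"]["eps_dg"],
            eps_ev=cfg["model"]["eps_ev"],
            sigma_nc=cfg["model"]["sigma_nc"],
            gauss_width=cfg["model"]["gauss_width"],
            cth_scale=cfg["model"]["cth_scale"],
            cth_range=tuple(cfg["contacts"]["cth_range"])
            if cfg["contacts"]["cth_range"] else None,
        )

        sim = cfg["simulate"]
        integrator = IntegratorParams(
            n_steps=int(sim["n_steps"]), dt=sim["dt"],
            temperature=sim["temperature"], friction=sim["friction"],
            save_every=int(sim["save_every"]), seed=cfg["seed"],
        )
        rc_pair = tuple(cfg["analysis"]["rc_pair"])
        open_thr = cfg["analysis"]["open_threshold"]
        closed_thr = cfg["analysis"]["closed_threshold"]

        scan_report = None
        if cfg["model"]["eps_cs"] is None:
            stage = "scan"
            scan_cfg = cfg["scan"]
            scan_p = replace(integrator, n_steps=int(scan_cfg["n_steps"]))
            result = tune_epsilon_cs(
                open_s, cm, mp, scan_p, list(scan_cfg["grid"]),
                rc_pair, open_thr, closed_thr,
                min_transitions=int(scan_cfg["min_transitions"]),
                population_window=tuple(scan_cfg["population_window"]),
            )
            mp = replace(mp, eps_cs=result.eps_cs)
            cfg["model"]["eps_cs"] = result.eps_cs
            scan_report = result.report
            log.info("scan chose eps_cs=%.3f", result.eps_cs)

        top = build_topology(open_s, cm, mp)
        export_topology(top, outdir / "model.json")

        stage = "simulate"
        traj = run_dynamics(top, open_s.ca_coords(), integrator)
        write_trajectory(traj, outdir / "traj.xtc")
        write_energy_log(traj, outdir / "energies.tsv")

        stage = "analyze"
        series = rc_series(traj, top.auth_ids, *rc_pair)
        stats = transition_stats(series, open_thr, closed_thr)
        profile = pmf(series, integrator.temperature,
                      n_bins=int(cfg["analysis"]["pmf_bins"]))
        np.savetxt(outdir / "rc_series.tsv",
                   np.column_stack([series.frame_indices, series.values]),
                   header=f"step\tdistance_nm ({series.descriptor})",
                   delimiter="\t", fmt="%.6g")
        np.savetxt(outdir / "pmf.tsv",
                   np.column_stack([profile.bin_centers, profile.f,
                                    profile.counts]),
                   header="distance_nm\tfree_energy_eps\tcount",
                   delimiter="\t", fmt="%.6g")
        summary = {
            "class_counts": counts,
            "eps_cs": mp.eps_cs,
            "n_transitions": stats.n_transitions,
            "populations": stats.populations,
            "thresholds": [stats.open_threshold, stats.closed_threshold],
            "rc_pair": list(rc_pair),
            "n_frames": len(traj),
        }
        if scan_report is not None:
            summary["scan_report"] = scan_report
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

        stage = "provenance"
        prov = {"config": cfg, "version": __version__,
                "class_counts": counts}
        (outdir / "provenance.yaml").write_text(yaml.safe_dump(prov))
    except TuningError:
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def _stage_structures(cfg: dict, outdir: Path):
    """Produce (open, closed) structures and fill analysis defaults."""
    inp = cfg["input"]
    if inp["kind"] == "toy":
        toy_cfg = dict(inp["toy"])
        toy = make_two_state_toy(ToySpec(seed=cfg["seed"], **toy_cfg))
        open_s, closed_s = toy.open, toy.closed
        if cfg["contacts"]["mode"] == "all_atom":
            cfg["contacts"]["mode"] = "ca_cutoff"
            cfg["contacts"]["cutoff"] = toy.contacts.parameters["cutoff"]
        if cfg["contacts"]["cth_range"] is None and toy.cth_range:
            cfg["contacts"]["cth_range"] = list(toy.cth_range)
        if cfg["analysis"]["rc_pair"] is None:
            cfg["analysis"]["rc_pair"] = list(toy.rc_pair)
        ri, rj = cfg["analysis"]["rc_pair"]
        from .structure_io import ca_distance

        d_open = ca_distance(open_s, ri, rj)
        d_closed = ca_distance(closed_s, ri, rj)
        mid = 0.5 * (d_open + d_closed)
        span = abs(d_open - d_closed)
        if cfg["analysis"]["open_threshold"] is None:
            cfg["analysis"]["open_threshold"] = round(mid + 0.25 * span, 4)
        if cfg["analysis"]["closed_threshold"] is None:
            cfg["analysis"]["closed_threshold"] = round(mid - 0.25 * span, 4)
        write_structure(open_s, outdir / "open.pdb")
        write_structure(closed_s, outdir / "closed.pdb")
    elif inp["kind"] == "files":
        open_s = read_structure(inp["open_pdb"])
        closed_s = read_structure(inp["closed_pdb"])
        if inp["graft"]:
            g = inp["graft"]
            chain_a = read_structure(g["dimer_pdb"], chain=g.get("chain_a", "A"))
            chain_b = read_structure(g["dimer_pdb"], chain=g.get("chain_b", "B"))
            open_s = build_monomer_os_cth(open_s, chain_a, chain_b,
                                          tuple(g.get("range", (212, 225))))
            write_structure(open_s, outdir / "grafted_open.pdb")
        if cfg["analysis"]["rc_pair"] is None:
            cfg["analysis"]["rc_pair"] = [56, 143]
        if cfg["analysis"]["open_threshold"] is None:
            cfg["analysis"]["open_threshold"] = 1.8
        if cfg["analysis"]["closed_threshold"] is None:
            cfg["analysis"]["closed_threshold"] = 1.0
    else:
        raise ValueError(f"unknown input kind {inp['kind']!r}")
    return open_s, closed_s, cfg
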