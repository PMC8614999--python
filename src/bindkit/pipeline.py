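"""Pipeline orchestration: config validation and the end-to-end run.

The pipeline chains the post-processing stages — snapshot sampling, pose
selection, complex assembly, rescoring-table ranking — and any requested
binding-model fits, and writes a single JSON report carrying versions,
seeds, parameters and per-stage outputs so a run is auditable and
reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .binding_thermo import (
    estimate_kd_quench,
    fit_dsc,
    fit_ic50,
    fit_itc_one_site,
    fit_stern_volmer,
)
from .io import (
    read_dose_response_csv,
    read_itc_csv,
    read_pose_ensemble,
    read_rescore_csv,
    read_structures,
    read_thermogram_csv,
    read_titration_csv,
    read_trajectory,
    write_structure_pdb,
)
from .pose_ensemble import build_complexes, rank_rescoring, select_poses
from .traj_analysis import sample_snapshots

logger = logging.getLogger("bindkit")

__all__ = ["PipelineConfig", "run_pipeline"]

_SCHEMA = {
    "seed": 0,
    "output_dir": "bindkit_out",
    "trajectory": None,
    "n_snapshots": None,
    "snapshot_strategy": "stride",
    "poses": None,
    "scores": None,
    "k_score": 10,
    "k_kde": 10,
    "rescore": None,
    "quench_csv": None,
    "itc_csv": None,
    "dsc_csv": None,
    "dsc_transitions": 2,
    "ic50_csv": None,
    "n_boot": 1000,
    "probe_radius": 1.4,
    "temperature": 298.15,
}


@dataclass
class PipelineConfig:
    """Validated stage parameters; unknown keys are rejected at load time."""

    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.params) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(_SCHEMA)
        merged.update(self.params)
        self.params = merged

    def __getitem__(self, key):
        return self.params[key]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config must be a YAML mapping")
        return cls(params=data)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input digest."""


def _stage(name, path=None):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                digest = _digest(path) if path else "n/a"
                raise StageError(f"stage {name!r} failed (input {digest}): {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return (and write) the JSON report."""
    out_dir = Path(config["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "bindkit_version": __version__,
        "seed": config["seed"],
        "parameters": {k: v for k, v in config.params.items() if v is not None},
        "stages": {},
    }

    snapshots = None
    if config["trajectory"]:
        path = config["trajectory"]

        @_stage("sample_snapshots", path)
        def _sample():
            traj = read_trajectory(path)
            n = config["n_snapshots"] or min(10, traj.n_frames)
            idx = sample_snapshots(traj, n, strategy=config["snapshot_strategy"])
            return traj, idx

        traj, idx = _sample()
        # poses key snapshots by sampling ordinal (0 = first sampled frame)
        snapshots = {k: traj.frame(int(i)) for k, i in enumerate(idx)}
        report["stages"]["sample_snapshots"] = {
            "n_frames": traj.n_frames, "selected": [int(i) for i in idx],
        }

    selection = None
    ensemble = None
    if config["poses"]:
        path = config["poses"]

        @_stage("select_poses", path)
        def _select():
            ens = read_pose_ensemble(path, config["scores"])
            if ens.n_poses == 0:
                raise ValueError("pose ensemble is empty")
            return ens, select_poses(ens, config["k_score"], config["k_kde"])

        ensemble, selection = _select()
        report["stages"]["select_poses"] = {
            "n_poses": ensemble.n_poses,
            "score_indices": selection.score_indices.tolist(),
            "kde_indices": selection.kde_indices.tolist(),
            "union_indices": selection.union_indices.tolist(),
            "n_selected": int(selection.union_indices.size),
            "mdcom_A": selection.mdcom,
            "overlap_fraction": selection.overlap_fraction,
        }

    if selection is not None and snapshots is not None:

        @_stage("build_complexes", config["poses"])
        def _complexes():
            sids = set(ensemble.provenance["snapshot_id"])
            usable = {s: snapshots[s] for s in sids if s in snapshots}
            if len(usable) < len(sids):
                # poses may reference snapshot ids outside the sampled set
                missing = sorted(sids - set(usable))
                raise KeyError(f"missing snapshots for ids {missing}")
            cxs = build_complexes(usable, ensemble, selection.union_indices)
            paths = []
            for k, cx in enumerate(cxs):
                p = out_dir / f"complex_{k:03d}.pdb"
                write_structure_pdb(cx, p)
                paths.append(str(p))
            return paths

        report["stages"]["build_complexes"] = {"files": _complexes()}

    if config["rescore"]:
        path = config["rescore"]

        @_stage("rank_rescoring", path)
        def _rank():
            table = read_rescore_csv(path)
            best, gap = rank_rescoring(table)
            return {"best_pose": best if isinstance(best, str) else int(best),
                    "energy_gap_kcal_mol": gap if np.isfinite(gap) else None}

        report["stages"]["rank_rescoring"] = _rank()

    if config["quench_csv"]:
        @_stage("fit_quench", config["quench_csv"])
        def _quench():
            series = read_titration_csv(config["quench_csv"])
            sv = fit_stern_volmer(series)
            kd = estimate_kd_quench(series)
            return {"K_sv_per_M": sv.K_sv, "K_q_per_M_s": sv.K_q,
                    "intercept": sv.intercept, "r_squared": sv.r_squared,
                    "K_d_M": kd.K_d, "n_sites": kd.n_sites,
                    "converged": kd.converged}

        report["stages"]["fit_quench"] = _quench()

    if config["itc_csv"]:
        @_stage("fit_itc", config["itc_csv"])
        def _itc():
            fit = fit_itc_one_site(read_itc_csv(config["itc_csv"]))
            return {"n": fit.n, "K_d_M": fit.K_d, "dH_kcal_mol": fit.dH,
                    "dG_kcal_mol": fit.dG, "TdS_kcal_mol": fit.TdS,
                    "c_value": fit.c_value}

        report["stages"]["fit_itc"] = _itc()

    if config["dsc_csv"]:
        @_stage("fit_dsc", config["dsc_csv"])
        def _dsc():
            fit = fit_dsc(read_thermogram_csv(config["dsc_csv"]),
                          config["dsc_transitions"])
            return {"transitions": [
                {"T_m_K": tr.T_m, "T_m_C": tr.T_m - 273.15,
                 "dH_cal_kcal_mol": tr.dH_cal, "dH_vH_kcal_mol": tr.dH_vH}
                for tr in fit.transitions]}

        report["stages"]["fit_dsc"] = _dsc()

    if config["ic50_csv"]:
        @_stage("fit_ic50", config["ic50_csv"])
        def _ic50():
            fit = fit_ic50(read_dose_response_csv(config["ic50_csv"]),
                           n_boot=config["n_boot"], seed=config["seed"])
            return {"ic50_M": fit.ic50, "hill": fit.hill,
                    "ci95_M": list(fit.ci95)}

        report["stages"]["fit_ic50"] = _ic50()

    with (out_dir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
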