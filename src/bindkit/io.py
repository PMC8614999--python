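"""Readers and writers: multi-model PDB, CSV series with ground-truth headers.

PDB handling is delegated to biotite's ``AtomArray``/``AtomArrayStack``
behind the package's own containers; one pose or frame per MODEL record,
coordinates at the standard %8.3f precision.  Measurement series round-trip
through CSV with an optional ``# truth:`` JSON comment line carrying the
generator's ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .datatypes import (
    DoseResponse,
    ITCExperiment,
    ITCGeometry,
    PoseEnsemble,
    Structure,
    Thermogram,
    TitrationSeries,
    Topology,
    Trajectory,
)

__all__ = [
    "write_series_csv",
    "read_titration_csv",
    "read_itc_csv",
    "read_thermogram_csv",
    "read_dose_response_csv",
    "write_structure_pdb",
    "write_trajectory_pdb",
    "write_poses_pdb",
    "read_structures",
    "read_trajectory",
    "read_pose_ensemble",
    "read_rescore_csv",
]


# ---------------------------------------------------------------------------
# CSV series
# ---------------------------------------------------------------------------

_SERIES_COLUMNS = {
    TitrationSeries: ("ligand_conc_M", "fluorescence"),
    Thermogram: ("temperature_K", "excess_cp_kcal_mol_K"),
    DoseResponse: ("conc_M", "activity"),
}


def write_series_csv(obj, path) -> None:
    """Write a measurement series as CSV with a ``# truth:`` JSON header."""
    path = Path(path)
    lines = []
    if getattr(obj, "truth", None) is not None:
        lines.append("# truth: " + json.dumps(obj.truth))
    if isinstance(obj, TitrationSeries):
        lines.append(f"# protein_conc_M: {obj.protein_conc}")
        df = pd.DataFrame({"ligand_conc_M": obj.ligand_conc,
                           "fluorescence": obj.fluorescence})
    elif isinstance(obj, ITCExperiment):
        g = obj.geometry
        lines.append("# geometry: " + json.dumps({
            "cell_volume": g.cell_volume, "cell_conc": g.cell_conc,
            "syringe_conc": g.syringe_conc, "temperature": g.temperature,
        }))
        df = pd.DataFrame({"injection_volume_L": g.injection_volumes,
                           "heat_ucal": obj.heats})
        if obj.dilution_heats is not None:
            df["dilution_heat_ucal"] = obj.dilution_heats
    elif isinstance(obj, Thermogram):
        df = pd.DataFrame({"temperature_K": obj.temperature,
                           "excess_cp_kcal_mol_K": obj.excess_cp})
    elif isinstance(obj, DoseResponse):
        df = pd.DataFrame({"conc_M": obj.conc, "activity": obj.activity})
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    with path.open("w") as fh:
        for line in lines:
            fh.write(line + "\n")
        df.to_csv(fh, index=False)


def _read_csv_with_truth(path):
    path = Path(path)
    truth = None
    extras = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if body.startswith("truth:"):
                truth = json.loads(body[len("truth:"):])
            elif ":" in body:
                key, val = body.split(":", 1)
                extras[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=skip)
    return df, truth, extras


def read_titration_csv(path) -> TitrationSeries:
    df, truth, extras = _read_csv_with_truth(path)
    protein_conc = float(extras.get("protein_conc_M", 0.0))
    return TitrationSeries(ligand_conc=df["ligand_conc_M"].to_numpy(),
                           fluorescence=df["fluorescence"].to_numpy(),
                           protein_conc=protein_conc, truth=truth)


def read_itc_csv(path) -> ITCExperiment:
    df, truth, extras = _read_csv_with_truth(path)
    g = json.loads(extras["geometry"]) if "geometry" in extras else {}
    geom = ITCGeometry(
        cell_volume=g.get("cell_volume", 0.2e-3),
        cell_conc=g.get("cell_conc", 25e-6),
        syringe_conc=g.get("syringe_conc", 250e-6),
        injection_volumes=tuple(df["injection_volume_L"].to_numpy()),
        temperature=g.get("temperature", 298.15),
    )
    dil = df["dilution_heat_ucal"].to_numpy() if "dilution_heat_ucal" in df else None
    return ITCExperiment(geometry=geom, heats=df["heat_ucal"].to_numpy(),
                         dilution_heats=dil, truth=truth)


def read_thermogram_csv(path) -> Thermogram:
    df, truth, _ = _read_csv_with_truth(path)
    return Thermogram(temperature=df["temperature_K"].to_numpy(),
                      excess_cp=df["excess_cp_kcal_mol_K"].to_numpy(), truth=truth)


def read_dose_response_csv(path) -> DoseResponse:
    df, truth, _ = _read_csv_with_truth(path)
    return DoseResponse(conc=df["conc_M"].to_numpy(),
                        activity=df["activity"].to_numpy(), truth=truth)


def read_rescore_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"pose_id", "energy_kcal_mol"} <= set(df.columns):
        raise ValueError("rescoring CSV needs columns pose_id, energy_kcal_mol")
    return df


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _topology_to_atom_array(topo: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topo.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = topo.chain.astype("U4")
    arr.res_id = topo.res_id.astype(int)
    arr.res_name = topo.res_name.astype("U5")
    arr.atom_name = topo.atom_name.astype("U6")
    arr.element = np.char.upper(topo.element.astype("U2"))
    arr.hetero = np.array([rn == "PUN" or rn == "LIG" for rn in topo.res_name])
    return arr


def _atom_array_topology(arr) -> Topology:
    return Topology(
        element=np.asarray(arr.element, dtype="U4"),
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        res_id=np.asarray(arr.res_id, dtype=int),
        res_name=np.asarray(arr.res_name, dtype="U4"),
        chain=np.asarray(arr.chain_id, dtype="U2"),
    )


def write_structure_pdb(structure: Structure, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(_topology_to_atom_array(structure.topology, structure.coords))
    pdb.write(str(path))


def write_trajectory_pdb(traj: Trajectory, path) -> None:
    """One MODEL per frame, fixed topology."""
    arrays = [_topology_to_atom_array(traj.topology, traj.frames[i])
              for i in range(traj.n_frames)]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_poses_pdb(ensemble: PoseEnsemble, pdb_path, scores_path=None) -> None:
    """One MODEL per pose plus a score/provenance CSV keyed by model number."""
    topo = Topology(
        element=ensemble.element.astype("U4"),
        atom_name=ensemble.atom_name.astype("U6"),
        res_id=np.full(ensemble.n_atoms, 1),
        res_name=np.full(ensemble.n_atoms, "PUN", dtype="U4"),
        chain=np.full(ensemble.n_atoms, "L", dtype="U2"),
    )
    arrays = [_topology_to_atom_array(topo, ensemble.coords[i])
              for i in range(ensemble.n_poses)]
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(pdb_path))
    if scores_path is not None:
        df = ensemble.provenance.copy()
        df.insert(0, "model", np.arange(1, ensemble.n_poses + 1))
        df["score"] = ensemble.scores
        df.to_csv(scores_path, index=False)


def _check_model_consistency(path) -> None:
    """Reject multi-model files whose models differ in atom count."""
    counts = []
    current = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                counts.append(current)
                current = None
    if current:
        counts.append(current)
    if counts and any(c != counts[0] for c in counts):
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise ValueError(f"inconsistent atom count in MODEL {bad + 1}")


def read_structures(path, multi_model: bool = False):
    """Parse a PDB file into a Structure (single) or list of Structures."""
    _check_model_consistency(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if not multi_model and n_models == 1:
        arr = pdb.get_structure(model=1)
        return Structure(topology=_atom_array_topology(arr),
                         coords=np.asarray(arr.coord, dtype=float))
    stack = pdb.get_structure()
    topo = _atom_array_topology(stack[0])
    return [Structure(topology=topo, coords=np.asarray(stack.coord[i], dtype=float))
            for i in range(stack.stack_depth())]


def read_trajectory(path) -> Trajectory:
    _check_model_consistency(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    return Trajectory(topology=_atom_array_topology(stack[0]),
                      frames=np.asarray(stack.coord, dtype=float))


def read_pose_ensemble(pdb_path, scores_path,
                       score_sign: str = "lower_better") -> PoseEnsemble:
    """Join a multi-model pose PDB with its score/provenance CSV.

    ``score_sign`` declares the CSV's convention: ``"lower_better"`` (e.g.
    smina affinities) keeps scores as-is, ``"higher_better"`` negates them so
    that internally lower always means better.
    """
    if score_sign not in ("lower_better", "higher_better"):
        raise ValueError("score_sign must be 'lower_better' or 'higher_better'")
    _check_model_consistency(pdb_path)
    pdb = PDBFile.read(str(pdb_path))
    stack = pdb.get_structure()
    n = stack.stack_depth()
    df = pd.read_csv(scores_path)
    if len(df) != n:
        raise ValueError(f"score table has {len(df)} rows for {n} models")
    if "model" in df.columns:
        df = df.sort_values("model").reset_index(drop=True)
    prov_cols = [c for c in ("snapshot_id", "conformer_id", "epimer") if c in df.columns]
    prov = df[prov_cols].copy() if prov_cols else pd.DataFrame(
        {"snapshot_id": np.zeros(n, int), "conformer_id": np.zeros(n, int),
         "epimer": ["alpha"] * n})
    for col, default in (("snapshot_id", 0), ("conformer_id", 0), ("epimer", "alpha")):
        if col not in prov:
            prov[col] = default
    scores = df["score"].to_numpy(dtype=float)
    if score_sign == "higher_better":
        scores = -scores
    return PoseEnsemble(
        element=np.asarray(stack.element, dtype="U4"),
        atom_name=np.asarray(stack.atom_name, dtype="U6"),
        coords=np.asarray(stack.coord, dtype=float),
        scores=scores,
        provenance=prov.reset_index(drop=True),
    )
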