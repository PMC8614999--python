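"""Seeded generators for every input the analysis pipeline consumes.

These stand in for the spectrofluorometer, the titration and scanning
calorimeters, the enzyme assay, and the MD/docking engines: each generator
draws noise from a single explicit seed, stores its ground truth on the
returned object, and (noise-free) agrees bit-for-bit with the corresponding
forward model in :mod:`bindkit.binding_thermo`.
"""

from __future__ import annotations

import numpy as np

from .binding_thermo import (
    dsc_model_cp,
    four_param_logistic,
    itc_model_heats,
    stern_volmer_fluorescence,
)
from .datatypes import (
    DoseResponse,
    DSCTransition,
    HingeSpec,
    ITCExperiment,
    ITCGeometry,
    ITCParams,
    PlantedPoseSpec,
    PlantedTruth,
    PoseEnsemble,
    QuenchParams,
    Thermogram,
    TitrationSeries,
    Topology,
    Trajectory,
)

import pandas as pd

__all__ = [
    "gen_quench_titration",
    "gen_itc_experiment",
    "gen_dsc_thermogram",
    "gen_dose_response",
    "gen_pose_ensemble",
    "gen_hinge_trajectory",
    "default_ligand_template",
]


def gen_quench_titration(params: QuenchParams, ligand_grid, noise_sd: float = 0.01,
                         seed: int = 0, protein_conc: float = 0.1e-6) -> TitrationSeries:
    """Static-quenching titration F = F0 / (1 + K_sv [L]) with multiplicative noise.

    ``noise_sd`` is relative (fluorescence error scales with intensity).  The
    grid must be sorted ascending and start at 0 µM (the F0 reading).
    """
    L = np.asarray(ligand_grid, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentrations must be non-negative")
    if L.size == 0 or L[0] != 0.0 or np.any(np.diff(L) < 0):
        raise ValueError("grid must be sorted ascending and start at 0")
    F = stern_volmer_fluorescence(params.F0, params.K_sv, L)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        F = F * (1.0 + noise_sd * rng.standard_normal(L.size))
    return TitrationSeries(
        ligand_conc=L, fluorescence=F, protein_conc=protein_conc,
        truth={"K_sv": params.K_sv, "F0": params.F0, "K_d": params.K_d,
               "n_sites": params.n_sites, "tau": params.tau,
               "noise_sd": noise_sd, "seed": seed},
    )


def gen_itc_experiment(params: ITCParams, geom: ITCGeometry = ITCGeometry(),
                       noise_sd: float = 0.05, dilution_heat: float = 0.0,
                       seed: int = 0) -> ITCExperiment:
    """Per-injection heats from the one-site forward model.

    A constant per-injection dilution heat (µcal) is added, mimicking the
    ligand-into-buffer blank that a real experiment subtracts, plus additive
    Gaussian noise of ``noise_sd`` µcal.
    """
    heats = itc_model_heats(params, geom) + dilution_heat
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + noise_sd * rng.standard_normal(heats.size)
    return ITCExperiment(
        geometry=geom, heats=heats,
        truth={"n": params.n, "K_d": params.K_d, "dH": params.dH,
               "dilution_heat": dilution_heat, "noise_sd": noise_sd, "seed": seed},
    )


def gen_dsc_thermogram(transitions, T_grid, baseline=(0.0, 0.0),
                       noise_sd: float = 0.0, seed: int = 0) -> Thermogram:
    """Thermogram from summed two-state peaks plus linear baseline and noise.

    The grid (kelvin) must be strictly increasing and span every T_m.
    """
    T = np.asarray(T_grid, dtype=float)
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    for tr in transitions:
        if not (T[0] <= tr.T_m <= T[-1]):
            raise ValueError(f"T_m {tr.T_m} K outside the grid span")
    cp = dsc_model_cp(transitions, T, baseline)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + noise_sd * rng.standard_normal(T.size)
    return Thermogram(
        temperature=T, excess_cp=cp,
        truth={"transitions": [(tr.T_m, tr.dH_cal, tr.dH_vH) for tr in transitions],
               "baseline": tuple(baseline), "noise_sd": noise_sd, "seed": seed},
    )


def gen_dose_response(ic50: float, hill: float = 1.0, top: float = 100.0,
                      bottom: float = 0.0, conc_grid=None, noise_sd: float = 0.0,
                      seed: int = 0) -> DoseResponse:
    """4PL inhibition curve over a log-spaced concentration grid.

    Default grid: 8 log-spaced points over the 0.2-50 µM assay range.
    ``noise_sd`` is in activity units (same scale as top/bottom).
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if conc_grid is None:
        conc_grid = np.logspace(np.log10(0.2e-6), np.log10(50e-6), 8)
    c = np.asarray(conc_grid, dtype=float)
    if not (c.min() <= ic50 <= c.max()):
        raise ValueError("ic50 must lie within the concentration grid span")
    y = four_param_logistic(c, ic50, hill, top, bottom)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * rng.standard_normal(c.size)
    return DoseResponse(
        conc=c, activity=y,
        truth={"ic50": ic50, "hill": hill, "top": top, "bottom": bottom,
               "noise_sd": noise_sd, "seed": seed},
    )


# ---------------------------------------------------------------------------
# pose ensembles
# ---------------------------------------------------------------------------

def default_ligand_template(n_heavy: int = 12) -> list:
    """A rigid mock ligand: heavy atoms on a deterministic 3D zig-zag scaffold."""
    atoms = []
    elements = ["C", "C", "O", "C", "C", "O", "C", "N", "C", "O", "C", "C"]
    for i in range(n_heavy):
        el = elements[i % len(elements)]
        xyz = (1.4 * i, 0.8 * ((-1) ** i), 0.3 * (i % 3))
        atoms.append((el, xyz))
    return atoms


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via quaternion sampling."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def gen_pose_ensemble(spec: PlantedPoseSpec, seed: int = 0) -> tuple[PoseEnsemble, PlantedTruth]:
    """Rigid-body poses planted around known cluster centres.

    Each pose is the ligand template centred at the origin, uniformly
    rotated, then translated to its cluster centre plus an isotropic Gaussian
    offset.  Scores are drawn per cluster from the spec's (mean, sd) model.
    Provenance cycles snapshot/conformer ids and alternates the anomer label.
    """
    rng = np.random.default_rng(seed)
    template = np.array([xyz for _, xyz in spec.ligand_template], dtype=float)
    template = template - template.mean(axis=0)
    elements = np.array([el for el, _ in spec.ligand_template], dtype="U4")
    names = np.array([f"{el}{i + 1}" for i, (el, _) in enumerate(spec.ligand_template)],
                     dtype="U6")

    coords, scores, members = [], [], []
    rows = []
    pose_id = 0
    for ci in range(spec.n_clusters):
        center = spec.centers[ci]
        sd = float(spec.spread[ci])
        mu_s, sd_s = spec.score_model[ci]
        for _ in range(int(spec.counts[ci])):
            R = _random_rotation(rng)
            offset = sd * rng.standard_normal(3) if sd > 0 else np.zeros(3)
            coords.append(template @ R.T + center + offset)
            scores.append(mu_s + sd_s * rng.standard_normal() if sd_s > 0 else mu_s)
            members.append(ci)
            rows.append({"snapshot_id": pose_id % 8, "conformer_id": pose_id % 5,
                         "epimer": "alpha" if pose_id % 2 == 0 else "beta"})
            pose_id += 1

    ensemble = PoseEnsemble(
        element=elements, atom_name=names,
        coords=np.array(coords), scores=np.array(scores),
        provenance=pd.DataFrame(rows),
    )
    truth = PlantedTruth(cluster_of=np.array(members, dtype=int),
                         centers=spec.centers.copy())
    return ensemble, truth


# ---------------------------------------------------------------------------
# hinge trajectory
# ---------------------------------------------------------------------------

def _cube_lattice(n_atoms: int, spacing: float = 3.8) -> np.ndarray:
    """Smallest cubic lattice holding n_atoms, centred at the origin."""
    side = int(np.ceil(n_atoms ** (1.0 / 3.0)))
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((i, j, k))
                if len(pts) == n_atoms:
                    break
            if len(pts) == n_atoms:
                break
        if len(pts) == n_atoms:
            break
    pts = np.array(pts, dtype=float) * spacing
    return pts - pts.mean(axis=0)


def gen_hinge_trajectory(spec: HingeSpec, seed: int = 0) -> Trajectory:
    """Toy two-domain closing trajectory with a buriable probe atom.

    Two rigid pseudo-domains (carbon pseudo-atoms on 3.8 Å lattices, chains A
    and B, one residue per atom with name CA so per-residue statistics work)
    face each other along x.  The mobile chain-B domain translates so that
    the closest interdomain distance interpolates linearly from ``start_gap``
    to ``end_gap``.  The probe atom protrudes from the fixed domain's facing
    surface, so its accessible surface shrinks as the mobile domain arrives.
    Gaussian jitter of ``jitter_sd`` is applied to all non-defining atoms.
    """
    rng = np.random.default_rng(seed)
    nA, nB = spec.domain_sizes
    fixed = _cube_lattice(nA)
    mobile0 = _cube_lattice(nB)

    # facing boundary atoms define the planted closest pair: keep them jitter-free
    iA = int(np.argmax(fixed[:, 0]))
    iB = int(np.argmin(mobile0[:, 0]))
    probe = spec.probe_index if spec.probe_index is not None else iA

    n_atoms = nA + nB
    element = np.full(n_atoms, "C", dtype="U4")
    atom_name = np.full(n_atoms, "CA", dtype="U6")
    res_id = np.arange(1, n_atoms + 1)
    res_name = np.full(n_atoms, "GLY", dtype="U4")
    chain = np.array(["A"] * nA + ["B"] * nB, dtype="U2")
    topo = Topology(element=element, atom_name=atom_name, res_id=res_id,
                    res_name=res_name, chain=chain)

    frames = np.empty((spec.n_frames, n_atoms, 3))
    gaps = np.linspace(spec.start_gap, spec.end_gap, spec.n_frames)
    for t, gap in enumerate(gaps):
        shift = fixed[iA, 0] + gap - mobile0[iB, 0]
        mobile = mobile0 + np.array([shift, 0.0, 0.0])
        frame = np.vstack([fixed, mobile])
        if spec.jitter_sd > 0:
            jitter = spec.jitter_sd * rng.standard_normal(frame.shape)
            jitter[iA] = 0.0
            jitter[nA + iB] = 0.0
            # jitter must not create a closer pair than the planted one
            frame = frame + np.clip(jitter, -gap / 4, gap / 4)
        frames[t] = frame

    traj = Trajectory(topology=topo, frames=frames,
                      frame_times=np.arange(spec.n_frames, dtype=float))
    traj.probe_index = probe
    traj.boundary_pair = (iA, nA + iB)
    return traj
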