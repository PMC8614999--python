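"""Trajectory geometry statistics: superposition, RMSD/RMSF, SASA, distances.

All metrics are invariant under a global rigid transform of every frame.
Superposition uses the Kabsch algorithm with the determinant correction that
enforces a proper rotation.  SASA follows Shrake-Rupley with a deterministic
generalized-spiral point set so results are bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .constants import VDW_RADII, WATER_PROBE_RADIUS
from .datatypes import SeriesResult, Topology, Trajectory

__all__ = [
    "superpose",
    "rmsd_series",
    "density_profile",
    "rmsf",
    "sasa_series",
    "shrake_rupley_sasa",
    "min_distance_series",
    "sample_snapshots",
    "backbone_mask",
    "sphere_points",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def backbone_mask(topology: Topology) -> np.ndarray:
    """Boolean mask of protein-backbone atoms (N, CA, C, O by atom name)."""
    return np.isin(topology.atom_name, BACKBONE_ATOMS)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, ref: np.ndarray,
              selection: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid fit of ``mobile`` onto ``ref`` (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``mobile[selection] @ rotation.T + translation`` best matches
    ``ref[selection]``; the RMSD is computed on the selection after the
    transform.  The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if selection is None:
        selection = np.arange(mobile.shape[0])
    a = mobile[selection]
    b = ref[selection]
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("selections must map 1:1 with at least 3 atoms")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    H = (a - ca).T @ (b - cb)
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear) configurations make the fit ill-posed
    if S[1] < 1e-9 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) selection: rotation not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    moved = a @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(traj: Trajectory, ref_frame: int = 0,
                selection: np.ndarray | None = None,
                fit_selection: np.ndarray | None = None) -> SeriesResult:
    """Per-frame RMSD to a reference frame after superposition.

    Default selection is the protein backbone (atom names N, CA, C, O).
    Frames are superposed on ``fit_selection`` (defaults to ``selection``)
    and the deviation is measured on ``selection`` — passing a rigid
    subdomain as ``fit_selection`` exposes relative motion of the rest.
    """
    if selection is None:
        selection = np.nonzero(backbone_mask(traj.topology))[0]
        if selection.size == 0:
            missing = np.unique(traj.topology.res_id)
            raise ValueError(f"no backbone atoms found (residues {missing[:5]}...)")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    fit_sel = selection if fit_selection is None else np.asarray(fit_selection, dtype=int)
    ref = traj.frames[ref_frame]
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        R, t, _ = superpose(traj.frames[i], ref, fit_sel)
        moved = traj.frames[i][selection] @ R.T + t
        values[i] = float(np.sqrt(np.mean(np.sum((moved - ref[selection]) ** 2, axis=1))))
    return SeriesResult(values=values, metric="rmsd", selection=f"{selection.size} atoms")


def density_profile(series: SeriesResult, bw_method="scott",
                    n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """1-D Gaussian KDE of a series; returns (grid, density) integrating to ~1."""
    x = series.values
    if x.size < 10:
        raise ValueError("need at least 10 points for a density profile")
    sd = float(np.std(x))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        warnings.warn("zero-variance series: returning a delta-like narrow kernel",
                      stacklevel=2)
        eps = max(1e-6, 1e-6 * abs(float(x[0])))
        grid = np.linspace(x[0] - 10 * eps, x[0] + 10 * eps, n_grid)
        dens = np.exp(-0.5 * ((grid - x[0]) / eps) ** 2) / (eps * np.sqrt(2 * np.pi))
        return grid, dens
    kde = gaussian_kde(x, bw_method=bw_method)
    pad = 4.0 * sd
    grid = np.linspace(x.min() - pad, x.max() + pad, n_grid)
    return grid, kde(grid)


def rmsf(traj: Trajectory, selection: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue RMSF of CA atoms about the mean structure.

    All frames are superposed to the running average structure (two passes),
    then RMSF_r = sqrt(<|x_r - <x_r>|^2>) for each residue's CA.  Returns
    (residue ids, rmsf values); residues lacking a CA are skipped with a
    warning.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    topo = traj.topology
    if selection is None:
        selection = np.arange(topo.n_atoms)
    fit_sel = np.asarray(selection, dtype=int)

    frames = traj.frames.copy()
    mean = frames[0]
    for _ in range(2):  # iterate superposition to the average structure
        aligned = np.empty_like(frames)
        for i in range(frames.shape[0]):
            R, t, _ = superpose(frames[i], mean, fit_sel)
            aligned[i] = frames[i] @ R.T + t
        frames = aligned
        mean = frames.mean(axis=0)

    res_ids, values = [], []
    skipped = []
    keys = list(dict.fromkeys(zip(topo.chain.tolist(), topo.res_id.tolist())))
    for chain, rid in keys:
        mask = (topo.chain == chain) & (topo.res_id == rid) & (topo.atom_name == "CA")
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            skipped.append((chain, rid))
            continue
        x = frames[:, idx[0], :]
        dev = x - x.mean(axis=0)
        res_ids.append(rid)
        values.append(float(np.sqrt(np.mean(np.sum(dev ** 2, axis=1)))))
    if skipped:
        warnings.warn(f"{len(skipped)} residues lack a CA atom and were skipped",
                      stacklevel=2)
    return np.array(res_ids), np.array(values)


# ---------------------------------------------------------------------------
# solvent accessible surface area
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """Deterministic generalized-spiral (golden-angle) unit-sphere point set."""
    k = np.arange(n) + 0.5
    z = 1.0 - 2.0 * k / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * k
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(elements: np.ndarray) -> np.ndarray:
    radii = np.empty(len(elements))
    for i, el in enumerate(elements):
        key = str(el).strip().upper().capitalize()
        if key not in VDW_RADII:
            raise ValueError(f"unknown element {el!r}: no van der Waals radius defined")
        radii[i] = VDW_RADII[key]
    return radii


def shrake_rupley_sasa(coords: np.ndarray, elements: np.ndarray,
                       probe: float = WATER_PROBE_RADIUS,
                       n_points: int = 960) -> np.ndarray:
    """Per-atom solvent accessible surface area (A^2), Shrake-Rupley.

    Each atom's sphere of radius vdW+probe is sampled with the deterministic
    spiral point set; a point is accessible if it lies outside every
    neighbour's expanded sphere.  Per-atom SASA = accessible fraction times
    the analytic sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = _atom_radii(elements) + probe
    n_atoms = coords.shape[0]
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        pts = coords[i] + radii[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i]
        if neighbors:
            diff = pts[:, None, :] - coords[neighbors][None, :, :]
            d2 = np.sum(diff * diff, axis=2)
            buried = np.any(d2 < (radii[neighbors] ** 2)[None, :] - 1e-12, axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def sasa_series(traj: Trajectory, residue_selection: np.ndarray,
                probe: float = WATER_PROBE_RADIUS, n_points: int = 960) -> SeriesResult:
    """Per-frame SASA (A^2) summed over the atoms in ``residue_selection``."""
    sel = np.asarray(residue_selection, dtype=int)
    if sel.size == 0:
        raise ValueError("selection resolves to no atoms")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        per_atom = shrake_rupley_sasa(traj.frames[i], traj.topology.element,
                                      probe=probe, n_points=n_points)
        values[i] = per_atom[sel].sum()
    return SeriesResult(values=values, metric="sasa", selection=f"{sel.size} atoms")


# ---------------------------------------------------------------------------
# interdomain distances
# ---------------------------------------------------------------------------

def min_distance_brute(xa: np.ndarray, xb: np.ndarray) -> float:
    """Reference double-loop minimum pairwise distance (oracle path)."""
    diff = xa[:, None, :] - xb[None, :, :]
    return float(np.sqrt(np.min(np.sum(diff * diff, axis=2))))


def min_distance_series(traj: Trajectory, idx_a: np.ndarray, idx_b: np.ndarray,
                        method: str = "grid") -> SeriesResult:
    """Per-frame closest distance between two atom selections.

    ``method='grid'`` uses a k-d tree nearest-neighbour query and returns
    values identical to the brute-force double loop (``method='brute'``).
    Overlapping selections are rejected.
    """
    idx_a = np.asarray(idx_a, dtype=int)
    idx_b = np.asarray(idx_b, dtype=int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("both selections must be non-empty")
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("selections overlap; closest distance is ill-defined")
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        xa, xb = traj.frames[i][idx_a], traj.frames[i][idx_b]
        if method == "brute":
            values[i] = min_distance_brute(xa, xb)
        else:
            d, _ = cKDTree(xb).query(xa, k=1)
            values[i] = float(d.min())
    return SeriesResult(values=values, metric="min_distance",
                        selection=f"{idx_a.size}x{idx_b.size} atoms")


# ---------------------------------------------------------------------------
# snapshot sampling
# ---------------------------------------------------------------------------

def sample_snapshots(traj: Trajectory, n: int, strategy: str = "stride",
                     selection: np.ndarray | None = None) -> np.ndarray:
    """Pick ``n`` representative frame indices for ensemble docking.

    ``stride``: evenly spaced including the first frame.  ``rmsd-spread``:
    greedy max-min selection on pairwise backbone RMSD, seeded at frame 0
    (deterministic).  Returns sorted unique indices.
    """
    if n > traj.n_frames:
        raise ValueError("cannot sample more snapshots than frames")
    if n == traj.n_frames:
        return np.arange(traj.n_frames)
    if strategy == "stride":
        return (np.arange(n) * (traj.n_frames // n)).astype(int)
    if strategy == "rmsd-spread":
        if selection is None:
            sel = np.nonzero(backbone_mask(traj.topology))[0]
            if sel.size == 0:
                sel = np.arange(traj.topology.n_atoms)
        else:
            sel = np.asarray(selection, dtype=int)
        chosen = [0]
        dmin = np.full(traj.n_frames, np.inf)
        for _ in range(n - 1):
            last = chosen[-1]
            for j in range(traj.n_frames):
                if j in chosen:
                    continue
                _, _, r = superpose(traj.frames[j], traj.frames[last], sel)
                dmin[j] = min(dmin[j], r)
            dmin[chosen] = -np.inf
            chosen.append(int(np.argmax(dmin)))
        return np.array(sorted(chosen))
    raise ValueError(f"unknown strategy {strategy!r}")
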