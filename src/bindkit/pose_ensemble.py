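"""Ensemble-docking post-processing: pose embedding, selection, and ranking.

Docked poses from many receptor snapshots are first brought into a common
frame (Kabsch superposition of each snapshot onto the first), embedded by
PCA of their flattened heavy-atom coordinates, and then representative
binding modes are selected two ways: by best docking score and by the modes
of a 2-D kernel density estimate of the embedding.  The mean pairwise
distance between selected poses' centres of mass (MDCOM) quantifies whether
the two selection routes converge on one binding site (small MDCOM) or
disagree (MDCOM approaching the inter-cluster separation).  Rescoring tables
(e.g. end-point binding free energies computed externally) are consumed to
pick the final binding mode and the energy gap to the runner-up.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import (
    DomainMap,
    Embedding,
    PoseEnsemble,
    SelectionResult,
    Structure,
    Topology,
)
from .traj_analysis import superpose

__all__ = [
    "common_frame",
    "pca_embed",
    "kde_select",
    "score_select",
    "mdcom",
    "select_poses",
    "build_complexes",
    "rank_rescoring",
    "pose_centers_of_mass",
]


def pose_centers_of_mass(ensemble: PoseEnsemble, heavy_only: bool = True,
                         mass_weighted: bool = False) -> np.ndarray:
    """Per-pose centre of mass; by default the unweighted heavy-atom centroid."""
    mask = ensemble.heavy_mask() if heavy_only else np.ones(ensemble.n_atoms, bool)
    coords = ensemble.coords[:, mask, :]
    if mass_weighted:
        masses = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
        w = np.array([masses.get(str(e).capitalize(), 12.0)
                      for e in ensemble.element[mask]])
        return (coords * w[None, :, None]).sum(axis=1) / w.sum()
    return coords.mean(axis=1)


def common_frame(snapshots: dict, ensemble: PoseEnsemble,
                 ref_selection: np.ndarray) -> PoseEnsemble:
    """Project all poses into the first snapshot's frame.

    ``snapshots`` maps snapshot_id -> Structure.  Each snapshot is
    Kabsch-superposed (on ``ref_selection`` atom indices) onto the first
    snapshot in key-sorted order, and the resulting rigid transform is
    applied to that snapshot's poses.
    """
    ids_needed = set(ensemble.provenance["snapshot_id"])
    missing = sorted(ids_needed - set(snapshots))
    if missing:
        raise KeyError(f"poses reference missing snapshots: {missing}")
    ref_selection = np.asarray(ref_selection, dtype=int)
    if ref_selection.size == 0:
        raise ValueError("ref_selection is empty")

    ordered = sorted(snapshots)
    ref = snapshots[ordered[0]].coords
    transforms = {}
    for sid in ordered:
        R, t, _ = superpose(snapshots[sid].coords, ref, ref_selection)
        transforms[sid] = (R, t)

    coords = ensemble.coords.copy()
    for i, sid in enumerate(ensemble.provenance["snapshot_id"]):
        R, t = transforms[sid]
        coords[i] = coords[i] @ R.T + t
    return PoseEnsemble(element=ensemble.element, atom_name=ensemble.atom_name,
                        coords=coords, scores=ensemble.scores.copy(),
                        provenance=ensemble.provenance.copy())


def pca_embed(ensemble: PoseEnsemble, heavy_only: bool = True) -> Embedding:
    """Top-2 principal components of flattened per-pose coordinates.

    Each pose's (heavy-atom) coordinates become one 3N vector; vectors are
    centred and projected onto the top-2 covariance eigenvectors (via SVD).
    Sign convention: the first nonzero loading of each component is positive.
    """
    if ensemble.n_poses < 3:
        raise ValueError("need at least 3 poses")
    mask = ensemble.heavy_mask() if heavy_only else np.ones(ensemble.n_atoms, bool)
    X = ensemble.coords[:, mask, :].reshape(ensemble.n_poses, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S ** 2 / max(ensemble.n_poses - 1, 1)
    total = float(eigvals.sum())

    comps = np.zeros((2, X.shape[1]))
    ev = [0.0, 0.0]
    n_ok = min(2, int(np.sum(S > 1e-10 * max(S[0], 1e-30))))
    if total <= 0 or n_ok == 0:
        warnings.warn("identical poses: embedding degenerate, variance set to (0, 0)",
                      stacklevel=2)
        points = np.zeros((ensemble.n_poses, 2))
        return Embedding(points=points, explained_variance=(0.0, 0.0),
                         mean_vector=mean, components=comps)
    if n_ok < 2:
        warnings.warn("coordinate rank < 2: second component zeroed", stacklevel=2)
    for k in range(n_ok):
        v = Vt[k]
        nz = v[np.abs(v) > 1e-12]
        if nz.size and nz[0] < 0:
            v = -v
        comps[k] = v
        ev[k] = float(eigvals[k] / total)
    points = Xc @ comps.T
    return Embedding(points=points, explained_variance=tuple(ev),
                     mean_vector=mean, components=comps)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _scott_bandwidths(points: np.ndarray) -> np.ndarray:
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1e-9)
    return sd * n ** (-1.0 / 6.0)


def _kde_eval(points: np.ndarray, bw: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Gaussian product-kernel density of ``points`` evaluated at ``at``.

    Evaluation points are processed in chunks to bound memory on large
    ensembles (the pairwise term is n_eval x n_points).
    """
    n = points.shape[0]
    norm = n * 2.0 * np.pi * bw.prod()
    out = np.empty(at.shape[0])
    chunk = max(1, int(4e6 / max(n, 1)))
    scaled = points / bw[None, :]
    for lo in range(0, at.shape[0], chunk):
        z = at[lo:lo + chunk, None, :] / bw[None, None, :] - scaled[None, :, :]
        out[lo:lo + chunk] = np.exp(-0.5 * np.sum(z * z, axis=2)).sum(axis=1) / norm
    return out


def kde_select(embedding: Embedding, k: int = 10,
               grid_size: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Representative poses at the modes of the 2-D embedding density.

    A Gaussian product-kernel KDE with per-axis Scott bandwidth
    (sd * n^(-1/6)) is evaluated on a ``grid_size``^2 grid padded by one
    bandwidth; grid local maxima are ranked by density and for each mode the
    nearest not-yet-selected pose is taken.  If the maxima run out, remaining
    slots are filled by the unselected poses of highest density.  Returns
    (selected indices, per-pose density values).
    """
    pts = embedding.points
    n = pts.shape[0]
    if k > n:
        raise ValueError(f"cannot select {k} poses from {n}")
    bw = _scott_bandwidths(pts)

    gx = np.linspace(pts[:, 0].min() - bw[0], pts[:, 0].max() + bw[0], grid_size)
    gy = np.linspace(pts[:, 1].min() - bw[1], pts[:, 1].max() + bw[1], grid_size)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    grid = np.column_stack([GX.ravel(), GY.ravel()])
    dens = _kde_eval(pts, bw, grid).reshape(grid_size, grid_size)

    # strict inequality so flat near-zero plateaus do not spawn spurious modes
    interior = dens[1:-1, 1:-1]
    is_max = np.ones_like(interior, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == dj == 0:
                continue
            is_max &= interior > dens[1 + di:grid_size - 1 + di,
                                      1 + dj:grid_size - 1 + dj]
    mi, mj = np.nonzero(is_max)
    mode_xy = np.column_stack([gx[mi + 1], gy[mj + 1]])
    order = np.argsort(dens[mi + 1, mj + 1])[::-1]
    mode_xy = mode_xy[order]

    pose_density = _kde_eval(pts, bw, pts)
    selected: list[int] = []
    for m in mode_xy:
        if len(selected) == k:
            break
        d2 = np.sum((pts - m) ** 2, axis=1)
        for idx in np.argsort(d2):
            if int(idx) not in selected:
                selected.append(int(idx))
                break
    if len(selected) < k:
        for idx in np.argsort(pose_density)[::-1]:
            if int(idx) not in selected:
                selected.append(int(idx))
            if len(selected) == k:
                break
    return np.array(selected, dtype=int), pose_density


def score_select(ensemble: PoseEnsemble, k: int = 10) -> np.ndarray:
    """The ``k`` best-scored poses (lower = better), deterministic tie-break.

    Ties are broken lexicographically by (snapshot_id, conformer_id, pose
    order) so repeated runs select identical poses.
    """
    if k > ensemble.n_poses:
        raise ValueError(f"cannot select {k} poses from {ensemble.n_poses}")
    prov = ensemble.provenance
    order = np.lexsort((np.arange(ensemble.n_poses),
                        prov["conformer_id"].to_numpy(),
                        prov["snapshot_id"].to_numpy(),
                        ensemble.scores))
    return order[:k]


def mdcom(ensemble: PoseEnsemble, indices, heavy_only: bool = True,
          pair_set: str = "union", split: int | None = None) -> float:
    """Mean distance between selected poses' centres of mass (angstrom).

    ``pair_set='union'`` (default) averages over all unordered pairs within
    the selection; ``'cross'`` averages only pairs straddling ``split`` (the
    first ``split`` indices vs the rest), for comparing two selection routes.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size < 2:
        raise ValueError("MDCOM needs at least 2 poses")
    coms = pose_centers_of_mass(ensemble.subset(idx), heavy_only=heavy_only)
    if pair_set == "cross":
        if split is None or not (0 < split < idx.size):
            raise ValueError("cross pair set requires 0 < split < len(indices)")
        d = np.linalg.norm(coms[:split, None, :] - coms[None, split:, :], axis=2)
        return float(d.mean())
    diff = coms[:, None, :] - coms[None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    iu = np.triu_indices(idx.size, k=1)
    return float(d[iu].mean())


def select_poses(ensemble: PoseEnsemble, k_score: int = 10,
                 k_kde: int = 10) -> SelectionResult:
    """Run both selection routes and report their union and its MDCOM.

    Duplicate picks collapse in the union, so its size is at most
    k_score + k_kde; ``overlap_fraction`` is the shared fraction of the
    smaller selection.
    """
    score_idx = score_select(ensemble, k_score)
    emb = pca_embed(ensemble)
    kde_idx, density = kde_select(emb, k_kde)
    union = np.concatenate([score_idx, kde_idx])
    _, first = np.unique(union, return_index=True)
    union = union[np.sort(first)]
    overlap = np.intersect1d(score_idx, kde_idx).size / max(min(k_score, k_kde), 1)
    return SelectionResult(
        score_indices=score_idx, kde_indices=kde_idx, union_indices=union,
        mdcom=mdcom(ensemble, union) if union.size >= 2 else 0.0,
        overlap_fraction=float(overlap), density_at_selected=density[union],
    )


# ---------------------------------------------------------------------------
# complexes and rescoring
# ---------------------------------------------------------------------------

def build_complexes(snapshots: dict, ensemble: PoseEnsemble,
                    indices, ligand_resname: str = "PUN",
                    ligand_chain: str = "L") -> list[Structure]:
    """Merge each selected pose with its originating receptor snapshot.

    The pose atoms are appended as one ligand residue on a dedicated chain
    (name collisions are impossible across chains and nothing is dropped);
    atom counts and coordinates are conserved exactly.
    """
    idx = np.asarray(indices, dtype=int)
    out = []
    for i in idx:
        sid = ensemble.provenance["snapshot_id"].iloc[i]
        if sid not in snapshots:
            raise KeyError(f"pose {i} references missing snapshot {sid}")
        snap = snapshots[sid]
        topo = snap.topology
        n_lig = ensemble.n_atoms
        if ligand_chain in set(topo.chain.tolist()):
            raise ValueError(f"ligand chain {ligand_chain!r} already used by the receptor")
        merged = Topology(
            element=np.concatenate([topo.element, ensemble.element]),
            atom_name=np.concatenate([topo.atom_name, ensemble.atom_name]),
            res_id=np.concatenate([topo.res_id, np.full(n_lig, 1, dtype=topo.res_id.dtype)]),
            res_name=np.concatenate([topo.res_name, np.full(n_lig, ligand_resname,
                                                            dtype="U4")]),
            chain=np.concatenate([topo.chain, np.full(n_lig, ligand_chain, dtype="U2")]),
        )
        coords = np.vstack([snap.coords, ensemble.coords[i]])
        out.append(Structure(topology=merged, coords=coords))
    return out


def rank_rescoring(table: pd.DataFrame) -> tuple:
    """Best pose and the energy gap to the runner-up from a rescoring table.

    ``table`` needs columns ``pose_id`` and ``energy_kcal_mol`` (lower =
    better).  Returns (best pose_id, gap); the gap is +inf for a single-row
    table.  The result is invariant to row order; duplicate pose ids raise.
    """
    if len(table) < 1:
        raise ValueError("rescoring table is empty")
    if table["pose_id"].duplicated().any():
        dupes = table.loc[table["pose_id"].duplicated(), "pose_id"].tolist()
        raise ValueError(f"duplicate pose ids in rescoring table: {dupes}")
    if not np.all(np.isfinite(table["energy_kcal_mol"])):
        raise ValueError("energies must be finite")
    ordered = table.sort_values(["energy_kcal_mol", "pose_id"], kind="mergesort")
    best_id = table["pose_id"].loc[ordered.index[0]]  # keep the column dtype
    energies = ordered["energy_kcal_mol"].to_numpy()
    if len(ordered) == 1:
        return best_id, float("inf")
    return best_id, float(energies[1] - energies[0])
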