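"""Trajectory statistics on a two-domain closing (hinge) motion.

Generates a toy trajectory in which two pseudo-domains approach from 15 A
to 4 A, then computes the closest interdomain distance series, the solvent
accessibility of a probe atom at the closing interface, RMSD relative to
the first frame, and per-residue RMSF.
"""

import numpy as np

from bindkit import HingeSpec, gen_hinge_trajectory
from bindkit.traj_analysis import (
    min_distance_series,
    rmsd_series,
    rmsf,
    sample_snapshots,
    sasa_series,
)

traj = gen_hinge_trajectory(
    HingeSpec(n_frames=60, start_gap=15.0, end_gap=4.0, jitter_sd=0.15), seed=11)
A = np.nonzero(traj.topology.chain == "A")[0]
B = np.nonzero(traj.topology.chain == "B")[0]

dist = min_distance_series(traj, A, B).values
print(f"closest interdomain distance: {dist[0]:.1f} A -> {dist[-1]:.1f} A "
      f"(frames below 5 A: {np.sum(dist < 5.0)})")

sasa = sasa_series(traj, np.array([traj.probe_index]), n_points=240).values
print(f"probe SASA: {sasa[:10].mean():.1f} A^2 (early) -> "
      f"{sasa[-10:].mean():.1f} A^2 (late)")

rms = rmsd_series(traj, 0, selection=np.arange(traj.topology.n_atoms),
                  fit_selection=A).values
print(f"RMSD vs frame 0 (fit on fixed domain): {rms[1]:.2f} -> {rms[-1]:.2f} A")

res_ids, flex = rmsf(traj, selection=A)
print(f"mean RMSF fixed domain {flex[:A.size].mean():.2f} A, "
      f"mobile domain {flex[A.size:].mean():.2f} A")

snaps = sample_snapshots(traj, 6, "stride")
print(f"snapshots sampled for docking: {snaps.tolist()}")
print()
print("Falling interdomain distance with simultaneous probe burial is the")
print("signature of a hinge closing over a reporter residue; high mobile-")
print("domain RMSF confirms where the motion lives.")
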