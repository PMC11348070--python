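"""Trajectory statistics: H-bond detection, near/far split, MSD.

Builds a toy coarse-grained trajectory with planted hydrogen-bonded base
pairs around a 0.6-nm-radius nanotube, detects contacts with the 3.5-A
rule, classifies them against the 6-A surface cutoff, and computes the
centre-of-mass mean square displacement of a free random walk.
"""

import numpy as np

from cntbind import synthetic, trajectory

traj = synthetic.simulate_toy_trajectory(
    n_frames=200,
    planted_pairs=[(3, 10, 0.3), (15, 22, 0.9), (25, 28, 0.5)],
    wobble_sd_nm=0.03,
    seed=2,
)
stats = trajectory.hbond_stats(traj, window_frames=200)
print("per-frame H-bond pairs (first frame):", stats.pairs_per_frame[0])
print(f"near H-bond %: {stats.near_pct:.1f}   far H-bond %: {stats.far_pct:.1f}")
occupied = np.nonzero(stats.per_position_mean)[0] + 1
print("nucleotide positions with H-bonds:", occupied.tolist())

walk = synthetic.simulate_random_walk_trajectory(2000, n_beads=4, seed=3)
curve = trajectory.msd(walk)
print("\nrandom-walk MSD (nm^2) at lags 1, 10, 100:",
      [round(float(curve.msd[i]), 4) for i in (1, 10, 100)])
print(
    "\nTwo of three planted pairs sit within 6 A of the tube surface, so\n"
    "near% is about 67: binding-stabilising contacts. MSD grows linearly\n"
    "with lag for a free molecule; adsorbed DNA shows a flatter curve."
)
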