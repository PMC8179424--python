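"""Trajectory observables and the hierarchical timescale report.

Interpolates a trajectory from closed state A to the contracted closed
state B, computes the radius of gyration, a domain-fitted RMSD and an
inter-chain distance, and orders synthetic response curves with the
first-crossing event report.
"""

import numpy as np

import fretdyn as fd
from fretdyn.traj import Trajectory

a = fd.make_toy_dimer(8, "closedA", seed=1)
b = fd.make_toy_dimer(8, "closedB", seed=1)
coords = fd.interpolate_coords(a, b, 50)
traj = Trajectory.from_structure(a, coords)

rg = fd.radius_of_gyration(traj)
print(f"radius of gyration: {rg[0]:.2f} -> {rg[-1]:.2f} A "
      "(the contracted state is more compact)")

m_idx = traj.select(res_range=a.domain_map["M"])
n_idx = traj.select(res_range=a.domain_map["N"])
rmsd_m = fd.domain_rmsd(traj, n_idx, m_idx, coords[0])
print(f"M-domain RMSD in the N-domain frame: 0 -> {rmsd_m[-1]:.2f} A")

pair = fd.designated_pairs(a)[0]
d = fd.distance_series(traj, [a.atom_index(*pair[0])],
                       [a.atom_index(*pair[1])], mode="atom")
print(f"inter-chain M-domain distance: {d[0]:.1f} -> {d[-1]:.1f} A")

# hierarchical ordering on planted response curves
t = np.linspace(0, 500, 2000)
series = {name: (t, 1 / (1 + np.exp(-(t - mid) / (0.2 * mid))))
          for name, mid in [("nucleotide site", 1.0),
                            ("M-domain", 10.0), ("M-loop", 100.0)]}
report = fd.timescale_report(series, {k: 0.5 for k in series})
print("\nfirst-crossing event order (fast to slow):")
for _, row in report.iterrows():
    print(f"  {row['series']:>15s}  t = {row['event_time']:.1f}")
# The ordered events mirror a cascade: a fast local change precedes the
# domain rearrangement, which precedes the slow loop response.
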