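"""Recover the channel free-energy profile by umbrella sampling + WHAM.

81 harmonically biased windows (k = 5 kcal/mol/Å², 0.5 Å spacing) cover
the 0-40 Å reaction coordinate of the calibrated landscape; WHAM unbiases
the window histograms into one PMF, from which the escape barriers of the
three binding sites are read.
"""

import numpy as np

from poreflux import (
    UmbrellaSpec,
    barrier_heights,
    build_windows,
    default_channel_potential,
    sample_umbrella_windows,
    umbrella_config,
    wham_pmf,
    windows_from_series,
)

potential = default_channel_potential()
centers = build_windows(span=40.0, spacing=0.5)
print(f"{len(centers)} windows, 10'000 samples each")

cfg = umbrella_config(n_samples=10_000, seed=7)
series = sample_umbrella_windows(cfg, potential, [UmbrellaSpec(c, 5.0) for c in centers])
result = wham_pmf(windows_from_series(series))
print(f"WHAM converged={result.converged} after {result.iterations} iterations")

pmf = result.pmf
cov = pmf.covered
diff = pmf.free_energy[cov] - potential.single_ion_energy(pmf.z_centers[cov])
diff -= diff.mean()
print(f"RMS deviation from the analytic landscape: {np.sqrt((diff**2).mean()):.3f} kcal/mol")

barriers = barrier_heights(pmf, {"A": (22, 26), "B": (17, 21), "C": (7, 11)})
for label, b in barriers.items():
    print(f"site {label}: escape barrier {b.value:.2f} kcal/mol "
          f"(well at z={b.site_minimum_z:.1f}, top at z={b.barrier_top_z:.1f})")
print(
    "\nThe barriers should reproduce the 0.71 / 6.37 / 7.52 kcal/mol values\n"
    "the landscape was calibrated to; site C (just above the gate) is the\n"
    "rate-limiting step of inward permeation."
)
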