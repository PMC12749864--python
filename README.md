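# poreflux

Trajectory analysis and free-energy estimation for ion conduction
through channel pores, bundled with a Langevin channel simulator that
generates its own test data.

Cation channels such as TRPV1 conduct sodium through a pore with a
selectivity filter (binding sites A and B), a gate-adjacent site C and a
hydrophobic gate whose crossing is the rate-limiting step. Channel MD
studies characterise this with a standard chain of analyses, all of
which this package implements on a common in-memory `Trajectory`:

* **Permeation counting and conductance** — completed passages detected
  with a three-compartment state machine, converted to single-channel
  conductance via G = N·Q / (t·|V|), reported as mean ± sample SD over
  runs.
* **Pore-radius profiling** — largest inscribed sphere at each height z
  (HOLE-style), with mean ± SD profiles over frames and open/closed
  classification at the 1.4 Å (water) and 2.0 Å (hydrated cation)
  thresholds.
* **Ion density and binding sites** — time-averaged 3D number density
  (Å⁻³), thresholded at 0.005 Å⁻³ and segmented into 26-connected
  components; plus coordination-number counting (oxygens within 3 Å)
  and RMSD utilities.
* **Umbrella sampling + WHAM** — harmonically biased windows over the
  pore axis, unbiased with the self-consistent WHAM equations into a
  potential of mean force F(z) = −kT ln P(z), with overlap/convergence
  diagnostics and per-site escape-barrier extraction, including
  multi-ion configurations with restrained upstream ions (knock-off).

Because no deposited channel trajectories accompany the studies this
mirrors, the inputs come from a built-in overdamped Langevin simulator:
ions diffuse on a calibrated 1D axial landscape (three wells + gate
barrier, inward barriers 0.71 / 6.37 / 7.52 kcal/mol for A/B/C), under a
membrane-potential field and screened ion–ion repulsion, with radial
confinement and reservoir re-injection. The generator's ground truth is
known analytically, so every estimator is testable end to end.

## Worked example

Recover the free-energy profile by umbrella sampling
(`examples/umbrella_wham_pmf.py`):

```sh
$ python examples/umbrella_wham_pmf.py
81 windows, 10'000 samples each
WHAM converged=True after 8794 iterations
RMS deviation from the analytic landscape: 0.093 kcal/mol
site A: escape barrier 0.77 kcal/mol (well at z=24.0, top at z=22.0)
site B: escape barrier 6.42 kcal/mol (well at z=19.0, top at z=13.6)
site C: escape barrier 7.48 kcal/mol (well at z=8.9, top at z=4.0)
```

The 81 windows (0.5 Å spacing, k = 5 kcal/mol/Å²) cover the 0–40 Å
reaction coordinate; WHAM reassembles the landscape to better than
0.1 kcal/mol RMS and reads back the three escape barriers the potential
was calibrated to — site C, just above the gate, carries the
rate-limiting 7.5 kcal/mol barrier.

Binding sites from ion density (`examples/density_binding_sites.py`):

```sh
$ python examples/density_binding_sites.py
...
32 components above 0.005 Å^-3; top three:
  S1: peak 0.0220 Å^-3, centroid (-0.06, -0.10,  8.85) Å, 875 voxels
  S2: peak 0.0192 Å^-3, centroid (-0.13,  0.03, 18.97) Å, 674 voxels
  S3: peak 0.0164 Å^-3, centroid (-0.05,  0.01, 24.10) Å, 656 voxels

B-C site spacing: 10.12 Å (configured: 10 Å)
```

The three strongest density components recover the generator's well
centres (9, 19, 24 Å) to a tenth of a voxel, and the B–C spacing comes
out at the configured ~10 Å.

The other examples cover permeation/conductance, pore profiling and the
multi-ion barrier lowering; each prints what its numbers mean. A thin
CLI mirrors the library (`poreflux simulate|permeate|pore|density|
umbrella|wham|pipeline`), and `poreflux.pipeline.run_pipeline` chains
everything from one YAML config into a JSON report with TSV sidecars.

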