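# Methods

`poreflux` analyses ion conduction through a channel pore the way channel
MD studies do — permeation counting and conductance, inscribed-sphere
pore profiling, 3D density mapping of binding sites, coordination
counting, and umbrella-sampling/WHAM free energies — but generates its
own input trajectories with a Langevin channel simulator instead of
all-atom MD. This note records the model, its parameters, the numerical
choices, and what the synthetic generator does and does not emulate.

## The channel landscape

The single-ion free energy along the pore axis z is

    U(z) = Σ_wells  -d_i exp(-(z - z_i)² / 2w²)
         + Σ_barriers h_j exp(-(z - z_j)² / 2w_j²)
         - q·E·z                                (membrane field term)

with three binding wells (A, B, C) and one gate barrier below site C.
The default geometry places the gate top at z = 4 Å, site C at 9 Å,
site B at 19 Å and site A at 24 Å on a 0–40 Å reaction coordinate, so
the B–C spacing is the ~10 Å separation reported for TRPV1-like pores.
Gaussian widths are 1.0 Å (wells) and 1.2 Å (gate); wider wells are not
usable because the deep B well (6.37 kcal/mol) then swallows the shallow
A minimum (0.71 kcal/mol) entirely.

`make_channel_potential` calibrates the well depths and gate height by
fixed-point iteration until the *numerically scanned* inward escape
barriers (maximum of U between a well minimum and the next minimum
inward, minus the well value) match the targets 0.71 / 6.37 / 7.52
kcal/mol for A / B / C within 0.01 kcal/mol. The C-well depth is fixed
at 2.0 kcal/mol, which puts the gate top near +5.5; only barrier
*heights* are constrained by the calibration, not absolute levels.

Ion–ion interactions are a screened Coulomb pair term

    U_pair(r) = 332.06 q₁q₂ / (ε_r r) · exp(-r/λ),

with ε_r = 80 (bulk water) and λ = 7.9 Å, the Debye length of 150 mM
1:1 electrolyte at 310 K. These are physically motivated bulk values,
deliberately not fitted: in a real pore interior the effective
permittivity is far lower, which is why the all-atom barrier lowering
from an upstream ion (~2.4 kcal/mol) is two orders of magnitude larger
than this model's analytic −0.075 kcal/mol. The mechanism — the
resident ion at B raises the C well more than the gate top, because C
is closer — is reproduced exactly; its magnitude is not.

The membrane potential enters as a uniform axial field
E = V · 23.0609 / L_z kcal/mol/Å/e (for −100 mV over the ~170 Å box of
the source systems this reproduces the published −0.0135 value; over
this package's 60 Å default box it is −0.0384). Negative fields drive
cations toward −z, the intracellular side.

## The Langevin simulator

Overdamped Euler–Maruyama dynamics,

    Δr = (D/kT)·F·Δt + √(2DΔt)·ξ,

with D = 0.1 Å²/ps and Δt = 0.01 ps by default. The scheme is stable
when k_eff·(D/kT)·Δt < 2 for the stiffest local curvature; a runtime
guard aborts with advice whenever any single step exceeds 2 Å. At
T = 0 the noise vanishes and the mobility is evaluated at a 310 K
reference thermal energy (it would otherwise diverge), giving a
deterministic gradient quench.

Geometry: reflecting walls bound a 30 × 30 × 60 Å box (z from −10 to
50 Å, the 0–40 Å core being the pore); inside the pore region a
harmonic wall (k = 2 kcal/mol/Å² beyond a 3 Å radius) confines ions
laterally. An ion crossing the exit plane 1 Å above the bottom wall is
re-injected near the top of the extracellular reservoir at a
deterministic per-ion lateral offset (so two ions can never coincide),
after the exit is appended to a raw-exit log. Re-injection rather than
z-periodicity means the linear field term needs no sawtooth correction.
The default ion count (8) gives a reservoir concentration of order
150 mM for this box volume.

The simulator also keeps a step-resolution three-compartment ledger
(above z_top / pore / below z_bottom) and records every completed
passage. The analysis-side detector applied to a save_stride = 1
trajectory reproduces this ledger exactly; at coarser strides the two
can differ only by transits faster than the saving interval.

Randomness: one master seed spawns a PCG64 stream per ion (and per
window, keyed `(seed, window_index)`, for umbrella batches), so runs are
bitwise reproducible and a batched window equals the same window run
alone.

Umbrella sampling applies the harmonic bias ½k(z − c)² to a tagged ion
(k = 5 kcal/mol/Å² at 0.5 Å spacing by default) plus, for multi-ion
configurations, 2.5 kcal/mol/Å² z-restraints on extra ions at upstream
sites. Windows are initialised at their centres; the slow-pulling
window preparation used with all-atom systems is unnecessary here
because only the stationary window distribution enters WHAM. Umbrella
and equilibrium-statistics configurations extend the radial confinement
over the whole z-range so the accessible lateral area is independent of
z and the recovered PMF is exactly the configured axial landscape (the
permeation configuration confines only inside the pore, which is what
the reservoir picture requires).

### Two standard landscapes

* **Calibrated** (`default_channel_potential`): barriers 0.71/6.37/7.52
  kcal/mol. Used for everything PMF-related. Its gate is > 12 kT, so
  unbiased desk-scale trajectories essentially never cross it — as in
  the real channel, where spontaneous conduction relies on multi-ion
  barrier lowering that this model's bulk-screened repulsion cannot
  supply.
* **Conducting** (`conduction_channel_potential`): same geometry with
  wells of 1.0/1.2/1.2 kcal/mol and a 1.5 kcal/mol gate, chosen a
  priori from a Kramers-rate estimate so that a 20 ns, 8-ion run yields
  of order ten permeation events. Used for unbiased permeation,
  occupancy and density runs. Conductances computed from it are
  correspondingly far larger than a real channel's (hundreds of pS);
  they exercise the estimator, not the physiology.

## Analyses

**Permeation detection.** A per-ion three-compartment state machine:
an inward event is the ordered sequence above(z > z_top = 40) → pore →
below(z < z_bottom = −5); after an event the ion must re-enter the pore
from the *opposite* bulk before it can count again, so boundary
dithering is never double-counted. Events feed the conductance
G = N·Q/(t·|V|), reported per run with the mean and the n−1 sample SD
across runs (the convention that reproduces published ± values).
`unwrap_axis` (minimum-image unwrapping of z series) exists for
externally produced periodic trajectories; it must not be applied to
re-injected synthetic runs, whose large jumps are real teleports already
book-kept by the simulator.

**Cooperativity.** The knock-off statistic is the fraction of inward
events for which the previous site-B occupant becomes the site-C
occupant within ±1 ns of the C release (the permeating ion's last frame
in C). The underlying cooperative motion is a qualitative observation
in channel trajectories; this counting rule is this package's own
definition, and it returns *undefined* (not zero) when there are no
events.

**Pore profiling.** At each z the pore radius is max over in-plane
centres p of min over atoms (|(p,z) − x_i| − r_i), capped at 15 Å
(beyond which the point is flagged bulk) — the inscribed-sphere
definition. The search is a deterministic 1 Å multi-start grid within
the cap followed by Nelder–Mead refinement of the five best starts,
subject to the feasibility rule |p − guess| ≤ clearance(p): the
inscribed sphere must still enclose the axis point, otherwise the
maximisation tunnels through the channel wall into bulk solvent. The
built-in vdW table is a small Bondi-style set (H 1.20, C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, Na 2.27, Cl 1.75 Å), overridable by a
two-column `element radius` file; absolute radii for real structures
therefore depend on the table chosen. Profiles over frames report the
mean and the sample SD (exactly 0 for identical frames), and the
narrowest mean radius classifies the pore: < 1.4 Å closed (no water),
1.4–2.0 Å water-only, ≥ 2.0 Å permeable to hydrated cations.

**Ion density and binding sites.** Selected positions are histogrammed
on a 0.5 Å voxel grid and divided by frames × voxel volume, so density
integrates exactly to the mean in-grid ion count per frame. Voxels at
or above 0.005 Å⁻³ (the customary display isovalue for sodium density)
are segmented into 26-connected components, ranked by peak density,
with density-weighted centroids. On default conducting runs the three
top components recover the well centres to ~0.1 Å and the B–C spacing
to ~0.1 Å.

**Coordination and RMSD.** Coordination is the count of (oxygen) atoms
within 3 Å centre-to-centre of an ion, via a KD-tree; the batch form
follows the convention of averaging over the final stretch of a run
(default last 20 %). RMSD is per-frame √(mean squared deviation) from a
reference; optimal rigid-body superposition (centroid match + Kabsch
rotation via `scipy.spatial.transform.Rotation.align_vectors`) is
available but off by default, matching the common membrane-protein
usage where frames share a fixed laboratory frame.

## WHAM

The standard self-consistent equations on histogrammed windows
(0.1 Å bins):

    P(z) ∝ Σ_i n_i(z) / Σ_j N_j exp(β f_j − β w_j(z)),
    exp(−β f_j) = Σ_z P(z) exp(−β w_j(z)),    w_j(z) = ½k_j(z − c_j)²,

iterated in log space (logsumexp) until max |Δf_j| < 1e-6 kcal/mol
(max 10⁵ iterations; an exceeded budget sets an unconverged flag). The
PMF is −kT ln P anchored to min 0 over sampled bins; empty bins inside
the covered range are flagged as gaps and never interpolated, and
zero-overlap adjacent windows set a `disconnected` flag. Window
histogram overlap is Σ_z min(p̂_i, p̂_j). The first 30 % of each window
is discarded as burn-in (the analogue of keeping the last 7 ns of a
10 ns window); windows are sampled at 1 ps intervals (stride 100 at
Δt = 0.01 ps), a couple of relaxation times of the k = 5 bias, so 10⁴
samples carry a few thousand effective samples each.

**Barrier extraction.** For each site, the free-energy minimum inside
the site range must be a genuine interior well (otherwise the barrier
is reported as *not defined*, never 0); the barrier is the maximum of F
between that minimum and the next minimum inward of it — located with a
0.5 kcal/mol prominence filter so statistical ripple does not truncate
the segment — or the profile edge, minus the well value.

When comparing a recovered PMF with the analytic landscape, the
arbitrary additive constant is fixed by the mean difference over
covered bins before computing the RMS.

## Problem sizes and what the tests show

Default analysis sizes: 81 windows × 10⁴ samples for the full PMF
(~0.05–0.15 kcal/mol RMS against the analytic landscape; site-C barrier
recovered within ~0.1 of its 7.52 construction target), 31 windows for
the multi-ion stretch, 20 ns × 8 ions for permeation/density runs.
These are this package's desk-scale study conditions.

The paired-seed design matters for the multi-ion comparison: with
common noise streams, overdamped trajectories in slightly different
potentials stay synchronised, so the ~0.07 kcal/mol systematic barrier
lowering resolves in every replicate even though it is comparable to
the single-run statistical error.

Passing tests show that the estimators are correct on data whose ground
truth is known exactly. They do not show anything about force-field
accuracy, about hydration structure (the generator has no explicit
water — coordination analyses are exercised on constructed shells),
about lateral pore anatomy (the axis is fixed and straight), or about
absolute conductance magnitudes (see the conducting landscape above).

## Known limitations

* No explicit solvent, lipids or protein flexibility; the pore is a
  static 1D landscape plus a radial wall.
* Ion–ion repulsion uses bulk-water screening; knock-off energetics are
  qualitatively, not quantitatively, reproduced.
* WHAM reports no statistical error bars (no bootstrap); overlap and
  convergence diagnostics are provided instead.
* The pore profiler assumes a straight z axis; curved pore axes are out
  of scope.
* Binary trajectory formats (DCD/NetCDF) are not read; the documented
  XYZ/TSV dialects are the interchange formats.
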