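"""Multi-ion (knock-off) lowering of the gate escape barrier.

Recovers the PMF of a tagged ion over the 0-15 Å stretch spanning the
gate and binding site C, once alone and once with an upstream ion
restrained at site B (z = 19 Å, k = 2.5 kcal/mol/Å²).  The screened
Coulomb repulsion from the resident ion raises the C well more than the
gate top, so the escape barrier drops — the energetic signature of
cooperative knock-off conduction.
"""

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
centers = build_windows(span=15.0, spacing=0.5)
print(f"{len(centers)} windows over the gate + site C stretch")


def site_c_barrier(seed: int, extra_ions) -> float:
    specs = [
        UmbrellaSpec(c, 5.0, extra_ion_positions=extra_ions,
                     restraint_constant_extra=2.5)
        for c in centers
    ]
    cfg = umbrella_config(n_samples=10_000, seed=seed)
    series = sample_umbrella_windows(cfg, potential, specs)
    result = wham_pmf(windows_from_series(series))
    return barrier_heights(result.pmf, {"C": (7.0, 11.0)})["C"].value


for seed in range(3):
    alone = site_c_barrier(seed, ())
    with_b = site_c_barrier(seed, (19.0,))
    print(
        f"seed {seed}: barrier out of C = {alone:.3f} kcal/mol alone, "
        f"{with_b:.3f} with an ion at B (Δ = {with_b - alone:+.3f})"
    )

print(
    "\nThe lowering is small with the bulk-water screening defaults\n"
    "(ε_r = 80, λ = 7.9 Å) but systematic: paired seeds make the ordering\n"
    "resolve in every replicate.  In the real channel, where the pore\n"
    "interior screens far less, the same mechanism is worth ~2.4 kcal/mol."
)
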