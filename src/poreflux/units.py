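"""Physical constants and unit conversions.

The package-wide unit system is: length Å, time ns (ps inside the
integrator), energy kcal/mol, voltage mV, charge in elementary charges,
conductance pS. Every conversion between these systems is centralised
here so no other module carries its own constants.
"""

from __future__ import annotations

#: Boltzmann constant, kcal/mol/K.
BOLTZMANN_KCAL_MOL_K = 0.0019872041

#: Energy gained by one elementary charge crossing one volt, kcal/mol.
KCAL_MOL_PER_VOLT_E = 23.0609

#: Elementary charge, coulomb.
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: Coulomb prefactor q1*q2/r in kcal*Å/mol for charges in e.
COULOMB_PREFACTOR = 332.06

#: Debye screening length of a 150 mM 1:1 electrolyte at body
#: temperature (310 K), Å.  Used as the default screening length of the
#: ion-ion pair term.
DEBYE_LENGTH_150MM_310K = 7.9


def thermal_energy(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol for a temperature in kelvin."""
    if temperature < 0:
        raise ValueError(f"temperature must be >= 0 K, got {temperature}")
    return BOLTZMANN_KCAL_MOL_K * temperature


def field_from_potential(potential_mv: float, box_height: float) -> float:
    """Convert a transmembrane potential into a uniform axial field.

    The membrane potential is modelled as a constant electric field along
    the channel (z) axis, spread over the full box height, exactly the
    way MD engines apply an ``efz``-style external field.

    Parameters
    ----------
    potential_mv:
        Membrane potential in millivolt.  Negative values (physiological
        resting/hyperpolarised potentials) drive cations toward -z, the
        intracellular side.
    box_height:
        Periodic box height Lz in Å over which the potential drops.

    Returns
    -------
    float
        Field in kcal/mol/Å/e.  A charge q (in e) feels an axial force
        q * field.
    """
    if box_height <= 0:
        raise ValueError(f"box_height must be > 0 Å, got {box_height}")
    return (potential_mv / 1000.0) * KCAL_MOL_PER_VOLT_E / box_height
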