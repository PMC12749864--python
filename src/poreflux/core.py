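"""Shared domain types: particles, trajectories, atom sets, conductance.

The axis convention used throughout the package: the channel pore runs
along z, z = 0 sits at the intracellular reference plane (the analogue of
the E685 Cα plane of TRPV1) and z increases toward the extracellular
side.  Physiological inward flux (extracellular -> intracellular) is
therefore movement in the -z direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .units import ELEMENTARY_CHARGE_C

#: Default van der Waals radii, Å.  A deliberately small built-in table
#: (Bondi-style values); callers may override with their own element ->
#: radius mapping.  Unknown elements fall back to ``DEFAULT_VDW_RADIUS``.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "NA": 2.27,
    "CL": 1.75,
    "K": 2.75,
}

DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(species: str, table: Optional[dict] = None) -> float:
    tab = VDW_RADII if table is None else table
    return tab.get(species.upper(), DEFAULT_VDW_RADIUS)


@dataclass
class Particle:
    """One mobile particle (typically an ion) of a trajectory."""

    id: int
    species: str = "NA"
    charge: float = 1.0
    vdw_radius: Optional[float] = None

    def __post_init__(self):
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be > 0 when present")


@dataclass
class Trajectory:
    """Time-ordered particle coordinates with box metadata.

    positions has shape (n_frames, n_particles, 3) in Å, times is in ns
    and strictly increasing, box is (n_frames, 3) orthorhombic lengths.
    ``axis`` records the axis convention (z, intracellular origin).
    """

    particles: list
    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    axis: str = "z-intracellular-origin"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.broadcast_to(self.box, (len(self.times), 3)).copy()
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_particles, 3)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.positions.shape[1] != len(self.particles):
            raise ValueError("per-frame particle count does not match particles")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.box <= 0):
            raise ValueError("all box lengths must be > 0")
        ids = [p.id for p in self.particles]
        if len(set(ids)) != len(ids):
            raise ValueError("particle ids must be unique")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def z(self, particle_index: int) -> np.ndarray:
        """Axial coordinate series of one particle (by array index)."""
        return self.positions[:, particle_index, 2]

    def select_species(self, species: str) -> np.ndarray:
        """Array indices of all particles of a species."""
        want = species.upper()
        return np.array(
            [i for i, p in enumerate(self.particles) if p.species.upper() == want],
            dtype=int,
        )


@dataclass
class AtomSet:
    """A static set of atoms (species, position, vdW radius)."""

    species: list
    positions: np.ndarray
    radii: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if len(self.species) != len(self.positions) or len(self.radii) != len(
            self.positions
        ):
            raise ValueError("species, positions and radii must have equal length")
        if self.positions.size and not np.all(np.isfinite(self.positions)):
            raise ValueError("coordinates must be finite")
        if self.radii.size and np.any(self.radii <= 0):
            raise ValueError("vdW radii must be > 0")

    def __len__(self) -> int:
        return len(self.radii)


@dataclass
class ConductanceEstimate:
    """Single-channel conductance from per-run permeation counts.

    Each run contributes G = N * Q / (t * |V|): N permeation events of
    charge Q (in e) over t nanoseconds under a membrane potential V (mV).
    The mean and the sample standard deviation (n-1 denominator, the
    convention matching reported ± values) summarise the runs.
    """

    per_run_pS: np.ndarray
    mean_pS: float
    sd_pS: Optional[float]
    n_events: np.ndarray
    durations_ns: np.ndarray
    potential_mV: float
    ion_charge_e: float


def conductance_estimate(
    event_counts: Sequence[int],
    durations_ns: Sequence[float],
    potential_mV: float,
    ion_charge_e: float = 1.0,
) -> ConductanceEstimate:
    """Estimate channel conductance from permeation counts.

    Parameters
    ----------
    event_counts:
        Number of completed permeation events per independent run.
    durations_ns:
        Length of each run in ns (same order as ``event_counts``).
    potential_mV:
        Membrane potential in mV (must be non-zero; the sign does not
        affect the magnitude of the conductance).
    ion_charge_e:
        Charge of the permeating ion in elementary charges.
    """
    counts = np.asarray(event_counts, dtype=float)
    durations = np.asarray(durations_ns, dtype=float)
    if counts.shape != durations.shape:
        raise ValueError("event_counts and durations_ns must have equal length")
    if counts.size == 0:
        raise ValueError("at least one run is required")
    if np.any(counts < 0):
        raise ValueError("event counts must be >= 0")
    if np.any(durations <= 0):
        raise ValueError("durations must be > 0 ns")
    if potential_mV == 0:
        raise ValueError("potential must be non-zero (conductance undefined at 0 mV)")

    t_seconds = durations * 1e-9
    v_volt = abs(potential_mV) / 1000.0
    g_siemens = counts * (ion_charge_e * ELEMENTARY_CHARGE_C) / (t_seconds * v_volt)
    per_run_ps = g_siemens * 1e12
    mean = float(np.mean(per_run_ps))
    sd = float(np.std(per_run_ps, ddof=1)) if per_run_ps.size > 1 else None
    if sd is not None and math.isnan(sd):  # pragma: no cover - defensive
        sd = None
    return ConductanceEstimate(
        per_run_pS=per_run_ps,
        mean_pS=mean,
        sd_pS=sd,
        n_events=np.asarray(event_counts, dtype=int),
        durations_ns=durations,
        potential_mV=potential_mV,
        ion_charge_e=ion_charge_e,
    )
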