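"""Permeation-event detection, site occupancy and cooperativity.

A permeation event is one ion's complete passage through the pore: for
an inward (physiological influx) event the ion is seen above the
extracellular plane ``z_top``, then inside the pore compartment, then
below the intracellular plane ``z_bottom``.  A three-compartment state
machine per ion enforces that an ion must re-enter the pore from the
*opposite* bulk compartment before it can count again, so dithering
across a single boundary is never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import Trajectory


@dataclass(frozen=True)
class PermeationEvent:
    """One completed passage of one ion."""

    ion_id: int
    t_enter_ns: float
    t_exit_ns: float
    direction: str  # "inward" | "outward"

    def __post_init__(self):
        if self.t_exit_ns <= self.t_enter_ns:
            raise ValueError("t_exit must be after t_enter")
        if self.direction not in ("inward", "outward"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class SiteDefinition:
    """Axial (and optional radial) extent of one binding site."""

    label: str
    z_range: Tuple[float, float]
    radial_cutoff: Optional[float] = None

    def __post_init__(self):
        lo, hi = self.z_range
        if hi <= lo:
            raise ValueError(f"site {self.label}: z_range must be increasing")
        if self.radial_cutoff is not None and self.radial_cutoff <= 0:
            raise ValueError(f"site {self.label}: radial cutoff must be > 0")


#: Default site boxes matching the generator's well centers (A 24, B 19,
#: C 9 Å), each ±2 Å.
DEFAULT_SITES = (
    SiteDefinition("A", (22.0, 26.0)),
    SiteDefinition("B", (17.0, 21.0)),
    SiteDefinition("C", (7.0, 11.0)),
)


@dataclass
class OccupancyTable:
    """Per-frame site occupants (ion ids; a site may hold several)."""

    times_ns: np.ndarray
    occupants: Dict[str, List[Tuple[int, ...]]]

    @property
    def labels(self) -> List[str]:
        return list(self.occupants)

    def fraction_occupied(self, label: str) -> float:
        occ = self.occupants[label]
        return sum(1 for o in occ if o) / len(occ)


@dataclass
class CooperativityResult:
    """Fraction of inward events with a B -> C hand-off near the release.

    ``fraction`` is None (undefined, not zero) when there are no events.
    """

    n_events: int
    n_handoffs: int

    @property
    def fraction(self) -> Optional[float]:
        if self.n_events == 0:
            return None
        return self.n_handoffs / self.n_events


def unwrap_axis(traj: Trajectory) -> Trajectory:
    """Minimum-image unwrap of each ion's axial (z) series.

    Inter-frame jumps larger than half the box height are treated as
    periodic-image artifacts and folded out, making each z series
    continuous.  The input trajectory is left untouched.  Do not apply
    this to trajectories produced with reservoir re-injection (their
    large jumps are real teleports, already book-kept by the simulator).
    """
    if traj.box is None or traj.box.size == 0:
        raise ValueError("trajectory has no box information")
    z = traj.positions[:, :, 2]
    lz = traj.box[:, 2]
    dz = np.diff(z, axis=0)
    shift = np.where(dz > lz[1:, None] / 2, -1.0, 0.0) + np.where(
        dz < -lz[1:, None] / 2, 1.0, 0.0
    )
    corr = np.concatenate(
        [np.zeros((1, z.shape[1])), np.cumsum(shift * lz[1:, None], axis=0)], axis=0
    )
    positions = traj.positions.copy()
    positions[:, :, 2] = z + corr
    return Trajectory(
        particles=traj.particles,
        times=traj.times.copy(),
        positions=positions,
        box=traj.box.copy(),
        axis=traj.axis,
        metadata=dict(traj.metadata, unwrapped=True),
    )


def detect_permeations(
    traj: Trajectory,
    z_top: float = 40.0,
    z_bottom: float = -5.0,
    particle_indices: Optional[Sequence[int]] = None,
    invert_axis: bool = False,
) -> List[PermeationEvent]:
    """Detect completed passages from a (frame-sampled) trajectory.

    An inward event is the ordered compartment sequence
    above(z > z_top) -> pore -> below(z < z_bottom); outward events are
    the mirror image.  Events are returned sorted by exit time.  With
    ``invert_axis`` the direction labels are flipped for trajectories
    recorded with the opposite orientation convention.
    """
    if z_top <= z_bottom:
        raise ValueError("z_top must be greater than z_bottom")
    idx = range(traj.n_particles) if particle_indices is None else particle_indices
    times = traj.times
    events: List[PermeationEvent] = []
    for i in idx:
        z = traj.positions[:, i, 2]
        comp = np.where(z > z_top, 0, np.where(z < z_bottom, 2, 1))
        came_from = -1
        t_enter = 0.0
        state = comp[0]
        changes = np.nonzero(np.diff(comp))[0] + 1
        for f in changes:
            nc = comp[f]
            if nc == 1:
                came_from = state
                t_enter = times[f]
            elif nc == 2 and state == 1 and came_from == 0:
                events.append(
                    PermeationEvent(
                        traj.particles[i].id,
                        t_enter,
                        times[f],
                        "outward" if invert_axis else "inward",
                    )
                )
                came_from = -1
            elif nc == 0 and state == 1 and came_from == 2:
                events.append(
                    PermeationEvent(
                        traj.particles[i].id,
                        t_enter,
                        times[f],
                        "inward" if invert_axis else "outward",
                    )
                )
                came_from = -1
            state = nc
    events.sort(key=lambda e: e.t_exit_ns)
    return events


def _validate_sites(sites: Sequence[SiteDefinition]) -> List[SiteDefinition]:
    ordered = sorted(sites, key=lambda s: s.z_range[0])
    for a, b in zip(ordered, ordered[1:]):
        if b.z_range[0] < a.z_range[1]:
            raise ValueError(f"site z-ranges overlap: {a.label} and {b.label}")
    return list(sites)


def site_occupancy(
    traj: Trajectory,
    sites: Sequence[SiteDefinition] = DEFAULT_SITES,
    particle_indices: Optional[Sequence[int]] = None,
) -> OccupancyTable:
    """Per-frame assignment of ions to binding sites.

    An ion occupies a site when its z lies in the site's range (and its
    lateral distance from the axis is within the radial cutoff, if set).
    Non-overlapping ranges guarantee at most one site per ion per frame;
    a site may hold several ions (multi-occupancy, as at site A).
    """
    sites = _validate_sites(sites)
    idx = (
        np.arange(traj.n_particles)
        if particle_indices is None
        else np.asarray(particle_indices, dtype=int)
    )
    pos = traj.positions[:, idx, :]
    ids = np.array([traj.particles[i].id for i in idx])
    occupants: Dict[str, List[Tuple[int, ...]]] = {}
    rho = None
    for site in sites:
        lo, hi = site.z_range
        inside = (pos[:, :, 2] >= lo) & (pos[:, :, 2] < hi)
        if site.radial_cutoff is not None:
            if rho is None:
                rho = np.sqrt(pos[:, :, 0] ** 2 + pos[:, :, 1] ** 2)
            inside &= rho <= site.radial_cutoff
        occupants[site.label] = [tuple(ids[row]) for row in inside]
    return OccupancyTable(times_ns=traj.times.copy(), occupants=occupants)


def cooperativity_fraction(
    occ: OccupancyTable,
    events: Sequence[PermeationEvent],
    window_ns: float = 1.0,
    site_b: str = "B",
    site_c: str = "C",
) -> CooperativityResult:
    """Knock-off statistic: fraction of inward events whose site-C
    release is accompanied by the previous site-B occupant moving into
    site C within ±``window_ns``.

    The release time of an event is the last frame at which the
    permeating ion still occupies site C before its exit.  This is an
    artifact-defined metric: cooperative multi-ion conduction is shown
    qualitatively in the source trajectories, and this statistic makes
    it countable.
    """
    if window_ns <= 0:
        raise ValueError("window must be > 0 ns")
    inward = [e for e in events if e.direction == "inward"]
    times = occ.times_ns
    occ_b = occ.occupants[site_b]
    occ_c = occ.occupants[site_c]
    n_handoffs = 0
    for ev in inward:
        in_c = np.array(
            [(ev.ion_id in o) and (t <= ev.t_exit_ns) for o, t in zip(occ_c, times)]
        )
        if not in_c.any():
            continue
        f_release = int(np.nonzero(in_c)[0][-1])
        t_release = times[f_release]
        prev_b = occ_b[f_release]
        if not prev_b:
            continue
        lo = t_release - window_ns
        hi = t_release + window_ns
        frames = np.nonzero((times >= lo) & (times <= hi))[0]
        if any(any(b in occ_c[f] for b in prev_b) for f in frames):
            n_handoffs += 1
    return CooperativityResult(n_events=len(inward), n_handoffs=n_handoffs)


def events_per_run(events: Sequence[PermeationEvent], direction: str = "inward") -> int:
    """Count events of one direction (convenience for conductance input)."""
    return sum(1 for e in events if e.direction == direction)
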