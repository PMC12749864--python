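"""Inscribed-sphere (HOLE-style) pore-radius profiling.

At each position z along the channel axis the pore radius is the radius
of the largest sphere centred in the plane z that touches no atom:

    radius(p, z) = min_i ( |(p, z) - x_i| - vdw_i )

maximised over the in-plane centre p.  The maximisation uses a
deterministic multi-start grid followed by derivative-free (Nelder-Mead)
refinement; radii are capped at 15 Å, beyond which the point is flagged
as bulk solvent (the usual HOLE convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize

from .core import AtomSet, Trajectory, vdw_radius

#: Pore-state classification thresholds, Å: below 1.4 not even water
#: passes; between 1.4 and 2.0 water but not hydrated cations; at or
#: above 2.0 the pore is permeable to (partially) hydrated cations.
WATER_RADIUS = 1.4
CATION_RADIUS = 2.0

SEARCH_CAP = 15.0


@dataclass
class SliceRadius:
    radius: float
    center: Tuple[float, float]
    bulk: bool


@dataclass
class PoreProfile:
    """Mean ± SD pore radius along z over a set of frames."""

    z_grid: np.ndarray
    radius_mean: np.ndarray
    radius_sd: np.ndarray
    n_frames: int
    stride: int = 1

    def __post_init__(self):
        if np.any(self.radius_mean < 0) or np.any(self.radius_mean > SEARCH_CAP + 1e-9):
            raise ValueError("radii must lie in [0, search cap]")

    @property
    def min_radius(self) -> Tuple[float, float]:
        """(value Å, z location) of the narrowest point of the mean profile."""
        i = int(np.argmin(self.radius_mean))
        return float(self.radius_mean[i]), float(self.z_grid[i])


def _clearance(points: np.ndarray, z: float, atoms: AtomSet) -> np.ndarray:
    """min over atoms of (3D distance - vdw) for in-plane points (m, 2)."""
    p3 = np.concatenate(
        [points, np.full((len(points), 1), z)], axis=1
    )  # (m, 3)
    d = np.linalg.norm(p3[:, None, :] - atoms.positions[None, :, :], axis=2)
    return np.min(d - atoms.radii[None, :], axis=1)


def slice_radius(
    atoms: AtomSet,
    z: float,
    axis_guess: Tuple[float, float] = (0.0, 0.0),
    cap: float = SEARCH_CAP,
    grid_spacing: float = 1.0,
    n_refine: int = 5,
) -> SliceRadius:
    """Largest inscribed-sphere radius in the plane at height z.

    Multi-start: a fixed grid of candidate centres (spacing
    ``grid_spacing``) within ``cap`` of ``axis_guess`` seeds Nelder-Mead
    refinements of the ``n_refine`` best starts; the search is fully
    deterministic.  If no atom constrains the slice the radius is capped
    and the result flagged as bulk.
    """
    guess = np.asarray(axis_guess, dtype=float)
    if len(atoms) == 0:
        return SliceRadius(cap, (float(guess[0]), float(guess[1])), True)

    # Feasibility: the inscribed sphere must still enclose the axis point
    # (|p - guess| <= clearance(p)); without it the maximisation tunnels
    # through the channel wall into bulk solvent.  Infeasible points score
    # the (negative) constraint violation so refinement is driven back in.
    def capped_clearance(points: np.ndarray) -> np.ndarray:
        return np.minimum(_clearance(points, z, atoms), cap)

    def offset(points: np.ndarray) -> np.ndarray:
        return np.hypot(points[:, 0] - guess[0], points[:, 1] - guess[1])

    def score(points: np.ndarray) -> np.ndarray:
        v = capped_clearance(points)
        gap = offset(points) - v
        return np.where(gap <= 0, v, -gap)

    ticks = np.arange(-cap, cap + grid_spacing / 2, grid_spacing)
    gx, gy = np.meshgrid(ticks, ticks, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
    grid = grid[np.hypot(grid[:, 0], grid[:, 1]) <= cap] + guess

    vals = score(grid)
    order = np.argsort(vals)[::-1]
    candidates = [grid[order[0]]]
    for k in order[:n_refine]:
        res = minimize(
            lambda p: -score(p.reshape(1, 2))[0],
            grid[k],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400},
        )
        candidates.append(res.x)
    pts = np.asarray(candidates)
    v = capped_clearance(pts)
    feasible = offset(pts) <= v + 1e-6
    if not feasible.any():
        return SliceRadius(0.0, (float(guess[0]), float(guess[1])), False)
    i = int(np.nonzero(feasible)[0][np.argmax(v[feasible])])
    best_p = pts[i]
    radius = float(np.clip(v[i], 0.0, cap))
    return SliceRadius(radius, (float(best_p[0]), float(best_p[1])), radius >= cap)


def _frame_atomsets(
    frames: Union[Trajectory, Sequence[AtomSet]],
    stride: int,
    radius_table: Optional[dict],
) -> list:
    if isinstance(frames, Trajectory):
        radii = np.array(
            [
                p.vdw_radius if p.vdw_radius else vdw_radius(p.species, radius_table)
                for p in frames.particles
            ]
        )
        species = [p.species for p in frames.particles]
        return [
            AtomSet(species=species, positions=frames.positions[f], radii=radii)
            for f in range(0, frames.n_frames, stride)
        ]
    return list(frames)[::stride]


def profile_over_frames(
    frames: Union[Trajectory, Sequence[AtomSet]],
    z_grid: Optional[np.ndarray] = None,
    stride: int = 1,
    axis_guess: Tuple[float, float] = (0.0, 0.0),
    cap: float = SEARCH_CAP,
    radius_table: Optional[dict] = None,
) -> PoreProfile:
    """Pore-radius profile (mean and sample SD across frames).

    ``frames`` is a Trajectory (converted per frame with the active vdW
    radius table) or a sequence of AtomSets.  ``z_grid`` defaults to
    0.5 Å spacing over the atoms' z extent.
    """
    atomsets = _frame_atomsets(frames, max(int(stride), 1), radius_table)
    if not atomsets:
        raise ValueError("empty frame selection")
    if z_grid is None:
        zmin = min(a.positions[:, 2].min() for a in atomsets if len(a))
        zmax = max(a.positions[:, 2].max() for a in atomsets if len(a))
        z_grid = np.arange(zmin, zmax + 0.25, 0.5)
    z_grid = np.asarray(z_grid, dtype=float)

    radii = np.empty((len(atomsets), len(z_grid)))
    for f, aset in enumerate(atomsets):
        for k, z in enumerate(z_grid):
            radii[f, k] = slice_radius(aset, z, axis_guess=axis_guess, cap=cap).radius
    mean = radii.mean(axis=0)
    sd = radii.std(axis=0, ddof=1) if len(atomsets) > 1 else np.zeros_like(mean)
    sd[np.ptp(radii, axis=0) == 0.0] = 0.0  # identical frames: SD exactly 0
    return PoreProfile(
        z_grid=z_grid,
        radius_mean=mean,
        radius_sd=sd,
        n_frames=len(atomsets),
        stride=max(int(stride), 1),
    )


def classify_pore_state(profile: PoreProfile) -> str:
    """closed (< 1.4 Å), water-only (1.4-2.0 Å) or cation-permeable (>= 2 Å),
    judged at the narrowest point of the mean profile."""
    if profile.z_grid.size == 0:
        raise ValueError("empty profile")
    rmin, _ = profile.min_radius
    if rmin < WATER_RADIUS:
        return "closed"
    if rmin < CATION_RADIUS:
        return "water-only"
    return "cation-permeable"
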