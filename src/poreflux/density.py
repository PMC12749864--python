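"""Time-averaged 3D ion density, binding-site segmentation, coordination
counting and RMSD utilities.

The density grid is a per-frame-normalised position histogram in Å⁻³,
so integrating density x voxel volume recovers the mean number of
selected ions inside the grid per frame.  Binding sites are segmented by
thresholding the grid (default 0.005 Å⁻³, the isovalue used to display
sodium density in the source channel study) and grouping voxels into
26-connected components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import AtomSet, Trajectory

DEFAULT_DENSITY_THRESHOLD = 0.005  # Å^-3


@dataclass
class DensityGrid:
    """Time-averaged number density on a regular voxel grid."""

    origin: np.ndarray  # (3,) lower corner, Å
    voxel_edge: float
    density: np.ndarray  # (nx, ny, nz), Å^-3
    n_frames: int
    selection: str = ""

    @property
    def voxel_volume(self) -> float:
        return self.voxel_edge**3

    def integral(self) -> float:
        """Mean selected-particle count inside the grid per frame."""
        return float(self.density.sum() * self.voxel_volume)

    def voxel_centers(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.density.shape
        cs = [
            self.origin[d] + self.voxel_edge * (np.arange(n) + 0.5)
            for d, n in zip(range(3), (nx, ny, nz))
        ]
        return cs[0], cs[1], cs[2]


@dataclass
class BindingSite:
    """One connected above-threshold density component."""

    label: str
    peak_density: float
    centroid: np.ndarray  # density-weighted, Å
    n_voxels: int
    z_extent: Tuple[float, float]


def _resolve_selection(traj: Trajectory, selection) -> np.ndarray:
    if isinstance(selection, str):
        idx = traj.select_species(selection)
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no particles")
    return idx


def density_grid(
    traj: Trajectory,
    selection: Union[str, Sequence[int]] = "NA",
    voxel_edge: float = 0.5,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    frame_slice: slice = slice(None),
) -> DensityGrid:
    """Histogram selected particle positions into a density grid.

    ``bounds`` is ((x0,x1),(y0,y1),(z0,z1)); each axis is covered by
    floor((hi-lo)/voxel_edge) whole voxels starting at the lower bound.
    The result is counts / (n_frames * voxel volume), i.e. Å⁻³.
    """
    if voxel_edge <= 0:
        raise ValueError("voxel_edge must be > 0")
    idx = _resolve_selection(traj, selection)
    pos = traj.positions[frame_slice][:, idx, :]
    n_frames = pos.shape[0]
    if n_frames == 0:
        raise ValueError("frame selection is empty")
    if bounds is None:
        lo = pos.reshape(-1, 3).min(axis=0)
        hi = pos.reshape(-1, 3).max(axis=0) + 1e-9
        bounds = tuple(zip(lo, hi))
    edges = []
    for (lo, hi) in bounds:
        n = int(np.floor((hi - lo) / voxel_edge + 1e-9))
        if n < 1:
            raise ValueError("bounds must enclose at least one voxel per axis")
        edges.append(lo + voxel_edge * np.arange(n + 1))
    counts, _ = np.histogramdd(pos.reshape(-1, 3), bins=edges)
    density = counts / (n_frames * voxel_edge**3)
    return DensityGrid(
        origin=np.array([e[0] for e in edges]),
        voxel_edge=voxel_edge,
        density=density,
        n_frames=n_frames,
        selection=str(selection),
    )


def find_binding_sites(
    grid: DensityGrid, threshold: float = DEFAULT_DENSITY_THRESHOLD
) -> List[BindingSite]:
    """Segment above-threshold voxels into candidate binding sites.

    Voxels with density >= threshold are grouped by 26-neighbour
    connectivity; components are ranked by their peak density and
    reported with density-weighted centroids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mask = grid.density >= threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return []
    cx, cy, cz = grid.voxel_centers()
    sites = []
    for lab in range(1, n + 1):
        sel = labels == lab
        w = grid.density[sel]
        ix, iy, iz = np.nonzero(sel)
        wsum = w.sum()
        centroid = np.array(
            [
                float(np.dot(w, cx[ix])) / wsum,
                float(np.dot(w, cy[iy])) / wsum,
                float(np.dot(w, cz[iz])) / wsum,
            ]
        )
        sites.append(
            BindingSite(
                label="",
                peak_density=float(w.max()),
                centroid=centroid,
                n_voxels=int(sel.sum()),
                z_extent=(float(cz[iz].min()), float(cz[iz].max())),
            )
        )
    sites.sort(key=lambda s: -s.peak_density)
    for rank, s in enumerate(sites, start=1):
        s.label = f"S{rank}"
    return sites


def coordination_count(
    ion_position: Sequence[float],
    atoms: AtomSet,
    cutoff: float = 3.0,
    species: Optional[str] = "O",
) -> int:
    """Number of atoms (of one species) within ``cutoff`` of an ion.

    Centre-to-centre distances; the 3 Å oxygen count is the standard
    proxy for an ion's hydration/contact shell.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if len(atoms) == 0:
        return 0
    keep = (
        np.ones(len(atoms), dtype=bool)
        if species is None
        else np.array([s.upper() == species.upper() for s in atoms.species])
    )
    pts = atoms.positions[keep]
    if len(pts) == 0:
        return 0
    tree = cKDTree(pts)
    return int(len(tree.query_ball_point(np.asarray(ion_position, dtype=float), cutoff)))


def coordination_series(
    traj: Trajectory,
    ion_index: int,
    partner_indices: Sequence[int],
    cutoff: float = 3.0,
    tail_fraction: float = 0.2,
) -> Tuple[np.ndarray, float]:
    """Per-frame coordination counts over the final part of a run.

    Mirrors the convention of counting over the last stretch of each
    trajectory (default: final 20 %, as in 300 of 1500 ns); returns the
    per-frame counts and their mean.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    start = int(round(traj.n_frames * (1 - tail_fraction)))
    partners = np.asarray(partner_indices, dtype=int)
    ion = traj.positions[start:, ion_index, :]
    pts = traj.positions[start:, partners, :]
    d = np.linalg.norm(pts - ion[:, None, :], axis=2)
    counts = (d <= cutoff).sum(axis=1)
    return counts, float(counts.mean())


def rmsd_series(
    traj: Trajectory,
    reference: Union[int, np.ndarray] = 0,
    selection: Optional[Sequence[int]] = None,
    superpose: bool = False,
) -> np.ndarray:
    """Root-mean-square deviation of each frame from a reference.

    ``reference`` is a frame index or an (n, 3) coordinate array.  With
    ``superpose`` the optimal rigid-body fit (centroid match + Kabsch
    least-squares rotation) is applied before computing the deviation;
    the default is off, matching the common membrane-protein usage where
    frames are already in a fixed laboratory frame.
    """
    idx = (
        np.arange(traj.n_particles)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    ref = (
        traj.positions[reference][idx]
        if isinstance(reference, (int, np.integer))
        else np.asarray(reference, dtype=float)
    )
    if ref.shape != (len(idx), 3):
        raise ValueError("reference shape does not match the selection")
    out = np.empty(traj.n_frames)
    ref_c = ref - ref.mean(axis=0)
    for f in range(traj.n_frames):
        x = traj.positions[f][idx]
        if superpose:
            xc = x - x.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, xc)
            x = rot.apply(xc)
            d = x - ref_c
        else:
            d = x - ref
        out[f] = np.sqrt((d**2).sum() / len(idx))
    return out
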