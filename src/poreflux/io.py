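"""Readers and writers for the package's text formats.

Formats (full column orders in docs/FORMATS.md):

* extended XYZ — per-frame comment line ``time_ns=<t> box=<Lx> <Ly> <Lz>``;
  the first frame's comment additionally carries ``seed=<s>`` when known.
* trajectory TSV — columns ``frame  time_ns  particle_id  species  x  y  z``
  with ``# key = value`` comment headers (box, seed).
* umbrella window samples — two-column TSV ``time_ns  z``.
* WHAM metadata — one window per line: ``samples_path  center  force_constant``
  (the widespread WHAM metadata layout).
* PMF TSV — ``z  free_energy_kcal_mol  n_samples``.
* density — OpenDX-style scalar grid text, or a TSV voxel list.
* PDB — read-only, via biotite; element names map to the active vdW table.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import VDW_RADII, AtomSet, Particle, Trajectory, vdw_radius
from .density import DensityGrid
from .simulate import WindowSamples
from .wham import PMFProfile, UmbrellaWindow

logger = logging.getLogger("poreflux")

_SPECIES_CHARGE = {"NA": 1.0, "K": 1.0, "CL": -1.0}


def _charge_for(species: str) -> float:
    return _SPECIES_CHARGE.get(species.upper(), 0.0)


# ---------------------------------------------------------------------------
# Trajectories


def write_trajectory_xyz(traj: Trajectory, path) -> None:
    seed = traj.metadata.get("seed")
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            bx, by, bz = traj.box[f]
            comment = f"time_ns={traj.times[f]:.6f} box={bx:.6f} {by:.6f} {bz:.6f}"
            if f == 0 and seed is not None:
                comment += f" seed={seed}"
            fh.write(comment + "\n")
            for p, (x, y, z) in zip(traj.particles, traj.positions[f]):
                fh.write(f"{p.species} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory_xyz(path) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    frames: List[np.ndarray] = []
    times: List[float] = []
    boxes: List[Tuple[float, float, float]] = []
    species: Optional[List[str]] = None
    seed = None
    ln = 0
    n_total = len(lines)
    while ln < n_total:
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError:
            raise ValueError(f"{path}:{ln + 1}: expected an atom count")
        meta = dict(
            kv.split("=", 1) for kv in _split_meta(lines[ln + 1]) if "=" in kv
        )
        if "time_ns" not in meta or "box" not in meta:
            raise ValueError(f"{path}:{ln + 2}: frame comment must carry time_ns and box")
        times.append(float(meta["time_ns"]))
        boxes.append(tuple(float(v) for v in meta["box"].split()))
        if "seed" in meta:
            seed = int(meta["seed"])
        block = lines[ln + 2 : ln + 2 + n]
        if len(block) < n:
            raise ValueError(
                f"{path}:{ln + 2}: frame {len(frames)} declares {n} atoms but the "
                f"file ends after {len(block)}"
            )
        sp = []
        coords = np.empty((n, 3))
        for k, row in enumerate(block):
            parts = row.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln + 3 + k}: expected 'species x y z'")
            sp.append(parts[0])
            coords[k] = [float(v) for v in parts[1:]]
        if species is None:
            species = sp
        elif sp != species or n != len(species):
            raise ValueError(
                f"{path}:{ln + 1}: frame {len(frames)} has an inconsistent particle list"
            )
        frames.append(coords)
        ln += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames parsed")
    particles = [Particle(i, s, _charge_for(s)) for i, s in enumerate(species)]
    md = {} if seed is None else {"seed": seed}
    return Trajectory(
        particles=particles,
        times=np.array(times),
        positions=np.stack(frames),
        box=np.array(boxes),
        metadata=md,
    )


def _split_meta(comment: str) -> List[str]:
    # tokens are key=value; 'box=' consumes the following two bare tokens
    toks = comment.split()
    out: List[str] = []
    i = 0
    while i < len(toks):
        t = toks[i]
        if t.startswith("box=") and i + 2 < len(toks):
            out.append(f"box={t[4:]} {toks[i + 1]} {toks[i + 2]}")
            i += 3
        else:
            out.append(t)
            i += 1
    return out


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    seed = traj.metadata.get("seed")
    bx, by, bz = traj.box[0]
    with open(path, "w") as fh:
        fh.write(f"# box = {bx:.6f} {by:.6f} {bz:.6f}\n")
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        fh.write("frame\ttime_ns\tparticle_id\tspecies\tx\ty\tz\n")
        for f in range(traj.n_frames):
            t = traj.times[f]
            for p, (x, y, z) in zip(traj.particles, traj.positions[f]):
                fh.write(f"{f}\t{t:.6f}\t{p.id}\t{p.species}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_trajectory_tsv(path) -> Trajectory:
    box = None
    seed = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("box"):
                    box = tuple(float(v) for v in body.split("=", 1)[1].split())
                elif body.startswith("seed"):
                    seed = int(body.split("=", 1)[1])
                continue
            if line.startswith("frame\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{ln}: expected 7 tab-separated columns")
            rows.append(
                (int(parts[0]), float(parts[1]), int(parts[2]), parts[3],
                 float(parts[4]), float(parts[5]), float(parts[6]))
            )
    if not rows:
        raise ValueError(f"{path}: no data rows parsed")
    if box is None:
        raise ValueError(f"{path}: missing '# box = Lx Ly Lz' header")
    n_frames = max(r[0] for r in rows) + 1
    first = [r for r in rows if r[0] == 0]
    ids = [r[2] for r in first]
    species = [r[3] for r in first]
    n = len(first)
    order = {pid: k for k, pid in enumerate(ids)}
    positions = np.full((n_frames, n, 3), np.nan)
    times = np.full(n_frames, np.nan)
    per_frame = np.zeros(n_frames, dtype=int)
    for f, t, pid, sp, x, y, z in rows:
        positions[f, order[pid]] = (x, y, z)
        times[f] = t
        per_frame[f] += 1
    bad = np.nonzero(per_frame != n)[0]
    if bad.size:
        raise ValueError(
            f"{path}: frame {bad[0]} has {per_frame[bad[0]]} particles, expected {n}"
        )
    if np.any(np.isnan(times)) or (n_frames > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError(f"{path}: frame times are missing or not strictly increasing")
    particles = [Particle(pid, sp, _charge_for(sp)) for pid, sp in zip(ids, species)]
    md = {} if seed is None else {"seed": seed}
    return Trajectory(
        particles=particles,
        times=times,
        positions=positions,
        box=np.tile(np.asarray(box, dtype=float), (n_frames, 1)),
        metadata=md,
    )


def read_trajectory(path, format: Optional[str] = None) -> Trajectory:
    """Dispatch on ``format`` or the file suffix (.xyz / .tsv)."""
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        return read_trajectory_xyz(path)
    if fmt == "tsv":
        return read_trajectory_tsv(path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def write_trajectory(traj: Trajectory, path, format: Optional[str] = None) -> None:
    fmt = format or Path(path).suffix.lstrip(".").lower()
    if fmt == "xyz":
        return write_trajectory_xyz(traj, path)
    if fmt == "tsv":
        return write_trajectory_tsv(traj, path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# Static structures (PDB, read-only)


def read_structure(path, radius_table: Optional[dict] = None) -> AtomSet:
    """Read ATOM/HETATM records of a PDB file into an AtomSet.

    Elements are mapped to vdW radii through the active radius table;
    unknown elements get the 1.70 Å default with a logged warning.
    AltLoc/occupancy fields are ignored (with a warning when present).
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        atoms = pdb.get_structure(model=1, extra_fields=["occupancy"])
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no ATOM/HETATM records parsed")
    if np.any(atoms.occupancy != 1.0):
        logger.warning("%s: occupancy/altLoc fields present and ignored", path)
    elements = [e if e else "X" for e in atoms.element]
    known = VDW_RADII if radius_table is None else radius_table
    radii = []
    for e in elements:
        if e.upper() not in known:
            logger.warning("unknown element %r: using default vdW radius 1.70 Å", e)
        radii.append(vdw_radius(e, radius_table))
    return AtomSet(
        species=list(elements),
        positions=atoms.coord.astype(float),
        radii=np.array(radii),
        label=str(path),
    )


def read_radius_table(path) -> dict:
    """Two-column ``element radius`` file overriding the built-in table."""
    table = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'element radius'")
            table[parts[0].upper()] = float(parts[1])
    return table


# ---------------------------------------------------------------------------
# Umbrella windows / WHAM metadata / PMF


def write_window_samples(ws: WindowSamples, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# center = {ws.center:.6f}\n")
        fh.write(f"# force_constant = {ws.force_constant:.6f}\n")
        fh.write(f"# seed = {ws.seed}\n")
        fh.write(f"# window_index = {ws.window_index}\n")
        fh.write("time_ns\tz\n")
        for t, z in zip(ws.times_ns, ws.z):
            fh.write(f"{t:.6f}\t{z:.6f}\n")


def read_window_samples(path) -> Tuple[np.ndarray, np.ndarray]:
    times, zs = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("time_ns") or not line.strip():
                continue
            t, z = line.split("\t")
            times.append(float(t))
            zs.append(float(z))
    return np.array(times), np.array(zs)


def write_wham_metadata(
    paths: Sequence[str], centers: Sequence[float], force_constants: Sequence[float], meta_path
) -> None:
    with open(meta_path, "w") as fh:
        for p, c, k in zip(paths, centers, force_constants):
            fh.write(f"{p}\t{c:.6f}\t{k:.6f}\n")


def read_wham_metadata(meta_path, burn_in: float = 0.3) -> List[UmbrellaWindow]:
    """Load windows from a metadata file (samples_path center k per line)."""
    base = Path(meta_path).parent
    windows = []
    with open(meta_path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{meta_path}:{ln}: expected 'samples_path center force_constant'"
                )
            spath = Path(parts[0])
            if not spath.is_absolute():
                spath = base / spath
            _, z = read_window_samples(spath)
            n0 = int(round(len(z) * burn_in))
            windows.append(
                UmbrellaWindow(
                    center=float(parts[1]),
                    force_constant=float(parts[2]),
                    samples=z[n0:],
                    n_raw=len(z),
                )
            )
    if not windows:
        raise ValueError(f"{meta_path}: no windows parsed")
    return windows


def write_pmf(pmf: PMFProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bin_width = {pmf.bin_width:.6f}\n")
        fh.write(f"# temperature = {pmf.temperature:.2f}\n")
        fh.write("z\tfree_energy_kcal_mol\tn_samples\n")
        for z, fe, n in zip(pmf.z_centers, pmf.free_energy, pmf.counts):
            fe_s = "nan" if not np.isfinite(fe) else f"{fe:.6f}"
            fh.write(f"{z:.6f}\t{fe_s}\t{int(n)}\n")


# ---------------------------------------------------------------------------
# Density grids


def write_density_dx(grid: DensityGrid, path) -> None:
    """OpenDX-style scalar grid text (plot-ready for common viewers)."""
    nx, ny, nz = grid.density.shape
    d = grid.voxel_edge
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        ox, oy, oz = grid.origin + d / 2.0
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {d:.6f} 0 0\ndelta 0 {d:.6f} 0\ndelta 0 0 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.density.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def write_density_tsv(grid: DensityGrid, path, threshold: float = 0.0) -> None:
    """Voxel list TSV (x, y, z, density), optionally thresholded."""
    cx, cy, cz = grid.voxel_centers()
    with open(path, "w") as fh:
        fh.write(f"# voxel_edge = {grid.voxel_edge}\n# n_frames = {grid.n_frames}\n")
        fh.write("x\ty\tz\tdensity\n")
        ix, iy, iz = np.nonzero(grid.density >= threshold)
        for a, b, g in zip(ix, iy, iz):
            fh.write(
                f"{cx[a]:.3f}\t{cy[b]:.3f}\t{cz[g]:.3f}\t{grid.density[a, b, g]:.8f}\n"
            )


def write_events_tsv(events, path) -> None:
    with open(path, "w") as fh:
        fh.write("ion_id\tt_enter_ns\tt_exit_ns\tdirection\n")
        for e in events:
            fh.write(f"{e.ion_id}\t{e.t_enter_ns:.6f}\t{e.t_exit_ns:.6f}\t{e.direction}\n")


def write_profile_tsv(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("z\tradius_mean\tradius_sd\tn\n")
        for z, m, s in zip(profile.z_grid, profile.radius_mean, profile.radius_sd):
            fh.write(f"{z:.3f}\t{m:.4f}\t{s:.4f}\t{profile.n_frames}\n")
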