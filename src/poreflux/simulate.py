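"""Overdamped Langevin dynamics of ions in a channel landscape.

This is the package's synthetic-data generator.  It integrates the
overdamped (inertia-free) Euler-Maruyama update

    dr = mu * F * dt + sqrt(2 * D * dt) * xi,      mu = D / (kT)

for point ions moving in the 1D axial channel potential, a radial
harmonic confinement representing the pore walls, an optional uniform
membrane field, and screened-Coulomb ion-ion repulsion.  Reflecting
walls bound the box; an ion that leaves through the intracellular exit
plane is re-injected at the extracellular reservoir so a steady inward
flux can be sustained, with every exit logged before re-injection.

The simulator additionally keeps a step-resolution three-compartment
ledger (above the pore / inside / below) so that completed passages are
book-kept exactly, independent of the frame-saving stride.

Determinism: a single master seed spawns one PCG64 noise stream per ion
(and per window, for umbrella batches); identical seeds give bitwise
identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .core import AtomSet, Particle, Trajectory
from .potential import ChannelPotential
from .units import thermal_energy

_EVENT_CAP = 400_000
_REFERENCE_TEMPERATURE = 310.0  # K; sets the mobility in the T = 0 quench limit


@dataclass
class SimConfig:
    """Configuration of one Langevin run.

    Defaults emulate the study conditions at desk scale: 310 K, a
    60 Å-tall box whose 0-40 Å core is the pore (reaction coordinate),
    with ~5 Å reservoirs at both ends, and a sodium count matching a
    ~150 mM reservoir concentration for the default box volume.
    """

    n_ions: int = 8
    temperature: float = 310.0
    diffusion_coefficient: float = 0.1  # Å^2/ps
    timestep_ps: float = 0.01
    n_steps: int = 2_000_000
    save_stride: int = 100
    box: Tuple[float, float, float] = (30.0, 30.0, 60.0)
    z_origin: float = -10.0
    pore_region: Tuple[float, float] = (0.0, 40.0)
    pore_radius: float = 3.0
    radial_stiffness: float = 2.0  # kcal/mol/Å^2
    seed: int = 0
    reinjection: bool = True
    exit_margin: float = 1.0  # exit plane sits this far above the bottom wall
    detect_z_top: float = 40.0
    detect_z_bottom: float = -5.0
    species: str = "NA"
    ion_charge: float = 1.0
    initial_placement: str = "uniform"  # "uniform" | "top"

    def __post_init__(self):
        if self.timestep_ps <= 0:
            raise ValueError("timestep must be > 0")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        if self.n_ions < 1:
            raise ValueError("n_ions must be >= 1")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be > 0")

    @property
    def z_top_wall(self) -> float:
        return self.z_origin + self.box[2]


@dataclass
class UmbrellaSpec:
    """One umbrella window: harmonic bias on the tagged ion plus
    optional stiffly restrained extra ions upstream (e.g. at sites A/B)."""

    center: float
    force_constant: float = 5.0  # kcal/mol/Å^2
    extra_ion_positions: Tuple[float, ...] = ()
    restraint_constant_extra: float = 2.5  # kcal/mol/Å^2

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force constant must be > 0")
        if self.extra_ion_positions and self.restraint_constant_extra <= 0:
            raise ValueError("extra-ion restraint constant must be > 0")


@dataclass
class WindowSamples:
    """Tagged-ion axial series of one umbrella window."""

    times_ns: np.ndarray
    z: np.ndarray
    center: float
    force_constant: float
    seed: int
    window_index: int = 0


@njit(cache=False)
def _run_chunk(
    pos,
    charges,
    kz,
    cz,
    gc,
    ga,
    gw,
    fld,
    flo,
    fhi,
    rep_pref,
    rep_lam,
    pair_i,
    pair_j,
    pore_lo,
    pore_hi,
    pore_r,
    pore_k,
    xlo,
    xhi,
    ylo,
    yhi,
    zlo,
    zhi,
    reinject,
    z_exit,
    inj_z,
    inj_xy,
    mob_dt,
    noise,
    det_top,
    det_bot,
    state,
    came_from,
    enter_step,
    save_stride,
    step_offset,
    frames,
    ev_ion,
    ev_enter,
    ev_exit,
    ev_dir,
    counters,
    ex_ion,
    ex_step,
    max_disp,
    forces,
):
    nsteps = noise.shape[0]
    n = pos.shape[0]
    ng = gc.shape[0]
    npair = pair_i.shape[0]
    max_disp2 = max_disp * max_disp
    for s in range(nsteps):
        gstep = step_offset + s
        # single-ion forces
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            fz = 0.0
            for k in range(ng):
                d = z - gc[k]
                w2 = gw[k] * gw[k]
                fz += ga[k] * d / w2 * math.exp(-0.5 * d * d / w2)
            if fld != 0.0 and flo <= z <= fhi:
                fz += charges[i] * fld
            if kz[i] > 0.0:
                fz -= kz[i] * (z - cz[i])
            fx = 0.0
            fy = 0.0
            if pore_lo <= z <= pore_hi:
                rho = math.sqrt(x * x + y * y)
                if rho > pore_r and rho > 0.0:
                    c = pore_k * (rho - pore_r) / rho
                    fx -= c * x
                    fy -= c * y
            forces[i, 0] = fx
            forces[i, 1] = fy
            forces[i, 2] = fz
        # pair repulsion (screened Coulomb)
        if rep_pref != 0.0:
            for p in range(npair):
                i = pair_i[p]
                j = pair_j[p]
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                r2 = dx * dx + dy * dy + dz * dz
                r = math.sqrt(r2)
                if r < 1e-9:
                    return 2
                a = rep_pref * charges[i] * charges[j]
                # -dU/dr for U = a/r * exp(-r/lam)
                fmag = a * math.exp(-r / rep_lam) * (1.0 / r2 + 1.0 / (r * rep_lam))
                fx = fmag * dx / r
                fy = fmag * dy / r
                fz = fmag * dz / r
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[i, 2] += fz
                forces[j, 0] -= fx
                forces[j, 1] -= fy
                forces[j, 2] -= fz
        # update, walls, re-injection, passage bookkeeping
        for i in range(n):
            dx = mob_dt * forces[i, 0] + noise[s, i, 0]
            dy = mob_dt * forces[i, 1] + noise[s, i, 1]
            dz = mob_dt * forces[i, 2] + noise[s, i, 2]
            if dx * dx + dy * dy + dz * dz > max_disp2:
                return 1
            x = pos[i, 0] + dx
            y = pos[i, 1] + dy
            z = pos[i, 2] + dz
            if x < xlo:
                x = 2.0 * xlo - x
            elif x > xhi:
                x = 2.0 * xhi - x
            if y < ylo:
                y = 2.0 * ylo - y
            elif y > yhi:
                y = 2.0 * yhi - y
            if z < zlo:
                z = 2.0 * zlo - z
            elif z > zhi:
                z = 2.0 * zhi - z
            if reinject and z < z_exit:
                ne = counters[1]
                if ne < ex_ion.shape[0]:
                    ex_ion[ne] = i
                    ex_step[ne] = gstep + 1
                counters[1] = ne + 1
                x = inj_xy[i, 0]
                y = inj_xy[i, 1]
                z = inj_z
                state[i] = 0
                came_from[i] = -1
            else:
                if z > det_top:
                    nc = 0
                elif z < det_bot:
                    nc = 2
                else:
                    nc = 1
                oc = state[i]
                if nc != oc:
                    if nc == 1:
                        came_from[i] = oc
                        enter_step[i] = gstep + 1
                    elif nc == 2 and oc == 1 and came_from[i] == 0:
                        nev = counters[0]
                        if nev < ev_ion.shape[0]:
                            ev_ion[nev] = i
                            ev_enter[nev] = enter_step[i]
                            ev_exit[nev] = gstep + 1
                            ev_dir[nev] = -1
                        counters[0] = nev + 1
                        came_from[i] = -1
                    elif nc == 0 and oc == 1 and came_from[i] == 2:
                        nev = counters[0]
                        if nev < ev_ion.shape[0]:
                            ev_ion[nev] = i
                            ev_enter[nev] = enter_step[i]
                            ev_exit[nev] = gstep + 1
                            ev_dir[nev] = 1
                        counters[0] = nev + 1
                        came_from[i] = -1
                    state[i] = nc
            pos[i, 0] = x
            pos[i, 1] = y
            pos[i, 2] = z
        if (gstep + 1) % save_stride == 0:
            f = (gstep + 1) // save_stride
            for i in range(n):
                frames[f, i, 0] = pos[i, 0]
                frames[f, i, 1] = pos[i, 1]
                frames[f, i, 2] = pos[i, 2]
    return 0


def _pack_potential(pot: ChannelPotential):
    feats = pot.features()
    gc = np.array([g.center for g in feats], dtype=float)
    ga = np.array([g.amplitude for g in feats], dtype=float)
    gw = np.array([g.width for g in feats], dtype=float)
    if gc.size == 0:
        gc = np.zeros(1)
        ga = np.zeros(1)
        gw = np.ones(1)
    if pot.field_interval is not None:
        flo, fhi = pot.field_interval
    else:
        flo, fhi = -1e30, 1e30
    if pot.repulsion is None:
        rep_pref, rep_lam = 0.0, 1.0
    else:
        rep_pref = pot.repulsion.prefactor / pot.repulsion.eps_r
        rep_lam = pot.repulsion.screening_length
    return gc, ga, gw, float(pot.field), flo, fhi, rep_pref, rep_lam


def _mobility_dt(cfg: SimConfig) -> float:
    kt = thermal_energy(cfg.temperature if cfg.temperature > 0 else _REFERENCE_TEMPERATURE)
    return cfg.diffusion_coefficient / kt * cfg.timestep_ps


def _noise_scale(cfg: SimConfig) -> float:
    if cfg.temperature == 0:
        return 0.0
    return math.sqrt(2.0 * cfg.diffusion_coefficient * cfg.timestep_ps)


def _compartment(z: float, top: float, bot: float) -> int:
    if z > top:
        return 0
    if z < bot:
        return 2
    return 1


class _Engine:
    """Shared driver: packs arrays, loops noise chunks through the kernel."""

    def __init__(
        self,
        cfg: SimConfig,
        pot: ChannelPotential,
        positions0: np.ndarray,
        charges: np.ndarray,
        kz: np.ndarray,
        cz: np.ndarray,
        pairs: Tuple[np.ndarray, np.ndarray],
        ion_seeds: Sequence[np.random.SeedSequence],
        reinject: bool,
        pore_region: Tuple[float, float],
    ):
        self.cfg = cfg
        self.pos = np.array(positions0, dtype=float)
        self.n = self.pos.shape[0]
        self.charges = charges
        self.kz = kz
        self.cz = cz
        self.pair_i, self.pair_j = pairs
        (self.gc, self.ga, self.gw, self.fld, self.flo, self.fhi,
         self.rep_pref, self.rep_lam) = _pack_potential(pot)
        self.rngs = [np.random.Generator(np.random.PCG64(s)) for s in ion_seeds]
        self.reinject = reinject
        self.pore_lo, self.pore_hi = pore_region
        lx, ly, lz = cfg.box
        self.xlo, self.xhi = -lx / 2.0, lx / 2.0
        self.ylo, self.yhi = -ly / 2.0, ly / 2.0
        self.zlo, self.zhi = cfg.z_origin, cfg.z_origin + lz
        self.z_exit = cfg.z_origin + cfg.exit_margin
        self.inj_z = self.zhi - 2.0
        # deterministic, per-ion staggered lateral injection points so two
        # re-injected ions can never coincide (pair term is singular at r=0)
        idx = np.arange(self.n)
        self.inj_xy = np.stack(
            [
                np.minimum(0.4 * (idx % 5) - 0.8, cfg.pore_radius),
                np.minimum(0.4 * ((idx // 5) % 5) - 0.8, cfg.pore_radius),
            ],
            axis=1,
        ).astype(float)
        self.state = np.array(
            [_compartment(z, cfg.detect_z_top, cfg.detect_z_bottom) for z in self.pos[:, 2]],
            dtype=np.int64,
        )
        self.came_from = np.full(self.n, -1, dtype=np.int64)
        self.enter_step = np.zeros(self.n, dtype=np.int64)
        self.ev_ion = np.zeros(_EVENT_CAP, dtype=np.int64)
        self.ev_enter = np.zeros(_EVENT_CAP, dtype=np.int64)
        self.ev_exit = np.zeros(_EVENT_CAP, dtype=np.int64)
        self.ev_dir = np.zeros(_EVENT_CAP, dtype=np.int64)
        self.ex_ion = np.zeros(_EVENT_CAP, dtype=np.int64)
        self.ex_step = np.zeros(_EVENT_CAP, dtype=np.int64)
        self.counters = np.zeros(2, dtype=np.int64)
        self.forces = np.zeros((self.n, 3), dtype=float)

    def run(self) -> np.ndarray:
        cfg = self.cfg
        n_saves = cfg.n_steps // cfg.save_stride
        frames = np.zeros((n_saves + 1, self.n, 3), dtype=float)
        frames[0] = self.pos
        scale = _noise_scale(cfg)
        mob_dt = _mobility_dt(cfg)
        chunk = max(1, min(cfg.n_steps, 200_000, int(4e6 / max(self.n, 1))))
        step = 0
        noise = np.zeros((0, self.n, 3))
        while step < cfg.n_steps:
            k = min(chunk, cfg.n_steps - step)
            if noise.shape[0] != k:
                noise = np.empty((k, self.n, 3), dtype=float)
            if scale == 0.0:
                noise[:] = 0.0
            else:
                for i, rng in enumerate(self.rngs):
                    noise[:, i, :] = rng.standard_normal((k, 3)) * scale
            status = _run_chunk(
                self.pos, self.charges, self.kz, self.cz,
                self.gc, self.ga, self.gw, self.fld, self.flo, self.fhi,
                self.rep_pref, self.rep_lam, self.pair_i, self.pair_j,
                self.pore_lo, self.pore_hi, cfg.pore_radius, cfg.radial_stiffness,
                self.xlo, self.xhi, self.ylo, self.yhi, self.zlo, self.zhi,
                self.reinject, self.z_exit, self.inj_z, self.inj_xy,
                mob_dt, noise,
                cfg.detect_z_top, cfg.detect_z_bottom,
                self.state, self.came_from, self.enter_step,
                cfg.save_stride, step, frames,
                self.ev_ion, self.ev_enter, self.ev_exit, self.ev_dir,
                self.counters, self.ex_ion, self.ex_step,
                2.0, self.forces,
            )
            if status == 1:
                raise RuntimeError(
                    "integration step exceeded 2 Å; reduce timestep_ps (the "
                    "configured forces are too steep for the current step size)"
                )
            if status == 2:
                raise RuntimeError("two ions coincided (r = 0); pair term singular")
            step += k
        if self.counters[0] > _EVENT_CAP or self.counters[1] > _EVENT_CAP:
            raise RuntimeError("passage/exit ledger overflow")  # pragma: no cover
        return frames

    def passages(self, dt_ns: float) -> List[dict]:
        n = int(self.counters[0])
        return [
            {
                "ion": int(self.ev_ion[k]),
                "t_enter_ns": float(self.ev_enter[k] * dt_ns),
                "t_exit_ns": float(self.ev_exit[k] * dt_ns),
                "direction": "inward" if self.ev_dir[k] < 0 else "outward",
            }
            for k in range(n)
        ]

    def exits(self, dt_ns: float) -> List[dict]:
        n = int(self.counters[1])
        return [
            {"ion": int(self.ex_ion[k]), "t_ns": float(self.ex_step[k] * dt_ns)}
            for k in range(n)
        ]


def _initial_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    pos = np.empty((cfg.n_ions, 3))
    r = rng.uniform(0, cfg.pore_radius, cfg.n_ions)
    th = rng.uniform(0, 2 * np.pi, cfg.n_ions)
    pos[:, 0] = r * np.cos(th)
    pos[:, 1] = r * np.sin(th)
    if cfg.initial_placement == "top":
        pos[:, 2] = rng.uniform(cfg.detect_z_top + 0.5, cfg.z_top_wall - 0.5, cfg.n_ions)
    else:
        pos[:, 2] = rng.uniform(cfg.z_origin + 2.0, cfg.z_top_wall - 0.5, cfg.n_ions)
    return pos


def simulate_langevin(cfg: SimConfig, pot: ChannelPotential) -> Trajectory:
    """Free (unbiased) Langevin run of ``cfg.n_ions`` interacting ions.

    Returns a Trajectory whose ``metadata`` carries the seed, the config,
    the step-resolution passage ledger (``passages``) and the raw-exit
    log (``exits``) recorded before each re-injection.
    """
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_ions + 1)
    init_rng = np.random.Generator(np.random.PCG64(children[0]))
    pos0 = _initial_positions(cfg, init_rng)
    charges = np.full(cfg.n_ions, cfg.ion_charge, dtype=float)
    kz = np.zeros(cfg.n_ions)
    cz = np.zeros(cfg.n_ions)
    ii, jj = np.triu_indices(cfg.n_ions, k=1)
    engine = _Engine(
        cfg, pot, pos0, charges, kz, cz,
        (ii.astype(np.int64), jj.astype(np.int64)),
        children[1:], cfg.reinjection, cfg.pore_region,
    )
    frames = engine.run()
    dt_ns = cfg.timestep_ps / 1000.0
    times = np.arange(frames.shape[0]) * cfg.save_stride * dt_ns
    particles = [Particle(i, cfg.species, cfg.ion_charge) for i in range(cfg.n_ions)]
    return Trajectory(
        particles=particles,
        times=times,
        positions=frames,
        box=np.tile(np.asarray(cfg.box, dtype=float), (frames.shape[0], 1)),
        metadata={
            "seed": cfg.seed,
            "config": cfg,
            "passages": engine.passages(dt_ns),
            "exits": engine.exits(dt_ns),
            "z_origin": cfg.z_origin,
        },
    )


def sample_umbrella_windows(
    cfg: SimConfig,
    pot: ChannelPotential,
    specs: Sequence[UmbrellaSpec],
    first_window_index: int = 0,
) -> List[WindowSamples]:
    """Run many umbrella windows in one batched integration.

    Windows are mutually independent (no cross-window interactions), so
    they are stacked into a single kernel call for speed.  Window ``w``
    draws its noise from streams seeded by ``(cfg.seed, w)``; running a
    single window alone with the same index is bitwise identical.
    """
    if not specs:
        return []
    tagged_idx: List[int] = []
    pos0: List[Tuple[float, float, float]] = []
    kz: List[float] = []
    cz: List[float] = []
    pair_i: List[int] = []
    pair_j: List[int] = []
    seeds: List[np.random.SeedSequence] = []
    for w, spec in enumerate(specs):
        base = len(pos0)
        members = 1 + len(spec.extra_ion_positions)
        wseed = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(first_window_index + w,))
        seeds.extend(wseed.spawn(members))
        tagged_idx.append(base)
        pos0.append((0.0, 0.0, spec.center))
        kz.append(spec.force_constant)
        cz.append(spec.center)
        for e, zext in enumerate(spec.extra_ion_positions):
            pos0.append((0.0, 0.0, float(zext)))
            kz.append(spec.restraint_constant_extra)
            cz.append(float(zext))
        for a in range(members):
            for b in range(a + 1, members):
                pair_i.append(base + a)
                pair_j.append(base + b)
    n = len(pos0)
    engine = _Engine(
        cfg,
        pot,
        np.asarray(pos0, dtype=float),
        np.full(n, cfg.ion_charge, dtype=float),
        np.asarray(kz, dtype=float),
        np.asarray(cz, dtype=float),
        (np.asarray(pair_i, dtype=np.int64), np.asarray(pair_j, dtype=np.int64)),
        seeds,
        False,
        cfg.pore_region,
    )
    frames = engine.run()
    dt_ns = cfg.timestep_ps / 1000.0
    times = np.arange(frames.shape[0]) * cfg.save_stride * dt_ns
    out = []
    for w, spec in enumerate(specs):
        out.append(
            WindowSamples(
                times_ns=times.copy(),
                z=frames[:, tagged_idx[w], 2].copy(),
                center=spec.center,
                force_constant=spec.force_constant,
                seed=cfg.seed,
                window_index=first_window_index + w,
            )
        )
    return out


def simulate_umbrella_window(
    cfg: SimConfig, pot: ChannelPotential, spec: UmbrellaSpec
) -> WindowSamples:
    """Single umbrella window (see :func:`sample_umbrella_windows`)."""
    return sample_umbrella_windows(cfg, pot, [spec])[0]


def umbrella_config(
    n_samples: int = 10_000,
    save_stride: int = 100,
    burn_in_fraction: float = 0.3,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """A SimConfig sized so each window yields ``n_samples`` post-burn-in
    samples at a 1 ps sampling interval (stride 100 x 0.01 ps).

    Umbrella configs confine ions radially over the whole box so the
    accessible lateral area is independent of z and the recovered PMF is
    exactly the configured axial landscape.
    """
    n_saved = int(math.ceil(n_samples / (1.0 - burn_in_fraction)))
    kwargs = dict(
        n_ions=1,
        n_steps=n_saved * save_stride,
        save_stride=save_stride,
        reinjection=False,
        seed=seed,
    )
    kwargs.update({k: v for k, v in overrides.items() if k != "pore_region"})
    base = SimConfig(**kwargs)
    pore = overrides.get("pore_region", (base.z_origin, base.z_top_wall))
    return replace(base, pore_region=pore)


# ---------------------------------------------------------------------------
# Geometric fixtures


def make_pore_fixture(
    shape: str = "cylinder",
    ring_radius: float = 5.0,
    waist_radius: float = 3.0,
    mouth_radius: float = 6.0,
    vdw: float = 1.7,
    z_range: Tuple[float, float] = (0.0, 40.0),
    ring_spacing: float = 0.5,
    atoms_per_ring: int = 16,
    radius_function=None,
    species: str = "O",
) -> AtomSet:
    """Rings of atoms around the z-axis with a known inscribed radius.

    The analytic pore radius at a ring plane is ring_radius(z) - vdw,
    which makes these atom sets exact ground truth for the pore profiler.
    Shapes: ``cylinder`` (constant radius), ``hourglass`` (cosine-squared
    constriction from mouth_radius to waist_radius at mid-height) and
    ``from-radius-function`` (user callable z -> ring radius).
    """
    z0, z1 = z_range
    if z1 <= z0:
        raise ValueError("z_range must be increasing")
    if vdw <= 0:
        raise ValueError("vdW radius must be > 0")
    zs = np.arange(z0, z1 + ring_spacing / 2, ring_spacing)

    if shape == "cylinder":
        rad = np.full_like(zs, float(ring_radius))
    elif shape == "hourglass":
        mid = 0.5 * (z0 + z1)
        t = (zs - mid) / (z1 - z0)  # -0.5 .. 0.5
        rad = waist_radius + (mouth_radius - waist_radius) * np.sin(np.pi * t) ** 2
    elif shape == "from-radius-function":
        if radius_function is None:
            raise ValueError("radius_function required for shape 'from-radius-function'")
        rad = np.array([float(radius_function(z)) for z in zs])
    else:
        raise ValueError(f"unknown pore fixture shape {shape!r}")
    if np.any(rad <= vdw):
        raise ValueError("ring radius must exceed the atom vdW radius everywhere")

    th = np.linspace(0, 2 * np.pi, atoms_per_ring, endpoint=False)
    pos = []
    for z, r in zip(zs, rad):
        ring = np.stack([r * np.cos(th), r * np.sin(th), np.full_like(th, z)], axis=1)
        pos.append(ring)
    pos = np.concatenate(pos, axis=0)
    n = len(pos)
    return AtomSet(
        species=[species] * n,
        positions=pos,
        radii=np.full(n, vdw),
        label=f"{shape} fixture",
    )


_OCTAHEDRON = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=float,
)


def make_hydration_fixture(
    n_oxygens: int, distance: float, center=(0.0, 0.0, 0.0)
) -> AtomSet:
    """n oxygen atoms at exactly ``distance`` from ``center``.

    Up to six atoms use octahedral directions; larger shells use a
    Fibonacci sphere so atoms stay maximally spread.  Ground truth for
    coordination-number counting (e.g. the 3 Å oxygen-shell count).
    """
    if n_oxygens < 0:
        raise ValueError("n_oxygens must be >= 0")
    if distance <= 0:
        raise ValueError("distance must be > 0")
    if n_oxygens == 0:
        return AtomSet(species=[], positions=np.zeros((0, 3)), radii=np.zeros(0), label="hydration")
    if n_oxygens <= 6:
        dirs = _OCTAHEDRON[:n_oxygens]
    else:
        k = np.arange(n_oxygens)
        phi = np.pi * (3.0 - np.sqrt(5.0)) * k
        zc = 1.0 - 2.0 * (k + 0.5) / n_oxygens
        rc = np.sqrt(1.0 - zc**2)
        dirs = np.stack([rc * np.cos(phi), rc * np.sin(phi), zc], axis=1)
    pos = np.asarray(center, dtype=float) + distance * dirs
    return AtomSet(
        species=["O"] * n_oxygens,
        positions=pos,
        radii=np.full(n_oxygens, 1.52),
        label="hydration",
    )
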