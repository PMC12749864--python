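"""Umbrella-window construction and WHAM free-energy estimation.

The weighted histogram analysis method combines the biased histograms
n_i(z) of umbrella windows with harmonic biases w_i(z) = k_i/2 (z-c_i)²
through the standard coupled equations

    P(z)        =  sum_i n_i(z) / sum_j N_j exp(beta f_j - beta w_j(z))
    exp(-b f_j) =  sum_z P(z) exp(-beta w_j(z))

iterated to self-consistency on the window shifts f_j; the PMF is
F(z) = -kT ln P(z), anchored so its minimum over sampled bins is zero.
Empty bins inside the covered range are flagged, never interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks
from scipy.special import logsumexp

from .simulate import WindowSamples
from .units import thermal_energy

DEFAULT_BIN_WIDTH = 0.1  # Å
DEFAULT_TOLERANCE = 1e-6  # kcal/mol on window shifts
DEFAULT_MAX_ITER = 100_000
DEFAULT_BURN_IN = 0.3


def build_windows(span: float, spacing: float = 0.5) -> np.ndarray:
    """Umbrella-window centres covering [0, span] inclusive.

    A 40 Å reaction coordinate at 0.5 Å spacing gives 81 windows; a
    15 Å one gives 31.  ``span`` must be an integer multiple of
    ``spacing``.
    """
    if span < 0:
        raise ValueError("span must be >= 0")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    n = span / spacing
    if abs(n - round(n)) > 1e-9:
        lo = math.floor(n) * spacing
        hi = math.ceil(n) * spacing
        raise ValueError(
            f"span {span} is not an integer multiple of spacing {spacing}; "
            f"use a span of {lo:g} or {hi:g}"
        )
    return np.round(np.arange(int(round(n)) + 1) * spacing, 12)


@dataclass
class UmbrellaWindow:
    """One window's post-burn-in samples plus its bias parameters."""

    center: float
    force_constant: float
    samples: np.ndarray
    n_raw: int = 0

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force constant must be > 0")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.n_raw == 0:
            self.n_raw = self.samples.size
        if self.samples.size > self.n_raw:
            raise ValueError("n_used cannot exceed n_raw")

    @property
    def n_used(self) -> int:
        return self.samples.size

    @classmethod
    def from_samples(
        cls, ws: WindowSamples, burn_in: float = DEFAULT_BURN_IN
    ) -> "UmbrellaWindow":
        """Build a window from a simulated series, discarding the first
        ``burn_in`` fraction (default 30 %, the analogue of keeping the
        last 7 ns of a 10 ns window)."""
        if not 0 <= burn_in < 1:
            raise ValueError("burn_in must be in [0, 1)")
        n0 = int(round(ws.z.size * burn_in))
        return cls(
            center=ws.center,
            force_constant=ws.force_constant,
            samples=ws.z[n0:],
            n_raw=ws.z.size,
        )


@dataclass
class PMFProfile:
    """Free energy vs axial coordinate on a regular bin grid."""

    z_centers: np.ndarray
    bin_width: float
    free_energy: np.ndarray  # kcal/mol; NaN on empty bins
    counts: np.ndarray
    temperature: float = 310.0

    @property
    def covered(self) -> np.ndarray:
        return self.counts > 0

    @property
    def gaps(self) -> np.ndarray:
        """Empty bins strictly inside the covered range (flagged, never
        interpolated)."""
        cov = self.covered
        if not cov.any():
            return np.zeros_like(cov)
        first, last = np.nonzero(cov)[0][[0, -1]]
        inside = np.zeros_like(cov)
        inside[first : last + 1] = True
        return inside & ~cov

    def value_at(self, z: float) -> float:
        i = int(np.argmin(np.abs(self.z_centers - z)))
        return float(self.free_energy[i])


@dataclass
class WHAMResult:
    pmf: PMFProfile
    shifts: np.ndarray
    iterations: int
    final_change: float
    overlap_matrix: np.ndarray
    converged: bool
    disconnected: bool = False
    window_centers: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _histograms(
    windows: Sequence[UmbrellaWindow],
    bin_width: float,
    z_range: Optional[Tuple[float, float]],
) -> Tuple[np.ndarray, np.ndarray]:
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    if z_range is not None:
        lo, hi = z_range
    nb = max(1, int(math.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(nb + 1)
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def window_overlap(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> Tuple[np.ndarray, float]:
    """Pairwise histogram overlap sum_z min(p_i, p_j) in [0, 1].

    Returns the full matrix and the minimum overlap between windows that
    are adjacent in centre order (the quantity checked when declaring
    "sufficient overlap" between neighbouring umbrella windows).
    """
    counts, _ = _histograms(windows, bin_width, None)
    p = counts / counts.sum(axis=1, keepdims=True)
    m = len(windows)
    overlap = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            overlap[i, j] = np.minimum(p[i], p[j]).sum()
    order = np.argsort([w.center for w in windows])
    adjacent = [overlap[order[k], order[k + 1]] for k in range(m - 1)] or [1.0]
    return overlap, float(min(adjacent))


def wham_pmf(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = DEFAULT_BIN_WIDTH,
    temperature: float = 310.0,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
    z_range: Optional[Tuple[float, float]] = None,
) -> WHAMResult:
    """Self-consistent WHAM solution over a set of umbrella windows."""
    windows = [w for w in windows if w.n_used > 0]
    if not windows:
        raise ValueError("at least one window with samples is required")
    kt = thermal_energy(temperature)
    beta = 1.0 / kt
    counts, centers = _histograms(windows, bin_width, z_range)
    n_w = counts.sum(axis=1)  # N_j
    c = np.array([w.center for w in windows])
    k = np.array([w.force_constant for w in windows])
    bias = 0.5 * k[:, None] * (centers[None, :] - c[:, None]) ** 2  # w_j(z)

    tot = counts.sum(axis=0)
    sampled = tot > 0
    log_num = np.full(centers.shape, -np.inf)
    log_num[sampled] = np.log(tot[sampled])
    log_nw = np.log(n_w)

    f = np.zeros(len(windows))
    iterations = 0
    delta = np.inf
    for iterations in range(1, max_iter + 1):
        # log P(z) up to a constant
        log_den = logsumexp(
            log_nw[:, None] + beta * f[:, None] - beta * bias, axis=0
        )
        log_p = log_num - log_den
        # new shifts: exp(-beta f_j) = sum_z P(z) exp(-beta w_j(z))
        with np.errstate(invalid="ignore"):
            f_new = -kt * logsumexp(log_p[None, :] - beta * bias, axis=1)
        f_new = f_new - f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tolerance:
            break
    converged = delta < tolerance

    log_den = logsumexp(log_nw[:, None] + beta * f[:, None] - beta * bias, axis=0)
    log_p = log_num - log_den
    free = np.full(centers.shape, np.nan)
    free[sampled] = -kt * log_p[sampled]
    free -= np.nanmin(free)

    overlap, min_adjacent = window_overlap(windows, bin_width)
    order = np.argsort(c)
    disconnected = any(
        overlap[order[i], order[i + 1]] == 0.0 for i in range(len(windows) - 1)
    )

    pmf = PMFProfile(
        z_centers=centers,
        bin_width=bin_width,
        free_energy=free,
        counts=tot,
        temperature=temperature,
    )
    return WHAMResult(
        pmf=pmf,
        shifts=f,
        iterations=iterations,
        final_change=delta,
        overlap_matrix=overlap,
        converged=converged,
        disconnected=disconnected,
        window_centers=c,
    )


@dataclass
class Barrier:
    """Inward escape barrier out of one binding site (None if the site
    has no well in the profile)."""

    value: Optional[float]
    site_minimum_z: Optional[float] = None
    barrier_top_z: Optional[float] = None
    reason: str = ""


def barrier_heights(
    pmf: PMFProfile,
    site_ranges: Dict[str, Tuple[float, float]],
    min_prominence: float = 0.5,
) -> Dict[str, Barrier]:
    """Escape barrier out of each binding site, toward the intracellular
    side (decreasing z).

    For each site: locate the free-energy minimum inside the site range
    (it must be a genuine interior well); the barrier is the maximum of F
    between that minimum and the next minimum inward of it (or the
    profile edge), minus the well value.  Minima are identified with a
    prominence filter (default 0.5 kcal/mol) so statistical ripple does
    not truncate the inward segment.  A monotone or flat profile across a
    site yields value None, never 0.
    """
    cov = pmf.covered & np.isfinite(pmf.free_energy)
    z = pmf.z_centers[cov]
    fe = pmf.free_energy[cov]
    if z.size < 3:
        raise ValueError("PMF covers too few bins for barrier analysis")
    minima_idx, _ = find_peaks(-fe, prominence=min_prominence)
    out: Dict[str, Barrier] = {}
    for label, (lo, hi) in site_ranges.items():
        inside = (z >= lo) & (z <= hi)
        if not inside.any():
            out[label] = Barrier(None, reason="site range not covered by PMF")
            continue
        idx_in = np.nonzero(inside)[0]
        i_min = idx_in[np.argmin(fe[idx_in])]
        interior = idx_in[0] < i_min < idx_in[-1]
        strict = (
            interior
            and fe[i_min] < fe[idx_in[0]]
            and fe[i_min] < fe[idx_in[-1]]
        )
        if not strict:
            out[label] = Barrier(None, reason="no interior well within the site range")
            continue
        inward_minima = minima_idx[minima_idx < i_min]
        i_stop = int(inward_minima.max()) if inward_minima.size else 0
        seg = slice(i_stop, i_min + 1)
        i_top = i_stop + int(np.argmax(fe[seg]))
        height = float(fe[i_top] - fe[i_min])
        if height <= 0:
            out[label] = Barrier(None, reason="profile is monotone inward of the site")
            continue
        out[label] = Barrier(
            value=height,
            site_minimum_z=float(z[i_min]),
            barrier_top_z=float(z[i_top]),
        )
    return out


def windows_from_series(
    series: Sequence[WindowSamples], burn_in: float = DEFAULT_BURN_IN
) -> List[UmbrellaWindow]:
    """Convenience: apply the burn-in convention to simulated windows."""
    return [UmbrellaWindow.from_samples(ws, burn_in) for ws in series]
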