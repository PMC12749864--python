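"""WHAM estimator: window plans, closed-form oracles, barrier extraction."""

import numpy as np
import pytest
from scipy.stats import norm

from poreflux.units import thermal_energy
from poreflux.wham import (
    PMFProfile,
    UmbrellaWindow,
    barrier_heights,
    build_windows,
    wham_pmf,
    window_overlap,
)

KT = thermal_energy(310.0)


class TestWindowPlan:
    def test_forty_angstrom_span_gives_81_windows(self):
        assert len(build_windows(40.0, 0.5)) == 81

    def test_fifteen_angstrom_span_gives_31_windows(self):
        assert len(build_windows(15.0, 0.5)) == 31

    def test_zero_span_single_window(self):
        centers = build_windows(0.0, 0.5)
        assert list(centers) == [0.0]

    def test_indivisible_span_rejected_with_suggestion(self):
        with pytest.raises(ValueError, match="multiple"):
            build_windows(40.3, 0.5)

    def test_total_sampling_time(self):
        # 81 windows at 10 ns each: 810 ns of window sampling
        assert len(build_windows(40.0, 0.5)) * 10.0 == 810.0


def _gaussian_windows(rng, centers, k, n, landscape=None, kt=KT):
    """Windows sampled directly from the exact biased Boltzmann density
    (inverse-CDF on a fine grid) — independent of the Langevin engine."""
    windows = []
    grid = np.arange(min(centers) - 4, max(centers) + 4, 0.01)
    for c in centers:
        u = 0.5 * k * (grid - c) ** 2
        if landscape is not None:
            u = u + landscape(grid)
        p = np.exp(-(u - u.min()) / kt)
        p /= p.sum()
        z = rng.choice(grid, size=n, p=p) + rng.uniform(-0.005, 0.005, n)
        windows.append(UmbrellaWindow(center=c, force_constant=k, samples=z))
    return windows


class TestWhamEstimator:
    def test_single_unbiased_window_collapses_to_log_histogram(self):
        rng = np.random.default_rng(0)
        z = rng.normal(5.0, 1.0, 20_000)
        w = UmbrellaWindow(center=5.0, force_constant=1e-12, samples=z)
        res = wham_pmf([w], bin_width=0.2)
        counts = res.pmf.counts
        m = counts > 0
        expected = -KT * np.log(counts[m])
        expected -= expected.min()
        assert np.allclose(res.pmf.free_energy[m], expected, atol=1e-6)

    def test_flat_landscape_recovered_flat(self):
        rng = np.random.default_rng(1)
        windows = _gaussian_windows(rng, build_windows(10.0, 0.5), k=5.0, n=10_000)
        res = wham_pmf(windows)
        fe = res.pmf.free_energy[res.pmf.covered]
        fe = fe - fe.mean()
        assert np.sqrt((fe**2).mean()) < 0.15

    def test_recovers_known_landscape_from_exact_samples(self):
        """Dual-route check: windows drawn by inverse-CDF from the exact
        biased densities of a double-well landscape; WHAM must give the
        landscape back (RMS < 0.15 kcal/mol)."""
        def landscape(z):
            return -2.0 * np.exp(-0.5 * (z - 3.0) ** 2) + 3.0 * np.exp(
                -0.5 * ((z - 7.0) / 1.5) ** 2
            )

        rng = np.random.default_rng(2)
        windows = _gaussian_windows(
            rng, build_windows(10.0, 0.5), k=5.0, n=10_000, landscape=landscape
        )
        res = wham_pmf(windows)
        assert res.converged
        cov = res.pmf.covered
        diff = res.pmf.free_energy[cov] - landscape(res.pmf.z_centers[cov])
        diff -= diff.mean()
        assert np.sqrt((diff**2).mean()) < 0.15

    def test_constant_landscape_shift_leaves_pmf_unchanged(self):
        def base(z):
            return 3.0 * np.exp(-0.5 * (z - 5.0) ** 2)

        rng1 = np.random.default_rng(3)
        rng2 = np.random.default_rng(3)
        w1 = _gaussian_windows(rng1, build_windows(10.0, 0.5), 5.0, 4000, base)
        w2 = _gaussian_windows(
            rng2, build_windows(10.0, 0.5), 5.0, 4000, lambda z: base(z) + 7.0
        )
        r1 = wham_pmf(w1)
        r2 = wham_pmf(w2)
        assert np.allclose(
            r1.pmf.free_energy[r1.pmf.covered], r2.pmf.free_energy[r2.pmf.covered],
            atol=1e-9, equal_nan=True,
        )

    def test_window_order_irrelevant(self):
        rng = np.random.default_rng(4)
        windows = _gaussian_windows(rng, build_windows(6.0, 0.5), 5.0, 3000)
        r1 = wham_pmf(windows)
        r2 = wham_pmf(windows[::-1])
        assert np.allclose(r1.pmf.free_energy, r2.pmf.free_energy,
                           atol=1e-9, equal_nan=True)

    def test_self_consistency_at_convergence(self):
        rng = np.random.default_rng(5)
        windows = _gaussian_windows(rng, build_windows(6.0, 0.5), 5.0, 3000)
        res = wham_pmf(windows, tolerance=1e-8)
        assert res.converged
        assert res.final_change < 1e-8
        # rerunning the fixed point from the solution moves nothing
        res2 = wham_pmf(windows, tolerance=1e-8)
        assert np.allclose(res.shifts, res2.shifts, atol=1e-7)

    def test_max_iter_exceeded_flags_unconverged(self):
        rng = np.random.default_rng(6)
        windows = _gaussian_windows(rng, build_windows(6.0, 0.5), 5.0, 2000)
        res = wham_pmf(windows, max_iter=3)
        assert not res.converged

    def test_disjoint_windows_flagged_disconnected(self):
        rng = np.random.default_rng(7)
        w1 = UmbrellaWindow(0.0, 5.0, rng.normal(0.0, 0.3, 4000))
        w2 = UmbrellaWindow(20.0, 5.0, rng.normal(20.0, 0.3, 4000))
        res = wham_pmf([w1, w2])
        assert res.disconnected
        assert res.pmf.gaps.any()

    def test_requires_samples(self):
        with pytest.raises(ValueError):
            wham_pmf([])


class TestOverlap:
    def test_identical_sample_sets(self):
        z = np.random.default_rng(8).normal(0, 1, 5000)
        w = UmbrellaWindow(0.0, 5.0, z)
        m, min_adj = window_overlap([w, UmbrellaWindow(0.0, 5.0, z.copy())])
        assert m[0, 1] == pytest.approx(1.0)
        assert min_adj == pytest.approx(1.0)

    def test_disjoint_supports(self):
        rng = np.random.default_rng(9)
        w1 = UmbrellaWindow(0.0, 5.0, rng.uniform(0, 1, 1000))
        w2 = UmbrellaWindow(9.0, 5.0, rng.uniform(9, 10, 1000))
        m, min_adj = window_overlap([w1, w2])
        assert m[0, 1] == 0.0
        assert min_adj == 0.0

    def test_gaussian_pair_closed_form(self):
        # equal-σ Gaussians separated by d overlap by 2 Φ(-d / 2σ)
        rng = np.random.default_rng(10)
        sigma, d = 1.0, 1.0
        w1 = UmbrellaWindow(0.0, 5.0, rng.normal(0.0, sigma, 10_000))
        w2 = UmbrellaWindow(d, 5.0, rng.normal(d, sigma, 10_000))
        m, _ = window_overlap([w1, w2], bin_width=0.05)
        assert m[0, 1] == pytest.approx(2 * norm.cdf(-d / (2 * sigma)), abs=0.02)


def _profile(z, fe):
    fe = np.asarray(fe, dtype=float)
    return PMFProfile(
        z_centers=np.asarray(z, dtype=float),
        bin_width=float(z[1] - z[0]),
        free_energy=fe - fe.min(),
        counts=np.ones_like(fe),
    )


class TestBarriers:
    def test_hand_built_site_c_barrier(self):
        # well of -2.00 at z = 9 with a +5.52 maximum inward of it: 7.52
        z = np.arange(0.0, 14.0, 0.1)
        fe = -2.0 * np.exp(-0.5 * (z - 9.0) ** 2) + 5.52 * np.exp(
            -0.5 * ((z - 4.0) / 1.2) ** 2
        )
        out = barrier_heights(_profile(z, fe), {"C": (7.0, 11.0)})
        assert out["C"].value == pytest.approx(7.52, abs=0.01)
        assert out["C"].site_minimum_z == pytest.approx(9.0, abs=0.1)
        assert out["C"].barrier_top_z == pytest.approx(4.0, abs=0.1)

    def test_flat_profile_has_no_defined_barrier(self):
        z = np.arange(0.0, 14.0, 0.1)
        out = barrier_heights(_profile(z, np.zeros_like(z)), {"C": (7.0, 11.0)})
        assert out["C"].value is None

    def test_monotone_profile_has_no_defined_barrier(self):
        z = np.arange(0.0, 14.0, 0.1)
        out = barrier_heights(_profile(z, 0.3 * z), {"C": (7.0, 11.0)})
        assert out["C"].value is None

    def test_barrier_stops_at_next_inward_minimum(self):
        # two wells with a shallow saddle between them and a much taller
        # peak further in: the escape barrier out of the outer well must
        # use the saddle, not the distant peak
        z = np.arange(0.0, 20.0, 0.1)
        fe = (
            -3.0 * np.exp(-0.5 * (z - 15.0) ** 2)
            - 3.0 * np.exp(-0.5 * (z - 10.0) ** 2)
            + 8.0 * np.exp(-0.5 * (z - 3.0) ** 2)
        )
        out = barrier_heights(_profile(z, fe), {"B": (13.0, 17.0)})
        # independent arithmetic: saddle between the wells minus well value
        seg = (z >= 10.0) & (z <= 15.0)
        well = (z >= 13.0) & (z <= 17.0)
        expected = fe[seg].max() - fe[well].min()
        assert expected < 4.0  # sanity: far smaller than the 8 kcal/mol peak
        assert out["B"].value == pytest.approx(expected, abs=0.01)
        assert 10.0 < out["B"].barrier_top_z < 15.0

    def test_uncovered_site_flagged(self):
        z = np.arange(0.0, 5.0, 0.1)
        out = barrier_heights(_profile(z, np.cos(z)), {"A": (22.0, 26.0)})
        assert out["A"].value is None
        assert "not covered" in out["A"].reason
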