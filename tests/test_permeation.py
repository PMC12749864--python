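"""Permeation detection, unwrapping, occupancy and cooperativity."""

from dataclasses import replace

import numpy as np
import pytest

from poreflux.core import conductance_estimate
from poreflux.permeation import (
    OccupancyTable,
    PermeationEvent,
    SiteDefinition,
    cooperativity_fraction,
    detect_permeations,
    events_per_run,
    site_occupancy,
    unwrap_axis,
)
from poreflux.potential import conduction_channel_potential
from poreflux.simulate import SimConfig, simulate_langevin
from poreflux.units import field_from_potential


def brute_force_events(traj, z_top, z_bottom):
    """Independent frame-by-frame scanner: walks every frame of every ion,
    remembering which bulk compartment it last entered the pore from."""
    found = []
    for i, particle in enumerate(traj.particles):
        last_bulk = None
        in_pore = False
        t_enter = None
        z0 = traj.positions[0, i, 2]
        if z0 > z_top:
            prev = "above"
        elif z0 < z_bottom:
            prev = "below"
        else:
            prev = "pore"
        in_pore = prev == "pore"
        for f in range(1, traj.n_frames):
            z = traj.positions[f, i, 2]
            here = "above" if z > z_top else ("below" if z < z_bottom else "pore")
            if here == prev:
                continue
            if here == "pore":
                last_bulk = prev
                t_enter = traj.times[f]
                in_pore = True
            elif in_pore:
                if here == "below" and last_bulk == "above":
                    found.append((particle.id, t_enter, traj.times[f], "inward"))
                    last_bulk = None
                elif here == "above" and last_bulk == "below":
                    found.append((particle.id, t_enter, traj.times[f], "outward"))
                    last_bulk = None
                in_pore = False
            prev = here
    found.sort(key=lambda e: e[2])
    return found


class TestUnwrap:
    def test_boundary_crossing_becomes_monotone(self, traj_factory):
        lz = 60.0
        z = np.array([25.0, 26.0, 27.0, -32.0, -31.0, -30.0]) % lz - 10.0
        # construct an apparent -~lz jump from steady +1 Å/frame motion
        z = np.array([47.0, 48.0, 49.0, -10.0 + 0.0, -9.0, -8.0])
        traj = traj_factory(z, box=(30.0, 30.0, lz))
        unwrapped = unwrap_axis(traj)
        assert np.all(np.diff(unwrapped.positions[:, 0, 2]) > 0)

    def test_identity_without_jumps(self, traj_factory):
        z = np.linspace(0, 5, 20)
        traj = traj_factory(z)
        out = unwrap_axis(traj)
        assert np.array_equal(out.positions, traj.positions)

    def test_random_walk_matches_true_unwrapped_record(self, traj_factory):
        rng = np.random.default_rng(12)
        lz = 60.0
        steps = rng.normal(0, 4.0, size=(300, 5))
        true_z = 10.0 + np.cumsum(steps, axis=0)
        wrapped = (true_z + 10.0) % lz - 10.0
        traj = traj_factory(wrapped, box=(30.0, 30.0, lz))
        out = unwrap_axis(traj)
        # identical up to the initial wrap offset of each ion
        delta = out.positions[:, :, 2] - true_z
        assert np.allclose(delta, delta[0], atol=1e-9)


class TestDetector:
    def test_monotone_descent_is_one_inward_event(self, traj_factory):
        traj = traj_factory(np.linspace(45.0, -10.0, 80))
        events = detect_permeations(traj, 40.0, -5.0)
        assert len(events) == 1
        assert events[0].direction == "inward"
        assert events[0].t_exit_ns > events[0].t_enter_ns

    def test_oscillation_inside_pore_is_no_event(self, traj_factory):
        t = np.linspace(0, 8 * np.pi, 300)
        traj = traj_factory(25.0 + 5.0 * np.sin(t))
        assert detect_permeations(traj, 40.0, -5.0) == []

    def test_boundary_dithering_not_double_counted(self, traj_factory):
        z = np.concatenate([
            [45.0], np.linspace(35, 0, 10), [-6, -4, -6, -4, -6],  # dither at bottom
            np.linspace(0, 35, 10), [-1.0],
        ])
        traj = traj_factory(z)
        events = detect_permeations(traj, 40.0, -5.0)
        assert len(events) == 1

    def test_outward_direction_symmetric(self, traj_factory):
        traj = traj_factory(np.linspace(-10.0, 45.0, 80))
        events = detect_permeations(traj, 40.0, -5.0)
        assert [e.direction for e in events] == ["outward"]

    def test_invalid_planes_rejected(self, traj_factory):
        traj = traj_factory(np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            detect_permeations(traj, -5.0, 40.0)

    def test_matches_brute_force_on_random_walks(self, traj_factory):
        """Detector and an independent scanner agree on 100 random
        trajectories, including boundary-grazing paths."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            z = 20.0 + np.cumsum(rng.normal(0, 6.0, size=(120, 4)), axis=0)
            z = np.clip(z, -12.0, 52.0)
            traj = traj_factory(z)
            got = [
                (e.ion_id, e.t_enter_ns, e.t_exit_ns, e.direction)
                for e in detect_permeations(traj, 40.0, -5.0)
            ]
            assert got == brute_force_events(traj, 40.0, -5.0)

    def test_event_invariants(self, traj_factory):
        with pytest.raises(ValueError):
            PermeationEvent(0, 5.0, 4.0, "inward")
        with pytest.raises(ValueError):
            PermeationEvent(0, 1.0, 2.0, "sideways")


class TestSimulatorLedgerConsistency:
    def test_detector_matches_step_resolution_ledger(self):
        """At save_stride = 1 the analysis-side detector reproduces the
        simulator's internal passage ledger exactly."""
        pot = conduction_channel_potential(field=field_from_potential(-100, 60.0))
        cfg = SimConfig(n_ions=6, n_steps=100_000, save_stride=1, seed=33)
        traj = simulate_langevin(cfg, pot)
        events = detect_permeations(traj, cfg.detect_z_top, cfg.detect_z_bottom)
        ledger = traj.metadata["passages"]
        assert len(events) == len(ledger)
        for ev, led in zip(events, sorted(ledger, key=lambda p: p["t_exit_ns"])):
            assert ev.ion_id == led["ion"]
            assert ev.direction == led["direction"]
            assert ev.t_exit_ns == pytest.approx(led["t_exit_ns"], abs=1e-12)

    def test_conductance_pipeline_consistency(self):
        """Detected counts fed to the conductance estimator reproduce the
        hand-computed per-run values bit for bit."""
        pot = conduction_channel_potential(field=field_from_potential(-100, 60.0))
        counts, durations = [], []
        for seed in (1, 2):
            cfg = SimConfig(n_ions=8, n_steps=400_000, seed=seed)
            traj = simulate_langevin(cfg, pot)
            ev = detect_permeations(traj, 40.0, -5.0)
            counts.append(events_per_run(ev, "inward"))
            durations.append(float(traj.times[-1]))
        est = conductance_estimate(counts, durations, -100.0)
        for g, n, t in zip(est.per_run_pS, counts, durations):
            expected = n * 1.602176634e-19 / (t * 1e-9 * 0.1) * 1e12
            assert g == expected

    def test_field_increases_inward_flux(self):
        """Mean inward event count under the -100 mV field exceeds the
        zero-field count (paired seeds, 10 replicates)."""
        with_field = conduction_channel_potential(field=field_from_potential(-100, 60.0))
        no_field = conduction_channel_potential(field=0.0)
        n_with, n_without = [], []
        for seed in range(10):
            cfg = SimConfig(n_ions=8, n_steps=600_000, seed=seed)
            t1 = simulate_langevin(cfg, with_field)
            t2 = simulate_langevin(cfg, no_field)
            n_with.append(events_per_run(detect_permeations(t1, 40.0, -5.0), "inward"))
            n_without.append(events_per_run(detect_permeations(t2, 40.0, -5.0), "inward"))
        wins = sum(a > b for a, b in zip(n_with, n_without))
        ties = sum(a == b for a, b in zip(n_with, n_without))
        assert np.mean(n_with) > np.mean(n_without)
        assert wins > (10 - ties) / 2  # sign test majority


class TestOccupancy:
    sites = (
        SiteDefinition("A", (22.0, 26.0)),
        SiteDefinition("B", (17.0, 21.0)),
        SiteDefinition("C", (7.0, 11.0)),
    )

    def test_parked_ion_occupies_its_site(self, traj_factory):
        traj = traj_factory(np.full(50, 9.0))
        occ = site_occupancy(traj, self.sites)
        assert occ.fraction_occupied("C") == 1.0
        assert occ.fraction_occupied("B") == 0.0

    def test_empty_region_all_vacant(self, traj_factory):
        traj = traj_factory(np.full(20, 33.0))
        occ = site_occupancy(traj, self.sites)
        assert all(occ.fraction_occupied(s.label) == 0.0 for s in self.sites)

    def test_multi_occupancy_reported(self, traj_factory):
        z = np.stack([np.full(10, 23.0), np.full(10, 25.0)], axis=1)
        occ = site_occupancy(traj_factory(z), self.sites)
        assert all(len(o) == 2 for o in occ.occupants["A"])

    def test_overlapping_ranges_rejected(self, traj_factory):
        bad = (SiteDefinition("A", (0.0, 5.0)), SiteDefinition("B", (4.0, 8.0)))
        with pytest.raises(ValueError, match="overlap"):
            site_occupancy(traj_factory(np.zeros(3)), bad)

    def test_matches_per_frame_range_scan(self, traj_factory):
        rng = np.random.default_rng(7)
        z = rng.uniform(0, 30, size=(200, 6))
        traj = traj_factory(z)
        occ = site_occupancy(traj, self.sites)
        for s in self.sites:
            lo, hi = s.z_range
            for f in range(200):
                expected = tuple(np.nonzero((z[f] >= lo) & (z[f] < hi))[0])
                assert occ.occupants[s.label][f] == expected


def _occupancy_table(times, b_lists, c_lists):
    return OccupancyTable(
        times_ns=np.asarray(times, dtype=float),
        occupants={"B": [tuple(x) for x in b_lists], "C": [tuple(x) for x in c_lists]},
    )


class TestCooperativity:
    def test_every_release_handed_off(self):
        # ion 1 sits in C then exits; ion 2 moves from B into C right after
        times = np.arange(10) * 0.1
        c = [(1,)] * 5 + [(2,)] * 5
        b = [(2,)] * 5 + [()] * 5
        occ = _occupancy_table(times, b, c)
        events = [PermeationEvent(1, 0.1, 0.55, "inward")]
        res = cooperativity_fraction(occ, events, window_ns=0.3)
        assert res.fraction == 1.0

    def test_no_handoffs(self):
        times = np.arange(10) * 0.1
        c = [(1,)] * 5 + [()] * 5
        b = [()] * 10
        occ = _occupancy_table(times, b, c)
        events = [PermeationEvent(1, 0.1, 0.55, "inward")]
        assert cooperativity_fraction(occ, events, window_ns=0.3).fraction == 0.0

    def test_no_events_is_undefined_not_zero(self):
        occ = _occupancy_table([0.0, 0.1], [(), ()], [(), ()])
        res = cooperativity_fraction(occ, [], window_ns=0.5)
        assert res.fraction is None
        assert res.n_events == 0

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(41)
        times = np.arange(120) * 0.05
        for _ in range(20):
            b = [tuple(rng.choice(5, size=rng.integers(0, 2), replace=False)) for _ in times]
            c = [tuple(rng.choice(5, size=rng.integers(0, 2), replace=False)) for _ in times]
            occ = _occupancy_table(times, b, c)
            events = [
                PermeationEvent(int(i), 0.3, float(t), "inward")
                for i, t in zip(rng.integers(0, 5, 4), np.sort(rng.uniform(1.0, 5.0, 4)))
            ]
            window = 0.4
            # direct enumeration over events, independently coded
            n_hand = 0
            n_tot = 0
            for ev in events:
                n_tot += 1
                release = None
                for f in range(len(times) - 1, -1, -1):
                    if times[f] <= ev.t_exit_ns and ev.ion_id in c[f]:
                        release = f
                        break
                if release is None:
                    continue
                prev_b = b[release]
                ok = False
                for f in range(len(times)):
                    if abs(times[f] - times[release]) <= window + 1e-12:
                        if any(x in c[f] for x in prev_b):
                            ok = True
                if ok:
                    n_hand += 1
            res = cooperativity_fraction(occ, events, window_ns=window)
            assert (res.n_handoffs, res.n_events) == (n_hand, n_tot)
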