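import math

import numpy as np
import pytest

from featrack.simulate import (A_REF, GrowDivideConfig, RodState, SimConfig,
                               friction_factors, grow_divide_fixture,
                               integrate, lattice_state, observe,
                               packing_fraction, pair_forces,
                               potential_energy, sample_rod_properties,
                               simulate, step)


def _two_rod_state(r0, r1, phi0=0.3, phi1=1.2, a=3.0):
    return RodState(np.array([r0, r1], dtype=float),
                    np.array([phi0, phi1]), np.array([a, a]),
                    np.array([60.0, 60.0]))


class TestRodProperties:
    def test_analytic_gamma_mean(self):
        cfg = SimConfig()
        assert cfg.gamma_shape * cfg.gamma_scale == pytest.approx(3.7944)

    def test_sample_moments_match_analytic(self):
        cfg = SimConfig()
        a, intensity = sample_rod_properties(cfg, 100_000, np.random.default_rng(7))
        se_a = math.sqrt(cfg.gamma_shape) * cfg.gamma_scale / math.sqrt(len(a))
        assert abs(a.mean() - 3.7944) < 3 * se_a + 1e-3  # tiny clip bias at 1
        se_i = cfg.norm_sd / math.sqrt(len(intensity))
        assert abs(intensity.mean() - cfg.norm_mean) < 3 * se_i
        assert a.min() >= 1.0

    def test_same_seed_identical(self):
        cfg = SimConfig()
        out1 = sample_rod_properties(cfg, 100, np.random.default_rng(3))
        out2 = sample_rod_properties(cfg, 100, np.random.default_rng(3))
        assert np.array_equal(out1[0], out2[0])
        assert np.array_equal(out1[1], out2[1])


class TestPackingFraction:
    def test_unit_disk_limit(self):
        state = RodState(np.zeros((1, 2)), np.zeros(1), np.ones(1), np.ones(1))
        assert packing_fraction(state, 1.0) == pytest.approx(math.pi / 4)

    def test_single_rod_formula(self):
        state = RodState(np.zeros((1, 2)), np.zeros(1), np.array([2.0]), np.ones(1))
        assert packing_fraction(state, 10.0) == pytest.approx((1 + math.pi / 4) / 10)

    def test_baseline_density_near_quarter(self):
        cfg = SimConfig(n_rods=700, A=10_000.0, seed=5)
        state = lattice_state(cfg, np.random.default_rng(5))
        assert packing_fraction(state, cfg.A) == pytest.approx(0.2506, abs=0.01)


class TestPairForces:
    def test_zero_beyond_cutoff(self):
        cfg = SimConfig(n_rods=2, A=10_000.0)
        state = _two_rod_state([10.0, 10.0], [40.0, 40.0])
        F, tau, U = pair_forces(state, cfg)
        assert np.all(F == 0) and np.all(tau == 0) and U == 0

    def test_newtons_third_law(self):
        cfg = SimConfig(n_rods=2, A=10_000.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            state = _two_rod_state([50.0, 50.0],
                                   50.0 + rng.uniform(-3, 3, 2),
                                   phi0=rng.uniform(0, math.pi),
                                   phi1=rng.uniform(0, math.pi))
            F, _, _ = pair_forces(state, cfg)
            assert np.linalg.norm(F.sum(axis=0)) < 1e-12

    def test_gradient_matches_finite_differences(self):
        cfg = SimConfig(n_rods=2, A=10_000.0)
        rng = np.random.default_rng(1)
        h = 1e-6
        checked = 0
        for _ in range(10):
            state = _two_rod_state([50.0, 50.0],
                                   50.0 + rng.uniform(1.5, 2.5, 2),
                                   phi0=rng.uniform(0, math.pi),
                                   phi1=rng.uniform(0, math.pi))
            F, tau, U = pair_forces(state, cfg)
            if U == 0:
                continue
            checked += 1
            for i in range(2):
                for ax in range(2):
                    sp = state.copy()
                    sp.r[i, ax] += h
                    sm = state.copy()
                    sm.r[i, ax] -= h
                    fd = -(potential_energy(sp, cfg) - potential_energy(sm, cfg)) / (2 * h)
                    assert F[i, ax] == pytest.approx(fd, rel=1e-4, abs=1e-8)
                sp = state.copy()
                sp.phi[i] += h
                sm = state.copy()
                sm.phi[i] -= h
                fd = -(potential_energy(sp, cfg) - potential_energy(sm, cfg)) / (2 * h)
                assert tau[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)
        assert checked >= 5


class TestIntegration:
    def test_isolated_rod_without_drive_stays_put(self):
        cfg = SimConfig(n_rods=1, A=10_000.0, nu=0.0)
        state = RodState(np.array([[50.0, 50.0]]), np.array([0.7]),
                         np.array([3.0]), np.array([60.0]))
        out = integrate(state, cfg, 5.0)
        assert np.allclose(out.r, state.r) and np.allclose(out.phi, state.phi)

    def test_reference_rod_unit_speed(self):
        # the non-dimensionalisation: an isolated rod of reference aspect
        # ratio with nu = 1 covers one rod width per unit time
        cfg = SimConfig(n_rods=1, A=10_000.0, nu=1.0)
        state = RodState(np.array([[50.0, 50.0]]), np.array([0.25]),
                         np.array([A_REF]), np.array([60.0]))
        out = integrate(state, cfg, 1.0)
        disp = out.r[0] - state.r[0]
        assert np.linalg.norm(disp) == pytest.approx(1.0, rel=1e-9)
        u = np.array([math.cos(0.25), math.sin(0.25)])
        assert disp @ u == pytest.approx(1.0, rel=1e-9)

    def test_midpoint_second_order_convergence(self):
        # two short rods close together: every segment pair stays well
        # inside the interaction cutoff for the whole (short) run, so the
        # trajectory is smooth and the Richardson ratio isolates the
        # integrator's truncation error
        base = RodState(np.array([[50.0, 50.0], [51.5, 50.3]]),
                        np.array([0.2, 1.9]),
                        np.array([2.0, 2.0]), np.full(2, 60.0))

        def end_state(dt):
            cfg = SimConfig(n_rods=2, A=10_000.0, nu=1.0, dt=dt)
            s = base.copy()
            n = int(round(0.2 / dt))
            assert n * dt == pytest.approx(0.2)
            for _ in range(n):
                s = step(s, cfg, dt)
            return np.concatenate([s.r.ravel(), s.phi])

        e1 = np.linalg.norm(end_state(0.02) - end_state(0.01))
        e2 = np.linalg.norm(end_state(0.01) - end_state(0.005))
        order = math.log2(e1 / e2)
        assert 1.8 < order < 2.5

    def test_potential_nonincreasing_without_drive(self):
        rng = np.random.default_rng(3)
        state = RodState(50.0 + rng.uniform(-4, 4, (8, 2)),
                         rng.uniform(0, math.pi, 8),
                         rng.uniform(2, 4, 8), np.full(8, 60.0))
        cfg = SimConfig(n_rods=8, A=10_000.0, nu=0.0, dt=0.02)
        energies = [potential_energy(state, cfg)]
        for _ in range(20):
            state = integrate(state, cfg, 0.2)
            energies.append(potential_energy(state, cfg))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-8 + 1e-4 * np.abs(energies[:-1]))

    def test_translation_equivariance(self):
        cfg = SimConfig(n_rods=9, A=900.0, nu=1.0)
        rng = np.random.default_rng(4)
        state = RodState(rng.uniform(0, 30, (9, 2)), rng.uniform(0, math.pi, 9),
                         rng.uniform(2, 4, 9), np.full(9, 60.0))
        shift = np.array([10.0, 20.0])
        shifted = state.copy()
        shifted.r = (shifted.r + shift) % 30.0
        out = integrate(state, cfg, 2.0)
        out_shifted = integrate(shifted, cfg, 2.0)
        d = (out_shifted.r - out.r - shift) % 30.0
        d = np.minimum(d, 30.0 - d)
        assert np.abs(d).max() < 1e-6
        assert np.abs(out_shifted.phi - out.phi).max() < 1e-6


class TestObservation:
    def test_noise_free_observation_is_exact(self):
        cfg = SimConfig(n_rods=5, A=400.0, sigma_r=0, sigma_phi=0,
                        sigma_a=0, sigma_I=0)
        rng = np.random.default_rng(0)
        state = lattice_state(cfg, rng)
        table = observe(state, cfg, 0, rng)
        order = np.argsort(table.ids)
        assert np.allclose(np.sort(table.X[:, 3]), np.sort(state.a))
        assert np.allclose(np.sort(table.X[:, 2]), np.sort(state.phi % math.pi))

    def test_positional_noise_sd_recovered(self):
        cfg = SimConfig(n_rods=100, A=10_000.0, sigma_r=0.2, sigma_phi=0,
                        sigma_a=0, sigma_I=0)
        rng = np.random.default_rng(1)
        state = lattice_state(cfg, rng)
        errs = []
        for f in range(100):
            table = observe(state, cfg, f, rng)
            order = np.argsort(table.ids)
            errs.append(table.X[order][:, 0] - state.r[:, 0])
        errs = np.concatenate(errs)
        se = 0.2 / math.sqrt(2 * len(errs))
        assert abs(errs.std() - 0.2) < 3 * se

    def test_same_seed_identical_tables(self):
        cfg = SimConfig(n_rods=20, A=900.0)
        state = lattice_state(cfg, np.random.default_rng(2))
        t1 = observe(state, cfg, 0, np.random.default_rng(9))
        t2 = observe(state, cfg, 0, np.random.default_rng(9))
        assert np.array_equal(t1.X, t2.X) and np.array_equal(t1.ids, t2.ids)


class TestSimulate:
    def test_ground_truth_is_complete_bijection(self):
        ds = simulate(SimConfig(n_rods=25, A=900.0, n_frames=4, dT=2.0,
                                burn_in=5.0, seed=0))
        for f in range(3):
            g = ds.gt_links.df[ds.gt_links.df.frame_from == f]
            assert len(g) == 25
            assert len(set(g.id_from)) == 25 and len(set(g.id_to)) == 25
        assert all(t.n_o == 25 for t in ds.frames)

    def test_motionless_noiseless_system_is_trivially_trackable(self):
        ds = simulate(SimConfig(n_rods=16, A=1600.0, n_frames=3, dT=2.0,
                                nu=0.0, burn_in=5.0, sigma_r=0, sigma_phi=0,
                                sigma_a=0, sigma_I=0, seed=1))
        from featrack.model import compute_displacements
        from featrack.tracker import LinkSet
        g = LinkSet(ds.gt_links.df[ds.gt_links.df.frame_from == 0])
        d = compute_displacements(ds.frames[0], ds.frames[1], g, ds.spec)
        assert np.abs(d).max() < 1e-6

    def test_jammed_configuration_refused(self):
        with pytest.raises(ValueError, match="packing"):
            simulate(SimConfig(n_rods=900, A=900.0, n_frames=2))

    def test_same_seed_reproduces_dataset(self):
        cfg = SimConfig(n_rods=16, A=900.0, n_frames=3, dT=2.0, burn_in=2.0,
                        seed=11)
        d1, d2 = simulate(cfg), simulate(cfg)
        for t1, t2 in zip(d1.frames, d2.frames):
            assert np.array_equal(t1.X, t2.X)


class TestGrowDivideFixture:
    def test_three_generations_make_eight_cells(self):
        cfg = GrowDivideConfig(n_founders=1, growth_rate=0.1, n_frames=24,
                               seed=0)
        ds = grow_divide_fixture(cfg)
        assert ds.frames[-1].n_o == 8
        assert len(ds.gt_lineage) == 7

    def test_zero_growth_never_divides(self):
        ds = grow_divide_fixture(GrowDivideConfig(growth_rate=0.0,
                                                  n_frames=10, seed=0))
        assert len(ds.gt_lineage) == 0
        assert all(t.n_o == 1 for t in ds.frames)

    def test_lineage_log_replays_consistently(self):
        ds = grow_divide_fixture(GrowDivideConfig(n_founders=2, n_frames=24,
                                                  seed=3))
        lin = ds.gt_lineage
        # every child appears once, parents exist before their children,
        # and each parent has at most one new child per frame
        assert lin["child_cell"].is_unique
        born = {0: 0, 1: 0}
        for row in lin.sort_values("division_frame").itertuples():
            assert row.parent_cell in born
            assert born[row.parent_cell] < row.division_frame
            born[row.child_cell] = row.division_frame
        assert not lin.duplicated(["parent_cell", "division_frame"]).any()
        # cell count grows by one per division
        assert ds.frames[-1].n_o == 2 + len(lin)

    def test_friction_factors_positive_and_normalized(self):
        a = np.array([1.0, 2.0, A_REF, 6.0])
        f_par, f_perp, f_rot = friction_factors(a)
        assert np.all(f_par > 0) and np.all(f_perp > 0) and np.all(f_rot > 0)
        assert f_par[2] == pytest.approx(1.0)
        assert np.all(f_perp >= f_par * 0.99)
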