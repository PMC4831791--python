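import math

import numpy as np
import pytest

from shmoo.actin import make_pheromone_field
from shmoo.dynamics import (
    BatchSimulator,
    CellState,
    initial_state,
    run_simulation,
    solve_cyclic_tridiag,
    solve_tridiag,
    step_state,
)
from shmoo.mesh import build_mesh
from shmoo.metrics import is_polarized


def uniform_kappa(mesh, value=13.0):
    return np.full(mesh.n_theta, value)


class TestTridiagonalSolvers:
    def test_thomas_matches_dense_solve(self, rng):
        n = 12
        a = rng.uniform(-1, 0, (5, n))
        c = rng.uniform(-1, 0, (5, n))
        b = 4.0 + rng.uniform(0, 1, (5, n))
        d = rng.normal(size=(5, n))
        x = solve_tridiag(a, b, c, d)
        for s in range(5):
            A = np.diag(b[s]) + np.diag(a[s, 1:], -1) + np.diag(c[s, :-1], 1)
            assert np.allclose(A @ x[s], d[s], atol=1e-10)

    def test_cyclic_matches_dense_solve(self, rng):
        n = 10
        a = rng.uniform(-1, 0, (4, n))
        c = rng.uniform(-1, 0, (4, n))
        b = 4.0 + rng.uniform(0, 1, (4, n))
        d = rng.normal(size=(4, n))
        x = solve_cyclic_tridiag(a, b, c, d)
        for s in range(4):
            A = np.diag(b[s]) + np.diag(a[s, 1:], -1) + np.diag(c[s, :-1], 1)
            A[0, -1] = a[s, 0]
            A[-1, 0] = c[s, -1]
            assert np.allclose(A @ x[s], d[s], atol=1e-10)


class TestInitialState:
    def test_resting_partition(self, params, mesh24):
        st = initial_state(params, mesh24)
        mem = st.mu.sum() * mesh24.boundary_seg_len
        assert mem == pytest.approx(0.13 * params.M, rel=1e-12)
        assert st.mass(mesh24) == pytest.approx(params.M, rel=1e-12)
        # detailed balance of the exchange
        assert st.mu[0] / st.n[0, 0] == pytest.approx(params.k_on / params.k_off)

    def test_custom_partition(self):
        from shmoo.params import ModelParams

        p = ModelParams(R=2.0, R_n=0.0, membrane_fraction_rest=0.5)
        mesh = build_mesh(2.0, 0.0, 8, 20)
        st = initial_state(p, mesh)
        assert st.mu.sum() * mesh.boundary_seg_len == pytest.approx(500.0, rel=1e-12)


class TestStepState:
    def test_rest_state_is_fixed_point_without_pheromone(self, params, mesh24):
        st = initial_state(params, mesh24)
        S0 = make_pheromone_field(0.0, 0.0, 0.0, mesh24)
        st2 = step_state(st, params, uniform_kappa(mesh24), S0, 5.0, mesh24)
        assert np.allclose(st2.n, st.n, rtol=1e-10)
        assert np.allclose(st2.mu, st.mu, rtol=1e-10)

    def test_mass_conserved_and_nonnegative_under_forcing(self, params, mesh24):
        st = initial_state(params, mesh24)
        S = make_pheromone_field(2.0, 0.1, 0.0, mesh24)
        kap = uniform_kappa(mesh24) * np.linspace(0.5, 1.5, mesh24.n_theta)
        for _ in range(200):
            st = step_state(st, params, kap, S, 5.0, mesh24)
        assert st.mass(mesh24) == pytest.approx(params.M, rel=1e-8)
        assert st.n.min() >= 0 and st.mu.min() >= 0

    def test_relaxes_to_exchange_equilibrium_without_advection(self, params, mesh24):
        """chi=0: any nonnegative state relaxes to the uniform state with
        mu/n = k_on/k_off (no polarization without the actin feedback)."""
        p = params.with_(chi=0.0)
        rng = np.random.default_rng(0)
        st = initial_state(p, mesh24)
        n = rng.uniform(0, 2, st.n.shape) * st.n
        mu = rng.uniform(0, 2, st.mu.shape) * st.mu
        M = (n * mesh24.areas2d()).sum() + mu.sum() * mesh24.boundary_seg_len
        st = CellState(t=0.0, n=n, mu=mu)
        S = make_pheromone_field(5.0, 0.0, 0.0, mesh24)
        for _ in range(400):
            st = step_state(st, p, uniform_kappa(mesh24), S, 5.0, mesh24)
        area = math.pi * (p.R**2 - p.R_n**2)
        ratio = p.k_on / p.k_off
        n_eq = M / (area + ratio * 2 * math.pi * p.R)
        assert np.allclose(st.n, n_eq, rtol=1e-4)
        assert np.allclose(st.mu, ratio * n_eq, rtol=1e-4)

    def test_mass_scaling_invariance(self, params, mesh24):
        """Scaling the total pool M scales the fields linearly and leaves
        the dynamics otherwise unchanged (the nucleation flux normalizes mu
        by M, so only kappa*chi and the field shapes matter)."""
        S = make_pheromone_field(2.0, 0.0, 0.0, mesh24)
        kap = uniform_kappa(mesh24) * np.linspace(0.8, 1.2, mesh24.n_theta)
        alpha = 3.0
        p1, p2 = params, params.with_(M=alpha * params.M)
        s1, s2 = initial_state(p1, mesh24), initial_state(p2, mesh24)
        for _ in range(50):
            s1 = step_state(s1, p1, kap, S, 5.0, mesh24)
            s2 = step_state(s2, p2, kap, S, 5.0, mesh24)
        assert np.allclose(s2.n, alpha * s1.n, rtol=1e-8)
        assert np.allclose(s2.mu, alpha * s1.mu, rtol=1e-8)

    def test_kappa_chi_degeneracy(self, params, mesh24):
        """(kappa/2, 2 chi) leaves the noise-free trajectory unchanged:
        only the product kappa*chi enters the feedback."""
        S = make_pheromone_field(2.0, 0.0, 0.0, mesh24)
        kap = uniform_kappa(mesh24) * np.linspace(0.8, 1.2, mesh24.n_theta)
        p2 = params.with_(chi=2 * params.chi)
        s1, s2 = initial_state(params, mesh24), initial_state(p2, mesh24)
        for _ in range(50):
            s1 = step_state(s1, params, kap, S, 5.0, mesh24)
            s2 = step_state(s2, p2, kap / 2.0, S, 5.0, mesh24)
        assert np.allclose(s2.n, s1.n, rtol=1e-8)
        assert np.allclose(s2.mu, s1.mu, rtol=1e-8)

    def test_invalid_dt_rejected(self, params, mesh24):
        st = initial_state(params, mesh24)
        S = make_pheromone_field(0.0, 0.0, 0.0, mesh24)
        with pytest.raises(ValueError):
            step_state(st, params, uniform_kappa(mesh24), S, -1.0, mesh24)


class TestRunSimulation:
    def test_no_pheromone_never_polarizes(self, params):
        S_mesh = build_mesh(params.R, params.R_n, 8, 20)
        S = make_pheromone_field(0.0, 0.0, 0.0, S_mesh)
        res = run_simulation(params, S, seed=1, t_max=1800.0, mesh=S_mesh, dt=15.0)
        assert not res.polarized
        assert res.t_pol is None and res.cap_angle is None

    def test_frozen_uniform_noise_preserves_symmetry(self, params, tiny_mesh):
        """sigma = delta = 0 with uniform pheromone: with no noise to break
        it, rotational symmetry is preserved.  Below the aggregation
        threshold the symmetric state is stable and holds indefinitely;
        above it, it is an unstable equilibrium, so round-off can only grow
        at the instability rate and stays far below the criterion over a
        bounded horizon."""
        p = params.with_(sigma=0.0, delta=0.0, chi=0.3)  # subcritical
        S = make_pheromone_field(3.0, 0.0, 0.0, tiny_mesh)
        res = run_simulation(p, S, seed=2, t_max=2 * 3600.0, mesh=tiny_mesh, dt=15.0)
        assert not res.polarized
        mu_final = res.kymograph[-1]
        assert np.allclose(mu_final, mu_final[0], rtol=1e-10)

        p2 = params.with_(sigma=0.0, delta=0.0)  # supercritical at 3 nM
        res2 = run_simulation(p2, S, seed=2, t_max=900.0, mesh=tiny_mesh, dt=15.0)
        assert not res2.polarized
        mu2 = res2.kymograph[-1]
        assert np.abs(mu2 / mu2.mean() - 1.0).max() < 1e-4

    def test_bit_reproducible(self, params, tiny_mesh):
        S = make_pheromone_field(2.0, 0.0, 0.0, tiny_mesh)
        r1 = run_simulation(params, S, seed=3, t_max=3600.0, mesh=tiny_mesh, dt=15.0)
        r2 = run_simulation(params, S, seed=3, t_max=3600.0, mesh=tiny_mesh, dt=15.0)
        assert r1.polarized == r2.polarized
        assert np.array_equal(r1.kymograph, r2.kymograph)

    def test_kymograph_patch_coalescence(self, params, mesh24):
        """After polarization onset the number of distinct membrane patches
        (local maxima above background on a smoothed profile) does not
        increase: transient multiple patches coalesce into the single cap."""
        S = make_pheromone_field(2.0, 0.0, 0.0, mesh24)
        res = run_simulation(params, S, seed=5, t_max=4 * 3600.0, mesh=mesh24,
                             dt=15.0, record_every=60.0)
        assert res.polarized
        kernel = np.ones(5) / 5.0

        def n_patches(mu):
            sm = np.convolve(np.tile(mu, 2), kernel, mode="same")[
                mu.size // 2 : mu.size // 2 + mu.size
            ]
            above = sm > 1.5 * np.median(sm)
            left = np.roll(sm, 1)
            right = np.roll(sm, -1)
            return int(((sm >= left) & (sm > right) & above).sum())

        k_onset = int(np.searchsorted(res.kymograph_times, res.t_pol))
        counts = [n_patches(row) for row in res.kymograph[k_onset:]]
        assert counts[-1] <= counts[0]
        assert counts[-1] == 1

    def test_mesh_refinement_stability_of_polarization_time(self, params):
        """A deterministic run (frozen asymmetric kappa) polarizes at nearly
        the same time on the 24x60 and 48x120 meshes (< 10% shift)."""
        kap_sectors = np.full(10, params.kappa_mean)
        kap_sectors[0] *= 1.3  # one elevated sector seeds the cap
        times = {}
        for n_r, n_t in [(24, 60), (48, 120)]:
            mesh = build_mesh(params.R, params.R_n, n_r, n_t)
            p = params.with_(sigma=0.0, delta=0.0)
            S = make_pheromone_field(2.0, 0.0, 0.0, mesh)
            sim = BatchSimulator(p, mesh, [S], master_seed=0, dt=5.0,
                                 t_max=4 * 3600.0, check_interval=5.0)
            sim.kappa = kap_sectors[None, :].copy()  # frozen (sigma = 0)
            out = sim.run()
            assert out["polarized"][0]
            times[(n_r, n_t)] = out["t_pol"][0]
        t1, t2 = times[(24, 60)], times[(48, 120)]
        assert abs(t2 - t1) / t1 < 0.10


class TestBatchSimulator:
    def test_matches_single_cell_path(self, params, tiny_mesh):
        """The batched integrator and run_simulation agree member-by-member
        (same substream keys)."""
        S = make_pheromone_field(2.0, 0.0, 0.0, tiny_mesh)
        single = run_simulation(params, S, seed=9, t_max=3600.0,
                                mesh=tiny_mesh, dt=15.0)
        batch = BatchSimulator(params, tiny_mesh, [S, S], master_seed=9,
                               dt=15.0, t_max=3600.0, member_keys=[0, 123])
        out = batch.run()
        assert out["polarized"][0] == single.polarized
        if single.polarized:
            assert out["t_pol"][0] == single.t_pol
            assert out["cap_angle"][0] == pytest.approx(single.cap_angle)

    def test_member_mass_conservation(self, params, tiny_mesh):
        S = make_pheromone_field(1.5, 0.1, 0.0, tiny_mesh)
        sim = BatchSimulator(params, tiny_mesh, [S] * 3, master_seed=4,
                             dt=15.0, t_max=1800.0)
        sim.run()
        areas = tiny_mesh.areas2d()
        for b in range(3):
            mass = (sim.n[b] * areas).sum() + sim.mu[b].sum() * tiny_mesh.boundary_seg_len
            assert mass == pytest.approx(params.M, rel=1e-8)
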