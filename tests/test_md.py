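"""Toy MD engine: water force field, integrators, thermostats, fixtures."""

import numpy as np
import pytest

from fearcf import md
from fearcf.constants import AKMA_TIME_FS, KB


class TestWaterDimerInit:
    def test_oo_separation_honored(self):
        st = md.water_dimer_init(2.9, seed=1)
        assert np.linalg.norm(st.positions[3] - st.positions[0]) == pytest.approx(2.9)

    def test_same_seed_same_state(self):
        a = md.water_dimer_init(3.2, seed=7)
        b = md.water_dimer_init(3.2, seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.velocities, b.velocities)

    def test_velocity_equipartition(self):
        st = md.water_dimer_init(2.9, temperature=300.0, seed=3,
                                 batch_shape=(2000,))
        for i, m in enumerate(st.masses):
            var = st.velocities[:, i, :].var()
            assert var == pytest.approx(KB * 300.0 / m, rel=0.05)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="separation"):
            md.water_dimer_init(0.5)


class TestWaterForces:
    def test_forces_match_finite_differences(self, rng):
        ff = md.WaterForceField()
        st = md.water_dimer_init(3.1, seed=5)
        x = st.positions
        F, _ = ff(x, cavity_radius=6.0)
        h = 1e-6
        for a in range(6):
            for c in range(3):
                xp = x.copy(); xp[a, c] += h
                xm = x.copy(); xm[a, c] -= h
                fd = -(ff(xp, cavity_radius=6.0)[1]
                       - ff(xm, cavity_radius=6.0)[1]) / (2 * h)
                assert F[a, c] == pytest.approx(fd, rel=1e-6, abs=1e-7)

    def test_cutoff_zeroes_distant_interaction(self):
        ff = md.WaterForceField(cutoff=8.0)
        st = md.water_dimer_init(9.5, seed=2, cavity_radius=None)
        F, _ = md.compute_forces(st, ff)
        # intermolecular forces vanish; only bonded terms remain, and the
        # two molecules feel no net pull toward each other
        assert np.allclose(F[:3].sum(0), 0.0, atol=1e-10)
        assert np.allclose(F[3:].sum(0), 0.0, atol=1e-10)

    def test_energy_rotation_invariant(self, rng):
        ff = md.WaterForceField()
        st = md.water_dimer_init(3.0, seed=4, cavity_radius=None)
        q = rng.normal(size=4); q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1-2*(y*y+z*z), 2*(x*y-z*w), 2*(x*z+y*w)],
            [2*(x*y+z*w), 1-2*(x*x+z*z), 2*(y*z-x*w)],
            [2*(x*z-y*w), 2*(y*z+x*w), 1-2*(x*x+y*y)]])
        _, e1 = ff(st.positions)
        _, e2 = ff(st.positions @ R.T)
        assert e1 == pytest.approx(e2, abs=1e-10)

    def test_charge_neutrality_enforced(self):
        with pytest.raises(ValueError, match="charge"):
            md.WaterForceField(q_O=-0.8, q_H=0.417)


class TestVelocityVerlet:
    def test_harmonic_energy_conservation(self):
        k, m = 10.0, 12.0
        sys_ = md.harmonic_nd(k=k, ndim=1)
        sys_.mass = m
        period_fs = 2 * np.pi * np.sqrt(m / k) * AKMA_TIME_FS
        st = sys_.init_state(300.0, seed=0)
        st.velocities[..., 0] = 0.3
        provider = sys_.force_provider()
        energies = []
        for _ in range(10_000):
            md.velocity_verlet_step(st, provider, period_fs / 100.0)
            _, pe = provider(st.positions)
            energies.append(float(pe + md.kinetic_energy(st)))
        energies = np.asarray(energies)
        drift = (energies.max() - energies.min()) / energies.mean()
        assert drift < 1e-3

    def test_static_state_stays_static(self):
        st = md.MDState(positions=np.zeros((1, 3)), velocities=np.zeros((1, 3)),
                        masses=np.array([1.0]))
        md.velocity_verlet_step(st, lambda x: (np.zeros_like(x), 0.0), 1.0)
        assert np.all(st.positions == 0.0) and np.all(st.velocities == 0.0)

    def test_free_particle_ballistic(self):
        st = md.MDState(positions=np.zeros((1, 3)),
                        velocities=np.array([[0.2, 0.0, 0.0]]),
                        masses=np.array([1.0]))
        for _ in range(10):
            md.velocity_verlet_step(st, lambda x: (np.zeros_like(x), 0.0),
                                    AKMA_TIME_FS)  # dt = 1 internal unit
        assert st.positions[0, 0] == pytest.approx(2.0)

    def test_bias_hook_adds_to_forces(self):
        st = md.MDState(positions=np.zeros((1, 3)), velocities=np.zeros((1, 3)),
                        masses=np.array([1.0]))
        pull = lambda x: np.array([[1.0, 0.0, 0.0]])
        md.velocity_verlet_step(st, lambda x: (np.zeros_like(x), 0.0),
                                AKMA_TIME_FS, extra_force=pull)
        assert st.positions[0, 0] > 0.0

    def test_invalid_timestep(self):
        st = md.MDState(positions=np.zeros((1, 3)), velocities=np.zeros((1, 3)),
                        masses=np.array([1.0]))
        with pytest.raises(ValueError, match="dt"):
            md.velocity_verlet_step(st, lambda x: (np.zeros_like(x), 0.0), 0.0)


class TestThermostats:
    def _mean_kinetic_temperature(self, thermostat, n_steps=60_000, **kw):
        sys_ = md.harmonic_nd(k=5.0, ndim=3)
        st = sys_.init_state(300.0, seed=8, batch_shape=(8,))
        cond = md.SimulationConditions(thermostat=thermostat, timestep_fs=2.0,
                                       n_steps=n_steps, **kw)
        temps = []

        def cb(step, s):
            if step > n_steps // 5 and step % 10 == 0:
                # particle moves in 3 coupled-to-heat-bath dofs
                temps.append(2 * md.kinetic_energy(s) / (3 * KB))
        md.simulate(st, sys_.force_provider(), cond, callback=cb)
        return float(np.mean(temps))

    def test_langevin_canonical_temperature(self):
        T = self._mean_kinetic_temperature("langevin", friction_fs=0.005)
        assert T == pytest.approx(300.0, rel=0.03)

    def test_nose_hoover_canonical_temperature(self):
        T = self._mean_kinetic_temperature("nose_hoover", tau_fs=100.0,
                                           nh_substeps=10)
        assert T == pytest.approx(300.0, rel=0.03)

    def test_velocity_scale_reaches_target(self):
        T = self._mean_kinetic_temperature("velocity_scale", scale_interval=50)
        assert T == pytest.approx(300.0, rel=0.03)

    def test_rescale_noop_when_already_at_target(self):
        st = md.MDState(positions=np.zeros((1, 3)),
                        velocities=np.full((1, 3), np.sqrt(KB * 300.0)),
                        masses=np.array([1.0]))
        cond = md.SimulationConditions(thermostat="velocity_scale",
                                       scale_interval=1)
        v0 = st.velocities.copy()
        md.apply_thermostat(st, cond)
        np.testing.assert_allclose(st.velocities, v0, rtol=1e-12)

    def test_zero_friction_langevin_reduces_to_nve(self):
        sys_ = md.harmonic_nd(k=5.0, ndim=1)
        st1 = sys_.init_state(300.0, seed=9)
        st2 = st1.copy()
        rng = np.random.default_rng(0)
        for _ in range(100):
            md.velocity_verlet_step(st1, sys_.force_provider(), 1.0)
        for _ in range(100):
            md.langevin_baoab_step(st2, sys_.force_provider(), 1.0,
                                   friction_fs=0.0, temperature=300.0, rng=rng)
        np.testing.assert_allclose(st1.positions, st2.positions, atol=1e-10)

    def test_unknown_thermostat_rejected(self):
        with pytest.raises(ValueError, match="thermostat"):
            md.SimulationConditions(thermostat="maxwell_demon")


class TestAnalyticSystems:
    def test_double_well_force_is_minus_gradient(self):
        sys_ = md.double_well_1d(a=2.0)
        provider = sys_.force_provider()
        for x0 in (-1.4, -0.3, 0.7, 1.2):
            x = np.zeros((1, 3)); x[0, 0] = x0
            F, E = provider(x)
            h = 1e-6
            xp = x.copy(); xp[0, 0] += h
            xm = x.copy(); xm[0, 0] -= h
            fd = -(provider(xp)[1] - provider(xm)[1]) / (2 * h)
            assert F[0, 0] == pytest.approx(float(fd), rel=1e-8)
            assert E == pytest.approx(2.0 * (x0 ** 2 - 1) ** 2)

    def test_harmonic_boltzmann_density(self):
        # unbiased sampling reproduces exp(-W/kT) (chi^2 goodness of fit)
        from scipy.stats import chisquare
        k = 2.0
        sys_ = md.harmonic_nd(k=k, ndim=1)
        st = sys_.init_state(300.0, seed=11, batch_shape=(16,))
        cond = md.SimulationConditions(thermostat="langevin", friction_fs=0.02,
                                       timestep_fs=2.0, n_steps=30_000)
        samples = []

        def cb(step, s):
            if step > 2000 and step % 500 == 0:     # decorrelated draws
                samples.extend(s.positions[:, 0, 0].tolist())
        md.simulate(st, sys_.force_provider(), cond, callback=cb)
        samples = np.asarray(samples)
        sigma = np.sqrt(KB * 300.0 / k)
        edges = np.linspace(-2.5 * sigma, 2.5 * sigma, 9)
        obs, _ = np.histogram(samples, bins=edges)
        from scipy.stats import norm
        cdf = norm.cdf(edges, scale=sigma)
        expected = np.diff(cdf) / (cdf[-1] - cdf[0]) * obs.sum()
        _, p = chisquare(obs, expected)
        assert p > 0.01

    def test_nve_dimer_energy_drift(self):
        ff = md.WaterForceField()
        st = md.water_dimer_init(2.9, temperature=300.0, seed=6,
                                 cavity_radius=6.0)
        provider = lambda x: ff(x, cavity_radius=6.0)
        cond = md.SimulationConditions(thermostat="none", timestep_fs=0.5,
                                       n_steps=20_000)
        energies = []

        def cb(step, s):
            if step % 200 == 0:
                energies.append(float(provider(s.positions)[1]
                                      + md.kinetic_energy(s)))
        md.simulate(st, provider, cond, callback=cb)
        energies = np.asarray(energies)
        # symplectic integration: total energy oscillates boundedly; the
        # secular drift (early-block vs late-block mean) must be tiny
        n = len(energies) // 5
        drift = abs(energies[-n:].mean() - energies[:n].mean())
        assert drift / abs(energies.mean()) < 1e-3

    def test_deterministic_trajectories_with_same_seed(self):
        ff = md.WaterForceField()
        outs = []
        for _ in range(2):
            st = md.water_dimer_init(2.9, seed=12, cavity_radius=6.0)
            cond = md.SimulationConditions(thermostat="nose_hoover",
                                           n_steps=500, tau_fs=100.0)
            md.simulate(st, lambda x: ff(x, cavity_radius=6.0), cond,
                        rng=np.random.default_rng(12))
            outs.append(st.positions.copy())
        np.testing.assert_array_equal(outs[0], outs[1])
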