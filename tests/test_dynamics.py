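"""Magnetic velocity-Verlet integrator, constraints, thermostat, run loop."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from magmd import (
    FieldSpec,
    IntegratorConfig,
    Integrator,
    NoseHoover,
    PairParams,
    SystemState,
    Topology,
    build_free_ion,
    build_water_box,
    kinetic_temperature,
    larmor_frequency,
    magnetic_acceleration,
    position_step,
    rattle_positions,
    rattle_velocities,
    run,
    velocity_step,
)
from magmd.builders import SPCE, _thermalize_rigid
from magmd.constants import K_OMEGA


def analytic_free_ion(r0, v0, omega, t):
    """Closed-form helix for dv/dt = Ω S v (oracle, complex arithmetic)."""
    u0 = v0[0] + 1j * v0[1]
    u = u0 * np.exp(-1j * omega * t)
    zeta = (r0[0] + 1j * r0[1]) + u0 * (1 - np.exp(-1j * omega * t)) / (1j * omega)
    pos = np.array([zeta.real, zeta.imag, r0[2] + v0[2] * t])
    vel = np.array([u.real, u.imag, v0[2]])
    return pos, vel


class TestMagneticAcceleration:
    def test_zero_frequency_gives_zero(self):
        assert np.all(magnetic_acceleration(np.array([[1.0, 2, 3]]), 0.0) == 0)

    def test_axial_velocity_feels_no_force(self):
        acc = magnetic_acceleration(np.array([[0.0, 0, 5.0]]), 3.7)
        assert np.all(acc == 0)

    def test_matches_lorentz_cross_product_oracle(self):
        """Ω·S·v must equal (q/m)·v×B evaluated in SI units."""
        q, m, b = 1.0, 22.9898, 8.0e4
        omega = larmor_frequency(q, m, FieldSpec(b))
        v = np.array([[1.0, 2.0, 3.0]])
        got = magnetic_acceleration(v, omega)
        # oracle: a = (q e / m u) * v x (B ez), in nm/ps^2 = 1e-12 * (m/s^2 per nm/ps)
        cross = np.cross(v[0], [0.0, 0.0, b])
        expected = 1.602176634e-19 / (m * 1.66053906660e-27) * cross * 1e-12
        assert np.allclose(got[0], expected, rtol=1e-7)

    def test_explicit_value(self):
        acc = magnetic_acceleration(np.array([[1.0, 2.0, 3.0]]), 0.5)
        assert np.allclose(acc, [[1.0, -0.5, 0.0]], rtol=1e-15)


class TestPositionStep:
    def test_free_drift(self):
        r = position_step(
            np.zeros((1, 3)),
            np.array([[1.0, 2, 3]]),
            np.zeros((1, 3)),
            np.ones(1),
            0.0,
            0.01,
        )
        assert np.allclose(r, [[0.01, 0.02, 0.03]], rtol=1e-15)

    def test_magnetic_term_vanishes_at_rest(self):
        f = np.array([[2.0, 0, 0]])
        r = position_step(
            np.zeros((1, 3)), np.zeros((1, 3)), f, np.full(1, 0.5), 9.0, 0.1
        )
        assert np.allclose(r, [[0.5 * 0.01 * (2.0 * 0.5), 0, 0]], rtol=1e-14)

    def test_single_step_matches_helix_to_third_order(self):
        omega, dt = 0.335749, 1e-4
        v0 = np.array([0.4, 0.0, 0.0])
        r = position_step(
            np.zeros((1, 3)),
            v0[None],
            np.zeros((1, 3)),
            np.ones(1),
            omega,
            dt,
        )
        exact, _ = analytic_free_ion(np.zeros(3), v0, omega, dt)
        assert np.max(np.abs(r[0] - exact)) < abs(omega * dt) ** 3


class TestVelocityStep:
    def test_field_free_limit_is_plain_verlet(self):
        v = np.array([[0.3, -0.2, 0.5]])
        f_old = np.array([[1.0, 2.0, -1.0]])
        f_new = np.array([[-0.5, 1.0, 2.0]])
        out = velocity_step(v, f_old, f_new, np.full(1, 0.25), 0.0, 0.002)
        expected = v + 0.001 * (f_old + f_new) * 0.25
        assert np.array_equal(out, expected)

    def test_reference_value_against_generic_linear_solve(self):
        """h=0.1 example solved independently with numpy.linalg.solve."""
        dt, omega = 0.002, 100.0  # h = 0.1
        v = np.array([[0.4, 0.0, 0.1]])
        out = velocity_step(v, np.zeros((1, 3)), np.zeros((1, 3)), np.ones(1), omega, dt)
        h = 0.5 * dt * omega
        m = np.array([[1.0, -h], [h, 1.0]])
        rhs = np.array([0.4 + h * 0.0, 0.0 - h * 0.4])
        vxy = np.linalg.solve(m, rhs)
        assert np.allclose(out[0, :2], vxy, rtol=1e-14)
        assert np.allclose(out[0], [0.39208, -0.07921, 0.1], atol=5e-6)

    @given(
        h=st.floats(1e-3, 1e3),
        vx=st.floats(-2, 2),
        vy=st.floats(-2, 2),
    )
    def test_cayley_norm_preservation(self, h, vx, vy):
        """With no conservative force, |v_xy| is exactly conserved."""
        dt = 0.001
        omega = 2 * h / dt
        v = np.array([[vx, vy, 0.3]])
        out = velocity_step(v, np.zeros((1, 3)), np.zeros((1, 3)), np.ones(1), omega, dt)
        assert np.hypot(out[0, 0], out[0, 1]) == pytest.approx(
            np.hypot(vx, vy), rel=1e-13, abs=1e-15
        )
        assert out[0, 2] == 0.3


def _water_molecule():
    state, topo = build_water_box(1, seed=0, periodic=False)
    return state, topo


class TestConstraints:
    def test_satisfied_geometry_is_fixed_point(self):
        state, topo = _water_molecule()
        out = rattle_positions(
            state.positions, state.positions, topo, inv_masses=1.0 / state.masses
        )
        assert np.allclose(out, state.positions, atol=1e-12)

    def test_stretched_bond_restored(self):
        state, topo = _water_molecule()
        stretched = state.positions.copy()
        oh = stretched[1] - stretched[0]
        stretched[1] = stretched[0] + 1.01 * oh  # stretch one OH by 1%
        out = rattle_positions(
            stretched, state.positions, topo, tol=1e-8, inv_masses=1.0 / state.masses
        )
        for (i, j), d0 in zip(topo.constraints, topo.constraint_lengths):
            assert np.linalg.norm(out[i] - out[j]) == pytest.approx(d0, abs=1e-8)

    def test_velocity_projection_and_momentum_conservation(self):
        state, topo = _water_molecule()
        rng = np.random.default_rng(1)
        vel = rng.normal(0, 0.5, (3, 3))
        p_before = (state.masses[:, None] * vel).sum(axis=0)
        out = rattle_velocities(
            vel, state.positions, topo, tol=1e-10, inv_masses=1.0 / state.masses
        )
        p_after = (state.masses[:, None] * out).sum(axis=0)
        assert np.allclose(p_before, p_after, atol=1e-12)
        for (i, j), d0 in zip(topo.constraints, topo.constraint_lengths):
            bond = state.positions[i] - state.positions[j]
            rel = (out[i] - out[j]) @ bond / d0
            assert abs(rel) < 1e-10


class TestNoseHoover:
    def test_stationary_at_target_temperature(self):
        """At T = T_target the friction stays 0 and scaling is exp(-xi dt/2)."""
        state, topo = build_water_box(8, seed=4, periodic=False)
        _thermalize_rigid(state, topo, 300.0)
        n_df = 3 * state.n_particles - topo.n_constraints - 3
        nh = NoseHoover(300.0, 0.5, n_df)
        t_now = kinetic_temperature(state, topo.n_constraints, remove_com=True)
        assert t_now == pytest.approx(300.0, rel=1e-9)
        v = nh.half_step(state.velocities, state.masses, 0.001)
        assert nh.xi == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(v, state.velocities, rtol=1e-9)

    def test_nve_ignores_thermostat_settings(self):
        state, topo = build_free_ion("NA+", velocity=(0.4, 0, 0.05))
        params = PairParams(cutoff_nm=np.inf)
        cfg_a = IntegratorConfig(dt_ps=1e-3, n_steps=100, ensemble="NVE")
        cfg_b = IntegratorConfig(
            dt_ps=1e-3, n_steps=100, ensemble="NVE", temperature_K=10.0, tau_t_ps=0.01
        )
        tr_a = run(state, topo, params, cfg_a, FieldSpec(100.0))
        tr_b = run(state, topo, params, cfg_b, FieldSpec(100.0))
        assert np.array_equal(tr_a.positions, tr_b.positions)

    def test_canonical_temperature_control(self, water_cluster_27):
        """Long NVT run: time-averaged kinetic T within 2% of the target."""
        state, topo, params = water_cluster_27
        cfg = IntegratorConfig(
            dt_ps=0.001,
            n_steps=12000,
            ensemble="NVT",
            temperature_K=250.0,
            tau_t_ps=0.5,
            sample_stride=20,
            remove_com=True,
            seed=7,
        )
        traj = run(state, topo, params, cfg)
        temps = traj.energies.temperature_K.to_numpy()
        mean_t = temps[len(temps) // 3 :].mean()
        assert mean_t == pytest.approx(250.0, rel=0.02)


def test_functional_nose_hoover_wrapper_round_trips_friction():
    from magmd.dynamics import nose_hoover_step

    rng = np.random.default_rng(3)
    v = rng.normal(0, 0.4, (10, 3))
    m = np.full(10, 18.0)
    v2, xi = nose_hoover_step(v, m, 0.2, 300.0, 0.5, 0.001, 30)
    # hot system (xi growing): velocities scaled down by exp(-xi dt)
    assert v2 == pytest.approx(v * np.exp(-xi * 0.001))


def test_single_step_wrapper_matches_run(lj_dimer):
    from magmd import step

    state, topo = lj_dimer
    params = PairParams(cutoff_nm=np.inf, lj_shift=False)
    cfg = IntegratorConfig(dt_ps=1e-3, n_steps=1)
    one = step(state, topo, params, cfg, FieldSpec(50.0))
    traj = run(state, topo, params, cfg, FieldSpec(50.0))
    assert np.array_equal(one.positions, traj.positions[-1])
    assert np.array_equal(one.velocities, traj.velocities[-1])


class TestRunLoop:
    def test_zero_steps_returns_initial_frame(self):
        state, topo = build_free_ion("NA+", velocity=(0.1, 0, 0))
        cfg = IntegratorConfig(dt_ps=1e-3, n_steps=0)
        traj = run(state, topo, PairParams(cutoff_nm=np.inf), cfg)
        assert traj.n_frames == 1
        assert np.array_equal(traj.positions[0], state.positions)

    def test_rerun_is_bit_identical(self, lj_dimer):
        state, topo = lj_dimer
        params = PairParams(cutoff_nm=np.inf, lj_shift=False)
        cfg = IntegratorConfig(dt_ps=1e-3, n_steps=500, sample_stride=10)
        t1 = run(state, topo, params, cfg, FieldSpec(25.0))
        t2 = run(state, topo, params, cfg, FieldSpec(25.0))
        assert np.array_equal(t1.positions, t2.positions)
        assert np.array_equal(t1.velocities, t2.velocities)

    def test_nve_energy_conservation_water_cluster(self, water_cluster_27):
        """Total energy drift < 1e-4 relative over 10 ps of constrained NVE."""
        state, topo, params = water_cluster_27
        cfg = IntegratorConfig(
            dt_ps=0.0005, n_steps=20000, ensemble="NVE", sample_stride=200,
            constraint_tol_nm=1e-9,
        )
        traj = run(state, topo, params, cfg)
        e = traj.energies.total_kJmol.to_numpy()
        assert np.max(np.abs(e - e[0])) / abs(e[0]) < 1e-4

    def test_constraints_hold_at_every_sampled_frame(self, water_cluster_27):
        state, topo, params = water_cluster_27
        cfg = IntegratorConfig(
            dt_ps=0.001, n_steps=500, ensemble="NVE", sample_stride=50,
            constraint_tol_nm=1e-8,
        )
        traj = run(state, topo, params, cfg)
        for frame in traj.positions:
            d = np.linalg.norm(
                frame[topo.constraints[:, 0]] - frame[topo.constraints[:, 1]], axis=1
            )
            assert np.max(np.abs(d - topo.constraint_lengths)) < 1e-7

    def test_total_momentum_conserved_without_com_removal(self, water_cluster_27):
        state, topo, params = water_cluster_27
        cfg = IntegratorConfig(
            dt_ps=0.001, n_steps=1000, ensemble="NVE", sample_stride=1000,
            remove_com=False,
        )
        traj = run(state, topo, params, cfg)
        p0 = (state.masses[:, None] * traj.velocities[0]).sum(axis=0)
        p1 = (state.masses[:, None] * traj.velocities[-1]).sum(axis=0)
        assert np.allclose(p0, p1, atol=1e-9)

    def test_free_ion_helix_against_closed_form(self):
        """Simulated gyration matches the analytic helix at small Δt."""
        v0 = (0.4, 0.0, 0.05)
        state, topo = build_free_ion("NA+", velocity=v0)
        omega = K_OMEGA * 1.0 * 8.0e4 / 22.9898
        cfg = IntegratorConfig(dt_ps=1e-4, n_steps=5000, sample_stride=5000)
        traj = run(state, topo, PairParams(cutoff_nm=np.inf), cfg, FieldSpec(8.0e4))
        exact, _ = analytic_free_ion(np.zeros(3), np.array(v0), omega, traj.times[-1])
        assert np.max(np.abs(traj.positions[-1, 0] - exact)) < 1e-6
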