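"""Time integration: velocity Verlet coupled to a homogeneous magnetic field.

The Lorentz force of a static field B = B·ẑ enters through the per-particle
Larmor frequency Ω = K_Ω·q·B/m (rad/ps) and the in-plane skew operator
S·v = (v_y, −v_x, 0), so that the magnetic acceleration is Ω·S·v.

Position update (explicit, magnetic acceleration at the start of the step):

    r(t+Δt) = r(t) + v(t)·Δt + (Δt²/2)·[F(t)/m + Ω·S·v(t)]

Velocity update (trapezoidal in the magnetic acceleration, hence implicit in
the unknown end-of-step velocity):

    (I − hS)·v(t+Δt) = v(t) + (Δt/2)·[F(t) + F(t+Δt)]/m + h·S·v(t),
    h = Ω·Δt/2

The xy block of I − hS is [[1, −h], [h, 1]] with det 1 + h² > 0, inverted in
closed form; the z equation decouples and is the standard Verlet half-kick.
The map (I − hS)⁻¹(I + hS) is a Cayley rotation: with no conservative force
it conserves |v_xy| to machine precision and leaves v_z untouched — the
discrete statement that magnetic forces do no work.

Sub-step order of one full step (documented contract):

    [NVT: Nosé–Hoover half-kick] → position update → SHAKE on positions
    (with the Δr/Δt velocity correction) → force recompute → implicit
    magnetic velocity update → RATTLE on velocities → [NVT: half-kick]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import KB
from .interactions import NeighborList, PairParams, compute_forces
from .model import (
    FieldSpec,
    InvalidParameterError,
    SimulationDiagnosticError,
    SystemState,
    Topology,
    Trajectory,
    kinetic_temperature,
)

MAX_RATTLE_ITER = 500

try:  # optional acceleration for the constraint sweeps
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - environment dependent
    _HAVE_NUMBA = False


class ConstraintFailureError(SimulationDiagnosticError):
    """RATTLE/SHAKE failed to converge for some molecule."""


def _shake_sweeps(pos, ref, invm, ci, cj, d2_target, tol, max_iter):
    """Sequential (Gauss–Seidel) SHAKE sweeps; returns (sweeps, worst)."""
    nc = ci.shape[0]
    for sweep in range(max_iter):
        worst = 0.0
        for k in range(nc):
            i, j = ci[k], cj[k]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            diff = d2 - d2_target[k]
            viol = abs(np.sqrt(d2) - np.sqrt(d2_target[k]))
            if viol > worst:
                worst = viol
            if viol < 0.1 * tol:
                continue
            rx = ref[i, 0] - ref[j, 0]
            ry = ref[i, 1] - ref[j, 1]
            rz = ref[i, 2] - ref[j, 2]
            denom = 2.0 * (invm[i] + invm[j]) * (dx * rx + dy * ry + dz * rz)
            if abs(denom) < 1e-12:
                return -1, viol
            g = diff / denom
            pos[i, 0] -= g * invm[i] * rx
            pos[i, 1] -= g * invm[i] * ry
            pos[i, 2] -= g * invm[i] * rz
            pos[j, 0] += g * invm[j] * rx
            pos[j, 1] += g * invm[j] * ry
            pos[j, 2] += g * invm[j] * rz
        if worst < tol:
            return sweep + 1, worst
    return -1, worst


def _rattle_v_sweeps(vel, pos, invm, ci, cj, d2_target, tol, max_iter):
    """Sequential RATTLE velocity sweeps; returns (sweeps, worst)."""
    nc = ci.shape[0]
    for sweep in range(max_iter):
        worst = 0.0
        for k in range(nc):
            i, j = ci[k], cj[k]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            vx = vel[i, 0] - vel[j, 0]
            vy = vel[i, 1] - vel[j, 1]
            vz = vel[i, 2] - vel[j, 2]
            proj = dx * vx + dy * vy + dz * vz
            viol = abs(proj) / np.sqrt(d2_target[k])
            if viol > worst:
                worst = viol
            if viol < 0.1 * tol:
                continue
            kk = proj / (d2_target[k] * (invm[i] + invm[j]))
            vel[i, 0] -= kk * invm[i] * dx
            vel[i, 1] -= kk * invm[i] * dy
            vel[i, 2] -= kk * invm[i] * dz
            vel[j, 0] += kk * invm[j] * dx
            vel[j, 1] += kk * invm[j] * dy
            vel[j, 2] += kk * invm[j] * dz
        if worst < tol:
            return sweep + 1, worst
    return -1, worst


if _HAVE_NUMBA:
    _shake_sweeps = numba.njit(cache=False)(_shake_sweeps)
    _rattle_v_sweeps = numba.njit(cache=False)(_rattle_v_sweeps)


@dataclass
class IntegratorConfig:
    """Run control for :func:`run`.

    dt_ps : time step Δt in ps
    ensemble : "NVE" or "NVT" (single-chain Nosé–Hoover)
    temperature_K / tau_t_ps : thermostat target and coupling time
    constraint_tol_nm : SHAKE distance tolerance
    sample_stride : emit a frame every this many steps
    remove_com : None resolves to "periodic boxes yes, open boxes no";
        a free ion's drift along ẑ is an observable and must not be removed.
    """

    dt_ps: float = 0.001
    n_steps: int = 1000
    ensemble: str = "NVE"
    temperature_K: float = 300.0
    tau_t_ps: float = 0.5
    constraint_tol_nm: float = 1e-8
    sample_stride: int = 1
    seed: int = 0
    remove_com: bool | None = None
    com_stride: int = 100

    def __post_init__(self):
        if self.dt_ps <= 0:
            raise InvalidParameterError("dt_ps must be positive")
        if self.sample_stride < 1:
            raise InvalidParameterError("sample_stride must be >= 1")
        if self.ensemble not in ("NVE", "NVT"):
            raise InvalidParameterError(f"unknown ensemble {self.ensemble!r}")
        if self.ensemble == "NVT" and self.tau_t_ps <= 0:
            raise InvalidParameterError("tau_t_ps must be positive for NVT")


def magnetic_acceleration(velocities, omega):
    """Magnetic acceleration Ω·S·v = Ω·(v_y, −v_x, 0) in nm/ps².

    ``omega`` is scalar or per-particle (N,); the z component is always 0.
    """
    v = np.atleast_2d(np.asarray(velocities, dtype=float))
    om = np.broadcast_to(np.asarray(omega, dtype=float), v.shape[0])
    acc = np.empty_like(v)
    acc[:, 0] = om * v[:, 1]
    acc[:, 1] = -om * v[:, 0]
    acc[:, 2] = 0.0
    return acc.reshape(np.shape(velocities))


def position_step(positions, velocities, forces, inv_masses, omega, dt):
    """r + v·Δt + (Δt²/2)(F/m + Ω·S·v); raises on non-finite output."""
    acc = forces * inv_masses[:, None] + magnetic_acceleration(velocities, omega)
    new = positions + velocities * dt + (0.5 * dt * dt) * acc
    if not np.all(np.isfinite(new)):
        raise SimulationDiagnosticError("non-finite position after update")
    return new


def velocity_step(velocities, forces_old, forces_new, inv_masses, omega, dt):
    """Solve (I − hS)·v' = v + (Δt/2)(F_old + F_new)/m + h·S·v, h = ΩΔt/2.

    Uses the closed-form xy inverse (I − hS)⁻¹ = [[1, h], [−h, 1]]/(1+h²);
    the z component is the plain trapezoidal half-kick.
    """
    v = velocities
    h = 0.5 * dt * np.broadcast_to(np.asarray(omega, dtype=float), v.shape[0])
    rhs = v + (0.5 * dt) * (forces_old + forces_new) * inv_masses[:, None]
    rhs_x = rhs[:, 0] + h * v[:, 1]
    rhs_y = rhs[:, 1] - h * v[:, 0]
    det = 1.0 + h * h
    out = np.empty_like(v)
    out[:, 0] = (rhs_x + h * rhs_y) / det
    out[:, 1] = (rhs_y - h * rhs_x) / det
    out[:, 2] = rhs[:, 2]
    return out


def rattle_positions(
    positions_proposed,
    positions_reference,
    topo: Topology,
    tol: float = 1e-8,
    max_iter: int = MAX_RATTLE_ITER,
    inv_masses=None,
):
    """SHAKE: project proposed positions onto the constraint manifold.

    Iterative pairwise corrections along the pre-step bond directions
    (Jacobi sweeps); momentum-conserving by construction.  Returns the
    corrected positions; raises :class:`ConstraintFailureError` naming the
    worst molecule on non-convergence.
    """
    if topo.n_constraints == 0:
        return np.array(positions_proposed, dtype=float, copy=True)
    pos = np.array(positions_proposed, dtype=float, copy=True)
    if inv_masses is None:
        inv_masses = np.ones(pos.shape[0])
    ref = np.ascontiguousarray(positions_reference, dtype=float)
    sweeps, worst = _shake_sweeps(
        pos,
        ref,
        np.ascontiguousarray(inv_masses, dtype=float),
        topo.constraints[:, 0],
        topo.constraints[:, 1],
        topo.constraint_lengths**2,
        tol,
        max_iter,
    )
    if sweeps < 0:
        d = pos[topo.constraints[:, 0]] - pos[topo.constraints[:, 1]]
        viol = np.abs(
            np.sqrt(np.einsum("ij,ij->i", d, d)) - topo.constraint_lengths
        )
        k = int(np.argmax(viol))
        raise ConstraintFailureError(
            f"SHAKE failed to converge (molecule "
            f"{int(topo.molecule[topo.constraints[k, 0]])}, constraint "
            f"{int(topo.constraints[k, 0])}-{int(topo.constraints[k, 1])}, "
            f"violation {float(viol[k]):.3e} nm)"
        )
    return pos


def rattle_velocities(
    velocities,
    positions,
    topo: Topology,
    tol: float = 1e-10,
    max_iter: int = MAX_RATTLE_ITER,
    inv_masses=None,
):
    """RATTLE velocity stage: remove relative velocity along constrained bonds.

    After convergence |(v_i − v_j)·r̂_ij| < tol for every constraint; the
    pairwise corrections conserve linear momentum exactly.
    """
    if topo.n_constraints == 0:
        return np.array(velocities, dtype=float, copy=True)
    vel = np.array(velocities, dtype=float, copy=True)
    if inv_masses is None:
        inv_masses = np.ones(vel.shape[0])
    sweeps, _worst = _rattle_v_sweeps(
        vel,
        np.ascontiguousarray(positions, dtype=float),
        np.ascontiguousarray(inv_masses, dtype=float),
        topo.constraints[:, 0],
        topo.constraints[:, 1],
        topo.constraint_lengths**2,
        tol,
        max_iter,
    )
    if sweeps < 0:
        raise ConstraintFailureError(
            f"RATTLE velocity stage failed to converge "
            f"(worst residual {_worst:.3e} nm/ps)"
        )
    return vel


class NoseHoover:
    """Single-chain Nosé–Hoover thermostat.

    Thermostat mass Q = N_df·k_B·T·τ²; the friction ξ obeys
    ξ̇ = (2·KE − N_df·k_B·T)/Q and velocities are scaled by exp(−ξ·δt) in
    half-kicks around the velocity update.  ``eta`` integrates ξ for the
    conserved quantity E + ½Qξ² + N_df·k_B·T·η.
    """

    def __init__(self, temperature_K: float, tau_t_ps: float, n_df: int):
        if tau_t_ps <= 0:
            raise InvalidParameterError("tau_t_ps must be positive")
        if n_df < 1:
            raise InvalidParameterError("n_df must be >= 1")
        self.temperature_K = temperature_K
        self.tau_t_ps = tau_t_ps
        self.n_df = n_df
        self.Q = n_df * KB * temperature_K * tau_t_ps**2
        self.xi = 0.0
        self.eta = 0.0

    def half_step(self, velocities, masses, dt_half: float):
        """Advance ξ by δt with the current KE, then scale velocities."""
        ke = 0.5 * float(np.sum(masses * np.sum(velocities**2, axis=1)))
        self.xi += dt_half * (2.0 * ke - self.n_df * KB * self.temperature_K) / self.Q
        scale = np.exp(-self.xi * dt_half)
        self.eta += self.xi * dt_half
        return velocities * scale

    def energy(self) -> float:
        """Thermostat contribution to the conserved quantity, kJ/mol."""
        return 0.5 * self.Q * self.xi**2 + self.n_df * KB * self.temperature_K * self.eta


def nose_hoover_step(velocities, masses, xi, temperature_K, tau_t_ps, dt, n_df):
    """Functional single half-step wrapper: returns (scaled velocities, ξ')."""
    nh = NoseHoover(temperature_K, tau_t_ps, n_df)
    nh.xi = xi
    v = nh.half_step(np.asarray(velocities, dtype=float), np.asarray(masses), dt)
    return v, nh.xi


class Integrator:
    """Stateful stepper so single steps and full runs share one code path."""

    def __init__(
        self,
        state: SystemState,
        topo: Topology,
        params: PairParams,
        config: IntegratorConfig,
        field: FieldSpec | None = None,
    ):
        field = field if field is not None else FieldSpec(0.0)
        self.state = state.copy()
        self.topo = topo
        self.params = params
        self.config = config
        self.field = field
        self.inv_masses = 1.0 / self.state.masses
        self.omega = np.where(
            self.state.charges != 0.0,
            field.omega(self.state.charges, self.state.masses),
            0.0,
        )
        remove_com = config.remove_com
        if remove_com is None:
            remove_com = self.state.box is not None
        self.remove_com = bool(remove_com)
        self.n_df = (
            3 * self.state.n_particles
            - topo.n_constraints
            - (3 if self.remove_com else 0)
        )
        if self.n_df <= 0:
            raise InvalidParameterError("no degrees of freedom left")
        self.thermostat = (
            NoseHoover(config.temperature_K, config.tau_t_ps, self.n_df)
            if config.ensemble == "NVT"
            else None
        )
        self.nlist = NeighborList(params)
        self.forces, self.potential = compute_forces(
            self.state, topo, params, self.nlist
        )

    def _remove_com_velocity(self):
        m = self.state.masses
        p = m[:, None] * self.state.velocities
        self.state.velocities -= p.sum(axis=0) / m.sum()

    def step(self):
        """Advance the system by one Δt (documented sub-step order)."""
        st = self.state
        cfg = self.config
        dt = cfg.dt_ps
        has_constraints = self.topo.n_constraints > 0
        if self.thermostat is not None:
            st.velocities = self.thermostat.half_step(
                st.velocities, st.masses, 0.5 * dt
            )
        pos_prop = position_step(
            st.positions, st.velocities, self.forces, self.inv_masses, self.omega, dt
        )
        if has_constraints:
            pos_new = rattle_positions(
                pos_prop,
                st.positions,
                self.topo,
                tol=cfg.constraint_tol_nm,
                inv_masses=self.inv_masses,
            )
            st.velocities = st.velocities + (pos_new - pos_prop) / dt
        else:
            pos_new = pos_prop
        st.positions = pos_new
        forces_new, self.potential = compute_forces(
            st, self.topo, self.params, self.nlist
        )
        st.velocities = velocity_step(
            st.velocities, self.forces, forces_new, self.inv_masses, self.omega, dt
        )
        self.forces = forces_new
        if has_constraints:
            st.velocities = rattle_velocities(
                st.velocities,
                st.positions,
                self.topo,
                inv_masses=self.inv_masses,
            )
        if self.thermostat is not None:
            st.velocities = self.thermostat.half_step(
                st.velocities, st.masses, 0.5 * dt
            )
        st.step_index += 1
        st.time += dt
        if self.remove_com and st.step_index % cfg.com_stride == 0:
            self._remove_com_velocity()
        if not (
            np.all(np.isfinite(st.positions)) and np.all(np.isfinite(st.velocities))
        ):
            raise SimulationDiagnosticError(
                f"non-finite state at step {st.step_index} (t={st.time:.6g} ps); "
                f"|r|max={np.nanmax(np.abs(st.positions)):.3e} nm"
            )
        return st

    def sample_energies(self) -> dict:
        st = self.state
        ke = st.kinetic_energy()
        total = ke + self.potential
        conserved = total + (self.thermostat.energy() if self.thermostat else 0.0)
        return {
            "time_ps": st.time,
            "step": st.step_index,
            "kinetic_kJmol": ke,
            "potential_kJmol": self.potential,
            "total_kJmol": total,
            "conserved_kJmol": conserved,
            "temperature_K": kinetic_temperature(
                st, self.topo.n_constraints, self.remove_com
            ),
        }


def step(state, topo, params, config, field=None) -> SystemState:
    """Single-step convenience wrapper (fresh force evaluation each call)."""
    integ = Integrator(state, topo, params, config, field)
    return integ.step().copy()


def run(
    state: SystemState,
    topo: Topology,
    params: PairParams,
    config: IntegratorConfig,
    field: FieldSpec | None = None,
    store_velocities: bool = True,
) -> Trajectory:
    """Propagate ``config.n_steps`` steps; return the sampled Trajectory.

    Frames (and energy-ledger rows) are emitted every ``sample_stride``
    steps starting from the initial state; positions are stored unwrapped.
    Deterministic: identical inputs give bit-identical trajectories.
    """
    integ = Integrator(state, topo, params, config, field)
    times, frames, vels, ledger = [], [], [], []

    def emit():
        times.append(integ.state.time)
        frames.append(integ.state.positions.copy())
        if store_velocities:
            vels.append(integ.state.velocities.copy())
        ledger.append(integ.sample_energies())

    emit()
    for istep in range(1, config.n_steps + 1):
        integ.step()
        if istep % config.sample_stride == 0:
            emit()
    traj = Trajectory(
        times=np.array(times),
        positions=np.array(frames),
        velocities=np.array(vels) if store_velocities else None,
        box=None if integ.state.box is None else integ.state.box.copy(),
        energies=pd.DataFrame(ledger),
    )
    return traj


def minimize(
    state: SystemState,
    topo: Topology,
    params: PairParams,
    max_steps: int = 200,
    initial_step_nm: float = 0.01,
    force_tol: float = 100.0,
    constraint_tol_nm: float = 1e-6,
) -> SystemState:
    """Constrained steepest-descent relaxation (start-up utility).

    Moves along the force with an adaptive displacement cap and re-projects
    onto the constraint manifold after every move; used to relieve bad
    contacts in freshly built boxes before dynamics.  Velocities untouched.
    """
    st = state.copy()
    nlist = NeighborList(params)
    inv_m = 1.0 / st.masses
    forces, energy = compute_forces(st, topo, params, nlist)
    h = initial_step_nm
    for _ in range(max_steps):
        fmax = float(np.max(np.linalg.norm(forces, axis=1)))
        if fmax < force_tol:
            break
        trial = st.positions + forces * (h / fmax)
        if topo.n_constraints:
            trial = rattle_positions(
                trial, st.positions, topo, tol=constraint_tol_nm, inv_masses=inv_m
            )
        trial_state = st.copy()
        trial_state.positions = trial
        try:
            f_new, e_new = compute_forces(trial_state, topo, params, nlist)
        except Exception:
            e_new = np.inf
        if e_new < energy:
            st.positions = trial
            forces, energy = f_new, e_new
            h = min(h * 1.2, 0.02)
        else:
            h *= 0.5
            if h < 1e-6:
                break
    return st
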