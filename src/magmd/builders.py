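"""Programmatic system construction: free ions, SPC/E water boxes, and
synthetic analysis fixtures (exact helices, Brownian walks).

Everything is generated in memory from physical parameters — no structure
downloads.  All builders are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KB, NM2_PER_PS_TO_M2_PER_S
from .model import (
    InvalidParameterError,
    SystemState,
    Topology,
    Trajectory,
    kinetic_temperature,
)

# conversion: u → kg and nm³ → m³ for density arithmetic
_U_TO_KG = 1.66053906660e-27

#: Standard atomic masses (u) and integer charges (e) for the built-in ions.
ION_SPECIES = {
    "NA+": (22.9898, +1.0),
    "CL-": (35.453, -1.0),
}


@dataclass(frozen=True)
class SpceWaterModel:
    """Rigid three-site SPC/E water.

    LJ only on oxygen; point charges on all sites; rigidity realized as
    three distance constraints (two O–H plus the H–H distance closing the
    109.47° angle).
    """

    sigma_O: float = 0.3166  # nm
    epsilon_O: float = 0.650  # kJ/mol
    q_O: float = -0.8476  # e
    q_H: float = +0.4238  # e
    r_OH: float = 0.1  # nm
    angle_HOH_deg: float = 109.47
    mass_O: float = 15.9994  # u
    mass_H: float = 1.008  # u

    @property
    def r_HH(self) -> float:
        return 2.0 * self.r_OH * np.sin(np.deg2rad(self.angle_HOH_deg) / 2.0)

    @property
    def molecular_mass(self) -> float:
        return self.mass_O + 2.0 * self.mass_H

    def site_coordinates(self) -> np.ndarray:
        """O at the origin, H's in the xy plane (molecule frame), nm."""
        half = np.deg2rad(self.angle_HOH_deg) / 2.0
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [self.r_OH * np.cos(half), self.r_OH * np.sin(half), 0.0],
                [self.r_OH * np.cos(half), -self.r_OH * np.sin(half), 0.0],
            ]
        )


SPCE = SpceWaterModel()


def maxwell_boltzmann_velocities(masses, temperature_K, rng) -> np.ndarray:
    """Velocity draw (nm/ps): per-component variance k_B·T/m."""
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * temperature_K / masses)
    return rng.standard_normal((masses.shape[0], 3)) * sigma[:, None]


def build_free_ion(
    species: str = "NA+",
    mass: float | None = None,
    charge: float | None = None,
    velocity=None,
    temperature_K: float | None = None,
    seed: int = 0,
    position=(0.0, 0.0, 0.0),
):
    """Single ion in an open (non-periodic) box with no interactions.

    The initial velocity is either given explicitly (nm/ps) or drawn from a
    Maxwell–Boltzmann distribution at ``temperature_K`` with the given seed.
    Unknown species require explicit (mass, charge).
    """
    key = species.upper().replace("−", "-")
    if mass is None or charge is None:
        if key not in ION_SPECIES:
            raise InvalidParameterError(
                f"unknown species {species!r}: provide mass and charge"
            )
        mass, charge = ION_SPECIES[key]
    if velocity is None:
        if temperature_K is None:
            raise InvalidParameterError(
                "give an explicit velocity or a temperature for a thermal draw"
            )
        rng = np.random.default_rng(seed)
        velocity = maxwell_boltzmann_velocities(
            np.array([mass]), temperature_K, rng
        )[0]
    state = SystemState(
        positions=np.array([position], dtype=float),
        velocities=np.array([velocity], dtype=float).reshape(1, 3),
        masses=np.array([mass]),
        charges=np.array([charge]),
        box=None,
    )
    return state, Topology.free_particles(1)


def water_box_edge(n_molecules: int, density_kg_m3: float = 997.0) -> float:
    """Cubic box edge (nm) holding n SPC/E molecules at the given density."""
    mass_kg = n_molecules * SPCE.molecular_mass * _U_TO_KG
    volume_m3 = mass_kg / density_kg_m3
    return float(volume_m3 ** (1.0 / 3.0) * 1e9)


def build_water_box(
    n_molecules: int,
    density_kg_m3: float = 997.0,
    temperature_K: float = 300.0,
    seed: int = 0,
    min_OO_nm: float = 0.24,
    periodic: bool = True,
):
    """SPC/E water box: cubic sub-lattice of molecules, random orientations.

    ``periodic=False`` yields the same geometry in an open box (a droplet /
    cluster), useful for cutoff-free NVE checks.

    Molecules sit at the centers of a cubic grid (so the minimum O–O
    distance is the lattice spacing), each rotated by an independent random
    rotation; velocities are Maxwell–Boltzmann at ``temperature_K`` with
    net momentum removed, constraint-incompatible components projected out,
    and rescaled so the initial kinetic temperature matches the request.
    """
    if n_molecules < 1:
        raise InvalidParameterError("n_molecules must be positive")
    edge = water_box_edge(n_molecules, density_kg_m3)
    cells = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = edge / cells
    if spacing < min_OO_nm:
        raise InvalidParameterError(
            f"density {density_kg_m3} kg/m³ packs O–O closer than "
            f"{min_OO_nm} nm (spacing {spacing:.3f} nm)"
        )
    rng = np.random.default_rng(seed)
    site_local = SPCE.site_coordinates()
    rotations = Rotation.random(n_molecules, random_state=rng)
    idx = np.arange(cells**3)
    rng.shuffle(idx)
    chosen = np.sort(idx[:n_molecules])
    grid = np.stack(
        [(chosen // cells**2), (chosen // cells) % cells, chosen % cells], axis=1
    )
    centers = (grid + 0.5) * spacing
    positions = np.empty((3 * n_molecules, 3))
    for k in range(n_molecules):
        positions[3 * k : 3 * k + 3] = centers[k] + rotations[k].apply(site_local)

    masses = np.tile([SPCE.mass_O, SPCE.mass_H, SPCE.mass_H], n_molecules)
    charges = np.tile([SPCE.q_O, SPCE.q_H, SPCE.q_H], n_molecules)
    sigma = np.tile([SPCE.sigma_O, 0.0, 0.0], n_molecules)
    epsilon = np.tile([SPCE.epsilon_O, 0.0, 0.0], n_molecules)
    mol = np.repeat(np.arange(n_molecules, dtype=np.int64), 3)

    base = 3 * np.arange(n_molecules, dtype=np.int64)
    o, h1, h2 = base, base + 1, base + 2
    exclusions = np.concatenate(
        [
            np.stack([o, h1], axis=1),
            np.stack([o, h2], axis=1),
            np.stack([h1, h2], axis=1),
        ]
    )
    constraints = exclusions.copy()
    lengths = np.concatenate(
        [
            np.full(n_molecules, SPCE.r_OH),
            np.full(n_molecules, SPCE.r_OH),
            np.full(n_molecules, SPCE.r_HH),
        ]
    )
    # reorder so each molecule's constraints are contiguous (cosmetic)
    topo = Topology(
        molecule=mol,
        exclusions=exclusions,
        constraints=constraints,
        constraint_lengths=lengths,
        sigma=sigma,
        epsilon=epsilon,
    )
    velocities = maxwell_boltzmann_velocities(masses, temperature_K, rng)
    state = SystemState(
        positions=positions,
        velocities=velocities,
        masses=masses,
        charges=charges,
        box=np.full(3, edge) if periodic else None,
    )
    _thermalize_rigid(state, topo, temperature_K)
    return state, topo


def _thermalize_rigid(state: SystemState, topo: Topology, temperature_K: float):
    """Remove COM drift and bond-stretching velocity, then rescale to T."""
    from .dynamics import rattle_velocities  # local import avoids a cycle

    m = state.masses
    state.velocities -= (m[:, None] * state.velocities).sum(axis=0) / m.sum()
    if topo.n_constraints:
        state.velocities = rattle_velocities(
            state.velocities, state.positions, topo, inv_masses=1.0 / m
        )
    t_now = kinetic_temperature(state, topo.n_constraints, remove_com=True)
    if t_now > 0:
        state.velocities *= np.sqrt(temperature_K / t_now)


def equilibrated_water_box(
    n_molecules: int,
    temperature_K: float = 300.0,
    seed: int = 0,
    params=None,
    equil_ps: float = 10.0,
    dt_equil_ps: float = 0.001,
):
    """Build, relax and NVT-equilibrate an SPC/E box ready for production.

    Steepest-descent relaxation removes the lattice artifacts of
    :func:`build_water_box`, then a short Nosé–Hoover run with tight
    coupling (τ = 0.2 ps) brings the box to the target temperature.
    Returns (state, topology).
    """
    from .dynamics import IntegratorConfig, minimize, run
    from .interactions import PairParams

    if params is None:
        params = PairParams()
    state, topo = build_water_box(n_molecules, temperature_K=temperature_K, seed=seed)
    state = minimize(state, topo, params, max_steps=300, force_tol=500.0)
    _thermalize_rigid(state, topo, temperature_K)
    cfg = IntegratorConfig(
        dt_ps=dt_equil_ps,
        n_steps=int(round(equil_ps / dt_equil_ps)),
        ensemble="NVT",
        temperature_K=temperature_K,
        tau_t_ps=0.2,
        sample_stride=max(int(round(equil_ps / dt_equil_ps)) // 10, 1),
        seed=seed,
    )
    traj = run(state, topo, params, cfg, store_velocities=True)
    out = state.copy()
    out.positions = traj.positions[-1]
    out.velocities = traj.velocities[-1]
    out.time = 0.0
    out.step_index = 0
    return out, topo


def make_helix_fixture(
    radius: float,
    omega: float,
    v_z: float,
    dt_sample: float,
    n_frames: int,
    phase: float = 0.0,
    center=(0.0, 0.0, 0.0),
) -> Trajectory:
    """Exact analytic helix with consistent velocities (analysis oracle).

    x = x₀ + r·cos(Ωt+φ), y = y₀ + r·sin(Ωt+φ), z = z₀ + v_z·t, so the
    signed angular rate of the xy motion is exactly Ω (positive =
    counter-clockwise seen from +z).
    """
    if radius < 0:
        raise InvalidParameterError("radius must be nonnegative")
    t = np.arange(n_frames) * dt_sample
    ang = omega * t + phase
    x0, y0, z0 = center
    pos = np.empty((n_frames, 1, 3))
    pos[:, 0, 0] = x0 + radius * np.cos(ang)
    pos[:, 0, 1] = y0 + radius * np.sin(ang)
    pos[:, 0, 2] = z0 + v_z * t
    vel = np.empty_like(pos)
    vel[:, 0, 0] = -radius * omega * np.sin(ang)
    vel[:, 0, 1] = radius * omega * np.cos(ang)
    vel[:, 0, 2] = v_z
    return Trajectory(times=t, positions=pos, velocities=vel, box=None)


def make_brownian_fixture(
    D_m2_s: float,
    dt_sample: float,
    n_frames: int,
    n_particles: int,
    seed: int = 0,
) -> Trajectory:
    """Ideal Brownian walk of known diffusion coefficient (analysis oracle).

    Independent Gaussian increments with per-axis variance 2·D·Δt;
    coordinates are unwrapped (no box).
    """
    if D_m2_s <= 0:
        raise InvalidParameterError("D must be positive")
    d_nm2_ps = D_m2_s / NM2_PER_PS_TO_M2_PER_S
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_frames - 1, n_particles, 3)) * np.sqrt(
        2.0 * d_nm2_ps * dt_sample
    )
    pos = np.concatenate(
        [np.zeros((1, n_particles, 3)), np.cumsum(steps, axis=0)], axis=0
    )
    return Trajectory(
        times=np.arange(n_frames) * dt_sample, positions=pos, box=None
    )
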