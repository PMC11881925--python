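"""Core domain types: field, system state, topology, trajectory.

All quantities live in the internal unit system declared in
:mod:`magmd.constants` (nm, ps, u, e, kJ/mol); magnetic flux density is
tesla everywhere it appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import K_OMEGA, KB


class InvalidParameterError(ValueError):
    """A physical parameter violates its contract (e.g. nonpositive mass)."""


class SimulationDiagnosticError(RuntimeError):
    """A run aborted with diagnostic context (NaN/Inf, constraint failure...)."""


@dataclass(frozen=True)
class FieldSpec:
    """Homogeneous, static magnetic field along the +z axis.

    ``B_tesla`` may carry a sign: positive means the field points along +z.
    """

    B_tesla: float = 0.0

    @property
    def axis(self) -> np.ndarray:
        return np.array([0.0, 0.0, 1.0])

    def omega(self, q, m):
        """Per-particle Larmor frequency, rad/ps (vectorized over q, m)."""
        return larmor_frequency(q, m, self)


def larmor_frequency(q, m, field: FieldSpec):
    """Angular (Larmor/cyclotron) frequency Ω = K_Ω·q·B/m in rad/ps.

    Parameters
    ----------
    q : charge in e (scalar or array)
    m : mass in u, strictly positive (scalar or array)
    field : FieldSpec with B in tesla

    The sign of the result follows sign(q·B); neutral particles get 0.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise InvalidParameterError("mass must be strictly positive")
    return K_OMEGA * np.asarray(q, dtype=float) * field.B_tesla / m


@dataclass
class SystemState:
    """Instantaneous phase-space state of the simulated system.

    positions/velocities are (N, 3) in nm and nm/ps; ``box`` is either the
    three orthorhombic edge lengths in nm or ``None`` for an open
    (non-periodic) system such as a free ion.
    """

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0
    step_index: int = 0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        self.charges = np.asarray(self.charges, dtype=float).reshape(-1)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.validate()

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise InvalidParameterError("positions/velocities must be (N, 3)")
        if self.masses.shape != (n,) or self.charges.shape != (n,):
            raise InvalidParameterError("masses/charges must have length N")
        if np.any(self.masses <= 0):
            raise InvalidParameterError("masses must be strictly positive")
        if self.box is not None and np.any(self.box <= 0):
            raise InvalidParameterError("box edges must be strictly positive")
        if not np.all(np.isfinite(self.positions)):
            raise SimulationDiagnosticError(
                f"non-finite position at step {self.step_index}, "
                f"t={self.time:g} ps"
            )
        if not np.all(np.isfinite(self.velocities)):
            raise SimulationDiagnosticError(
                f"non-finite velocity at step {self.step_index}, "
                f"t={self.time:g} ps"
            )

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            box=None if self.box is None else self.box.copy(),
            time=self.time,
            step_index=self.step_index,
        )

    def kinetic_energy(self) -> float:
        """Total kinetic energy, kJ/mol (u·nm²/ps² = kJ/mol exactly)."""
        return 0.5 * float(np.sum(self.masses * np.sum(self.velocities**2, axis=1)))

    def wrapped_positions(self) -> np.ndarray:
        """Positions wrapped into [0, box) per axis; identity for open boxes."""
        if self.box is None:
            return self.positions.copy()
        return self.positions - np.floor(self.positions / self.box) * self.box


def kinetic_temperature(
    state: SystemState, n_constraints: int = 0, remove_com: bool = False
) -> float:
    """Instantaneous kinetic temperature in kelvin.

    T = 2·KE / (N_df·k_B) with N_df = 3N − n_constraints − (3 if remove_com).
    """
    n_df = 3 * state.n_particles - n_constraints - (3 if remove_com else 0)
    if n_df <= 0:
        raise InvalidParameterError(f"nonpositive degrees of freedom: {n_df}")
    return 2.0 * state.kinetic_energy() / (n_df * KB)


@dataclass
class Topology:
    """Connectivity and nonbonded parameters.

    molecule : (N,) integer molecule membership per particle
    exclusions : (M, 2) intramolecular pairs excluded from nonbonded forces
    constraints : (C, 2) particle pairs held at fixed distance
    constraint_lengths : (C,) target distances in nm
    sigma, epsilon : (N,) per-particle Lennard-Jones parameters (nm, kJ/mol);
        cross terms use Lorentz–Berthelot mixing.
    """

    molecule: np.ndarray
    exclusions: np.ndarray = dc_field(
        default_factory=lambda: np.zeros((0, 2), dtype=np.int64)
    )
    constraints: np.ndarray = dc_field(
        default_factory=lambda: np.zeros((0, 2), dtype=np.int64)
    )
    constraint_lengths: np.ndarray = dc_field(
        default_factory=lambda: np.zeros(0, dtype=float)
    )
    sigma: np.ndarray | None = None
    epsilon: np.ndarray | None = None

    def __post_init__(self):
        self.molecule = np.asarray(self.molecule, dtype=np.int64).reshape(-1)
        n = self.molecule.shape[0]
        self.exclusions = np.asarray(self.exclusions, dtype=np.int64).reshape(-1, 2)
        self.constraints = np.asarray(self.constraints, dtype=np.int64).reshape(-1, 2)
        self.constraint_lengths = np.asarray(
            self.constraint_lengths, dtype=float
        ).reshape(-1)
        if self.sigma is None:
            self.sigma = np.zeros(n)
        if self.epsilon is None:
            self.epsilon = np.zeros(n)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(-1)
        self.epsilon = np.asarray(self.epsilon, dtype=float).reshape(-1)
        self.validate()

    @property
    def n_particles(self) -> int:
        return self.molecule.shape[0]

    @property
    def n_constraints(self) -> int:
        return self.constraints.shape[0]

    def validate(self) -> None:
        if np.any(self.sigma < 0) or np.any(self.epsilon < 0):
            raise InvalidParameterError("LJ sigma/epsilon must be nonnegative")
        if self.constraints.shape[0] != self.constraint_lengths.shape[0]:
            raise InvalidParameterError("constraint list/length mismatch")
        if np.any(self.constraint_lengths <= 0):
            raise InvalidParameterError("constraint distances must be positive")
        # every constrained pair must also be a nonbonded exclusion
        excl = self._pair_keys(self.exclusions)
        cons = self._pair_keys(self.constraints)
        if not np.all(np.isin(cons, excl)):
            raise InvalidParameterError(
                "every constrained pair must appear in the exclusion list"
            )

    def _pair_keys(self, pairs: np.ndarray) -> np.ndarray:
        if pairs.size == 0:
            return np.zeros(0, dtype=np.int64)
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        return lo * np.int64(self.n_particles) + hi

    def exclusion_keys(self) -> np.ndarray:
        """Sorted canonical (i<j) keys of excluded pairs, for fast filtering."""
        return np.sort(self._pair_keys(self.exclusions))

    @classmethod
    def free_particles(cls, n: int) -> "Topology":
        """A topology of n independent particles with no interactions."""
        return cls(molecule=np.arange(n, dtype=np.int64))


@dataclass
class Trajectory:
    """Time-ordered frames with an energy ledger.

    Positions are stored unwrapped (continuous across box faces) so that
    displacement-based observables (MSD) are meaningful; wrapped coordinates
    are derived on demand.
    """

    times: np.ndarray
    positions: np.ndarray  # (F, N, 3), unwrapped nm
    velocities: np.ndarray | None = None  # (F, N, 3) nm/ps
    box: np.ndarray | None = None
    energies: pd.DataFrame | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.times.ndim != 1 or self.positions.shape[0] != self.times.shape[0]:
            raise InvalidParameterError("one time stamp per frame required")
        if self.n_frames > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise InvalidParameterError("frame times must strictly increase")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise InvalidParameterError("frame spacing must be constant")

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt_sample(self) -> float:
        if self.n_frames < 2:
            raise InvalidParameterError("need at least two frames for a spacing")
        return float(self.times[1] - self.times[0])

    def wrapped_positions(self) -> np.ndarray:
        if self.box is None:
            return self.positions.copy()
        return self.positions - np.floor(self.positions / self.box) * self.box
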