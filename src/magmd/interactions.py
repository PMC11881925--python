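"""Nonbonded interactions: Lennard-Jones + reaction-field Coulomb.

Pair interactions use Lorentz–Berthelot mixing, a shared cutoff r_c, the
minimum-image convention for orthorhombic periodic boxes, and a Verlet
neighbor list with a displacement-triggered rebuild.  The LJ potential is
shifted so U(r_c) = 0 (forces from the unshifted form); electrostatics use
the reaction-field form, which is zero at the cutoff by construction.

The hot pair loop is numba-jitted when numba is importable; an equivalent
vectorized numpy path is used otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import F_ELEC
from .model import InvalidParameterError, SystemState, Topology

try:  # optional acceleration
    import numba

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - environment dependent
    HAVE_NUMBA = False


class SingularityError(RuntimeError):
    """Two interacting particles are (near-)coincident."""


@dataclass
class PairParams:
    """Nonbonded scheme parameters.

    cutoff_nm : shared LJ/Coulomb cutoff r_c (ignored for open boxes when
        set to ``inf``); must not exceed half the smallest box edge.
    epsilon_rf : reaction-field dielectric (78.5 ~ water at 300 K).
    lj_shift : shift LJ energy so U(r_c) = 0 (recommended for NVE work).
    skin_nm : Verlet-list skin; pairs within r_c + skin are kept.
    """

    cutoff_nm: float = 0.9
    epsilon_rf: float = 78.5
    lj_shift: bool = True
    skin_nm: float = 0.1

    def validate_for_box(self, box: np.ndarray | None) -> None:
        if self.cutoff_nm <= 0:
            raise InvalidParameterError("cutoff must be positive")
        if box is not None and self.cutoff_nm > 0.5 * float(np.min(box)) + 1e-12:
            raise InvalidParameterError(
                f"cutoff {self.cutoff_nm} nm exceeds half the smallest box "
                f"edge ({0.5 * float(np.min(box)):.4f} nm)"
            )

    @property
    def k_rf(self) -> float:
        if not np.isfinite(self.cutoff_nm):
            return 0.0  # infinite cutoff: plain Coulomb
        return (self.epsilon_rf - 1.0) / (
            (2.0 * self.epsilon_rf + 1.0) * self.cutoff_nm**3
        )

    @property
    def c_rf(self) -> float:
        if not np.isfinite(self.cutoff_nm):
            return 0.0
        return 1.0 / self.cutoff_nm + self.k_rf * self.cutoff_nm**2


def lj_pair(r, sigma, epsilon, cutoff=None, shift=False):
    """Lennard-Jones energy (kJ/mol) and scalar force (kJ/mol/nm) at r.

    U = 4ε[(σ/r)¹² − (σ/r)⁶], optionally shifted by −U(r_c); the force
    magnitude −dU/dr is always that of the unshifted form (positive =
    repulsive).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise SingularityError("lj_pair evaluated at r <= 0")
    sr6 = (sigma / r) ** 6
    u = 4.0 * epsilon * (sr6**2 - sr6)
    f = 24.0 * epsilon * (2.0 * sr6**2 - sr6) / r
    if shift:
        if cutoff is None:
            raise InvalidParameterError("shift requires a cutoff")
        src6 = (sigma / cutoff) ** 6
        u = u - 4.0 * epsilon * (src6**2 - src6)
    return u, f


def coulomb_pair_rf(r, q_i, q_j, cutoff, epsilon_rf):
    """Reaction-field Coulomb energy and scalar force for one pair.

    U = f_elec·q_i·q_j·(1/r + k_rf·r² − c_rf), which vanishes at r = r_c.
    Pairs beyond the cutoff must be filtered upstream.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise SingularityError("coulomb_pair_rf evaluated at r <= 0")
    if np.any(r > cutoff * (1 + 1e-12)):
        raise InvalidParameterError("coulomb_pair_rf called beyond the cutoff")
    k_rf = (epsilon_rf - 1.0) / ((2.0 * epsilon_rf + 1.0) * cutoff**3)
    c_rf = 1.0 / cutoff + k_rf * cutoff**2
    qq = F_ELEC * q_i * q_j
    u = qq * (1.0 / r + k_rf * r**2 - c_rf)
    f = qq * (1.0 / r**2 - 2.0 * k_rf * r)
    return u, f


def _build_pairs_loop(pos, box, periodic, rlist2, excl_keys):
    """Count-then-fill all-pairs scan (numba-jitted when available)."""
    n = pos.shape[0]
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if periodic:
                dx -= box[0] * np.floor(dx / box[0] + 0.5)
                dy -= box[1] * np.floor(dy / box[1] + 0.5)
                dz -= box[2] * np.floor(dz / box[2] + 0.5)
            if dx * dx + dy * dy + dz * dz < rlist2:
                key = i * n + j
                lo = np.searchsorted(excl_keys, key)
                if lo < excl_keys.shape[0] and excl_keys[lo] == key:
                    continue
                count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if periodic:
                dx -= box[0] * np.floor(dx / box[0] + 0.5)
                dy -= box[1] * np.floor(dy / box[1] + 0.5)
                dz -= box[2] * np.floor(dz / box[2] + 0.5)
            if dx * dx + dy * dy + dz * dz < rlist2:
                key = i * n + j
                lo = np.searchsorted(excl_keys, key)
                if lo < excl_keys.shape[0] and excl_keys[lo] == key:
                    continue
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


if HAVE_NUMBA:
    _build_pairs_jit = numba.njit(cache=False)(_build_pairs_loop)
else:  # pragma: no cover - environment dependent
    _build_pairs_jit = None


class NeighborList:
    """Verlet pair list: all non-excluded pairs within r_c + skin.

    Built by a vectorized all-pairs distance scan (adequate at the system
    sizes this engine targets) and rebuilt whenever any particle has moved
    more than half the skin since the last build.
    """

    def __init__(self, params: PairParams):
        self.params = params
        self.pairs_i = np.zeros(0, dtype=np.int64)
        self.pairs_j = np.zeros(0, dtype=np.int64)
        self._ref_positions: np.ndarray | None = None

    def build(self, state: SystemState, topo: Topology) -> None:
        pos = state.positions
        n = pos.shape[0]
        self._ref_positions = pos.copy()
        if n < 2:
            self.pairs_i = np.zeros(0, dtype=np.int64)
            self.pairs_j = np.zeros(0, dtype=np.int64)
            return
        rlist = self.params.cutoff_nm + self.params.skin_nm
        periodic = state.box is not None
        box = state.box if periodic else np.ones(3)
        excl = topo.exclusion_keys()
        if _build_pairs_jit is not None:
            self.pairs_i, self.pairs_j = _build_pairs_jit(
                pos, box, periodic, min(rlist * rlist, 1e30), excl
            )
            return
        iu, ju = np.triu_indices(n, k=1)
        dr = pos[iu] - pos[ju]
        if periodic:
            dr -= box * np.floor(dr / box + 0.5)
        r2 = np.einsum("ij,ij->i", dr, dr)
        mask = r2 < rlist * rlist
        iu, ju = iu[mask], ju[mask]
        if excl.size:
            keys = iu.astype(np.int64) * np.int64(n) + ju
            keep = ~np.isin(keys, excl, assume_unique=False)
            iu, ju = iu[keep], ju[keep]
        self.pairs_i = iu.astype(np.int64)
        self.pairs_j = ju.astype(np.int64)

    def needs_rebuild(self, positions: np.ndarray) -> bool:
        if self._ref_positions is None:
            return True
        disp2 = np.max(
            np.sum((positions - self._ref_positions) ** 2, axis=1), initial=0.0
        )
        return disp2 > (0.5 * self.params.skin_nm) ** 2

    @property
    def n_pairs(self) -> int:
        return self.pairs_i.shape[0]


def _pair_loop_python(
    pos, box, periodic, pi, pj, sigma, eps, charge, rc, krf, crf, lj_shift, forces
):
    """Reference pair loop (numba-jitted when available)."""
    energy = 0.0
    rc2 = rc * rc
    for k in range(pi.shape[0]):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic:
            dx -= box[0] * np.floor(dx / box[0] + 0.5)
            dy -= box[1] * np.floor(dy / box[1] + 0.5)
            dz -= box[2] * np.floor(dz / box[2] + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        if r2 < 1e-12:  # r < 1e-6 nm
            return np.nan  # signals singularity; caller raises with indices
        e_ij = np.sqrt(eps[i] * eps[j])
        fscal = 0.0
        if e_ij > 0.0:
            s_ij = 0.5 * (sigma[i] + sigma[j])
            sr2 = s_ij * s_ij / r2
            sr6 = sr2 * sr2 * sr2
            energy += 4.0 * e_ij * (sr6 * sr6 - sr6)
            if lj_shift:
                src2 = s_ij * s_ij / rc2
                src6 = src2 * src2 * src2
                energy -= 4.0 * e_ij * (src6 * src6 - src6)
            fscal += 24.0 * e_ij * (2.0 * sr6 * sr6 - sr6) / r2
        qq = charge[i] * charge[j]
        if qq != 0.0:
            qq *= 138.935458
            rinv = 1.0 / np.sqrt(r2)
            energy += qq * (rinv + krf * r2 - crf)
            fscal += qq * (rinv / r2 - 2.0 * krf)
        if fscal != 0.0:
            fx = fscal * dx
            fy = fscal * dy
            fz = fscal * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
    return energy


if HAVE_NUMBA:
    _pair_loop_jit = numba.njit(cache=False, fastmath=False)(_pair_loop_python)
else:  # pragma: no cover - environment dependent
    _pair_loop_jit = None


def _pair_loop_numpy(
    pos, box, periodic, pi, pj, sigma, eps, charge, rc, krf, crf, lj_shift, forces
):
    """Vectorized equivalent of :func:`_pair_loop_python`."""
    if pi.shape[0] == 0:
        return 0.0
    dr = pos[pi] - pos[pj]
    if periodic:
        dr -= box * np.floor(dr / box + 0.5)
    r2 = np.einsum("ij,ij->i", dr, dr)
    within = r2 < rc * rc
    if not np.any(within):
        return 0.0
    pi, pj, dr, r2 = pi[within], pj[within], dr[within], r2[within]
    if np.any(r2 < 1e-12):
        return np.nan
    e_ij = np.sqrt(eps[pi] * eps[pj])
    s_ij = 0.5 * (sigma[pi] + sigma[pj])
    energy = 0.0
    fscal = np.zeros(r2.shape[0])
    lj = e_ij > 0
    if np.any(lj):
        sr6 = (s_ij[lj] ** 2 / r2[lj]) ** 3
        u_lj = 4.0 * e_ij[lj] * (sr6**2 - sr6)
        if lj_shift:
            src6 = (s_ij[lj] / rc) ** 6
            u_lj = u_lj - 4.0 * e_ij[lj] * (src6**2 - src6)
        energy += float(np.sum(u_lj))
        fscal[lj] += 24.0 * e_ij[lj] * (2.0 * sr6**2 - sr6) / r2[lj]
    qq = F_ELEC * charge[pi] * charge[pj]
    coul = qq != 0
    if np.any(coul):
        rinv = 1.0 / np.sqrt(r2[coul])
        energy += float(np.sum(qq[coul] * (rinv + krf * r2[coul] - crf)))
        fscal[coul] += qq[coul] * (rinv / r2[coul] - 2.0 * krf)
    fvec = fscal[:, None] * dr
    np.add.at(forces, pi, fvec)
    np.add.at(forces, pj, -fvec)
    return energy


def compute_forces(
    state: SystemState,
    topo: Topology,
    params: PairParams,
    nlist: NeighborList | None = None,
):
    """Total nonbonded force (N, 3) and potential energy of the system.

    Maintains (or accepts) a neighbor list; excluded pairs contribute
    nothing.  Raises :class:`SingularityError` when two interacting
    particles are closer than 1e-6 nm.
    """
    n = state.n_particles
    forces = np.zeros((n, 3))
    if n < 2:
        return forces, 0.0
    if nlist is None:
        nlist = NeighborList(params)
        nlist.build(state, topo)
    elif nlist.needs_rebuild(state.positions):
        nlist.build(state, topo)
    params.validate_for_box(state.box)
    periodic = state.box is not None
    box = state.box if periodic else np.ones(3)
    loop = _pair_loop_jit if _pair_loop_jit is not None else _pair_loop_numpy
    energy = loop(
        state.positions,
        box,
        periodic,
        nlist.pairs_i,
        nlist.pairs_j,
        topo.sigma,
        topo.epsilon,
        state.charges,
        params.cutoff_nm,
        params.k_rf,
        params.c_rf,
        params.lj_shift,
        forces,
    )
    if np.isnan(energy):
        i, j = _find_overlap(state, nlist)
        raise SingularityError(
            f"overlapping particles {i} and {j} (r < 1e-6 nm) at "
            f"step {state.step_index}"
        )
    return forces, float(energy)


def _find_overlap(state: SystemState, nlist: NeighborList):
    dr = state.positions[nlist.pairs_i] - state.positions[nlist.pairs_j]
    if state.box is not None:
        dr -= state.box * np.round(dr / state.box)
    r2 = np.einsum("ij,ij->i", dr, dr)
    k = int(np.argmin(r2))
    return int(nlist.pairs_i[k]), int(nlist.pairs_j[k])
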