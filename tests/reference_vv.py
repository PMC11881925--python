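"""Independent plain velocity-Verlet reference (no magnetic coupling).

Written from the textbook update equations, separate from the package's
integrator, to pin down the field-free limit of the magnetic integrator.
It shares the force routine (forces are not what the comparison exercises)
and uses the same constraint tolerances/sweep policy so that the two
integrators are comparable at the 1e-12/coordinate level over many steps.
"""

import numpy as np

from magmd.interactions import compute_forces


def _shake(pos, ref, invm, pairs, lengths, tol=1e-8, max_iter=500):
    pos = pos.copy()
    d2_target = [d0 * d0 for d0 in lengths]
    for _ in range(max_iter):
        worst = 0.0
        for (i, j), d0, d2t in zip(pairs, lengths, d2_target):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            viol = abs(np.sqrt(d2) - np.sqrt(d2t))
            worst = max(worst, viol)
            if viol < 0.1 * tol:
                continue
            rx = ref[i, 0] - ref[j, 0]
            ry = ref[i, 1] - ref[j, 1]
            rz = ref[i, 2] - ref[j, 2]
            denom = 2.0 * (invm[i] + invm[j]) * (dx * rx + dy * ry + dz * rz)
            g = (d2 - d2t) / denom
            pos[i, 0] -= g * invm[i] * rx
            pos[i, 1] -= g * invm[i] * ry
            pos[i, 2] -= g * invm[i] * rz
            pos[j, 0] += g * invm[j] * rx
            pos[j, 1] += g * invm[j] * ry
            pos[j, 2] += g * invm[j] * rz
        if worst < tol:
            return pos
    raise RuntimeError("reference SHAKE did not converge")


def _rattle_v(vel, pos, invm, pairs, lengths, tol=1e-10, max_iter=500):
    vel = vel.copy()
    d2_target = [d0 * d0 for d0 in lengths]
    for _ in range(max_iter):
        worst = 0.0
        for (i, j), d2t in zip(pairs, d2_target):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            vx = vel[i, 0] - vel[j, 0]
            vy = vel[i, 1] - vel[j, 1]
            vz = vel[i, 2] - vel[j, 2]
            proj = dx * vx + dy * vy + dz * vz
            viol = abs(proj) / np.sqrt(d2t)
            worst = max(worst, viol)
            if viol < 0.1 * tol:
                continue
            kk = proj / (d2t * (invm[i] + invm[j]))
            vel[i, 0] -= kk * invm[i] * dx
            vel[i, 1] -= kk * invm[i] * dy
            vel[i, 2] -= kk * invm[i] * dz
            vel[j, 0] += kk * invm[j] * dx
            vel[j, 1] += kk * invm[j] * dy
            vel[j, 2] += kk * invm[j] * dz
        if worst < tol:
            return vel
    raise RuntimeError("reference RATTLE did not converge")


def run_plain_vv(state, topo, params, dt, n_steps):
    """Textbook NVE velocity Verlet; returns (positions, velocities) arrays
    sampled every step (n_steps+1 frames)."""
    pos = state.positions.copy()
    vel = state.velocities.copy()
    invm = 1.0 / state.masses
    st = state.copy()
    forces, _ = compute_forces(st, topo, params)
    pairs = [tuple(p) for p in topo.constraints]
    lengths = list(topo.constraint_lengths)
    out_pos = [pos.copy()]
    out_vel = [vel.copy()]
    for _ in range(n_steps):
        prop = pos + vel * dt + (0.5 * dt * dt) * (forces * invm[:, None])
        if pairs:
            new = _shake(prop, pos, invm, pairs, lengths)
            vel = vel + (new - prop) / dt
        else:
            new = prop
        pos = new
        st.positions = pos
        forces_new, _ = compute_forces(st, topo, params)
        vel = vel + (0.5 * dt) * (forces + forces_new) * invm[:, None]
        forces = forces_new
        if pairs:
            vel = _rattle_v(vel, pos, invm, pairs, lengths)
        out_pos.append(pos.copy())
        out_vel.append(vel.copy())
    return np.array(out_pos), np.array(out_vel)
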