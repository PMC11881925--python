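import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def water_cluster_27():
    """Relaxed, thermalized 27-molecule SPC/E cluster (open box)."""
    from magmd import (
        IntegratorConfig,
        PairParams,
        build_water_box,
        minimize,
        rattle_positions,
        run,
    )
    from magmd.builders import _thermalize_rigid

    state, topo = build_water_box(27, seed=3, periodic=False)
    params = PairParams(cutoff_nm=np.inf, lj_shift=False)
    state = minimize(state, topo, params, max_steps=500, force_tol=20.0)
    state.positions = rattle_positions(
        state.positions, state.positions, topo, tol=1e-10,
        inv_masses=1.0 / state.masses,
    )
    _thermalize_rigid(state, topo, 200.0)
    cfg = IntegratorConfig(
        dt_ps=0.0005, n_steps=8000, ensemble="NVT", temperature_K=200.0,
        tau_t_ps=0.2, sample_stride=8000, remove_com=True,
        constraint_tol_nm=1e-10,
    )
    traj = run(state, topo, params, cfg)
    state.positions = traj.positions[-1]
    state.velocities = traj.velocities[-1]
    return state, topo, params


@pytest.fixture(scope="session")
def lj_dimer():
    """Two neutral LJ particles near their potential minimum, open box."""
    from magmd import SystemState, Topology

    sigma, eps = 0.34, 0.95
    state = SystemState(
        positions=np.array([[0.0, 0.0, 0.0], [0.39, 0.02, -0.01]]),
        velocities=np.array([[0.05, -0.02, 0.01], [-0.05, 0.02, -0.01]]),
        masses=np.array([39.948, 39.948]),
        charges=np.zeros(2),
        box=None,
    )
    topo = Topology(
        molecule=np.array([0, 1]),
        sigma=np.full(2, sigma),
        epsilon=np.full(2, eps),
    )
    return state, topo
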