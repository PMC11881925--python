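"""Trajectory observables: cyclotron characterization, MSD and
self-diffusion, RMSD after optimal superposition, radius of gyration.

All functions are pure: they read a Trajectory (or coordinate arrays) and
return plain results, so re-running an analysis reproduces its output
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import NM2_PER_PS_TO_M2_PER_S
from .model import InvalidParameterError, Trajectory


class InsufficientDataError(ValueError):
    """Too few frames / too little signal for the requested observable."""


@dataclass
class CyclotronSummary:
    """Circle-fit + phase-fit summary of single-particle gyration.

    chirality is +1 for counter-clockwise motion seen from +z, −1 for
    clockwise; drift is the mean velocity along the field axis.
    """

    radius_nm: float
    period_ps: float
    chirality: int
    v_z_nm_ps: float
    fit_residual_nm: float
    center_nm: tuple[float, float]
    omega_rad_ps: float


@dataclass
class DiffusionFit:
    """Einstein-relation fit: D = slope/6 on the linear MSD regime."""

    D_m2_s: float
    D_se_m2_s: float
    slope_nm2_ps: float
    intercept_nm2: float
    window_ps: tuple[float, float]
    n_points: int


def fit_circle_xy(x: np.ndarray, y: np.ndarray):
    """Algebraic (Kåsa) least-squares circle fit; returns (cx, cy, r, rms)."""
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx, cy = 0.5 * sol[0], 0.5 * sol[1]
    r = float(np.sqrt(max(sol[2] + cx**2 + cy**2, 0.0)))
    dist = np.hypot(x - cx, y - cy)
    return float(cx), float(cy), r, float(np.sqrt(np.mean((dist - r) ** 2)))


def cyclotron_characterize(traj: Trajectory, min_angle_rad: float = 0.5):
    """Radius, period, chirality and axial drift of a gyrating particle.

    The gyro-circle comes from an algebraic circle fit in the xy plane; the
    angular rate from a linear fit to the unwrapped phase of (v_x, v_y)
    (falling back to the position phase about the fitted center when
    velocities are absent).  Requires at least ~half a radian of angular
    progress over >= 10 frames.
    """
    if traj.n_particles != 1:
        raise InvalidParameterError("cyclotron analysis expects a single particle")
    if traj.n_frames < 10:
        raise InsufficientDataError("need at least 10 frames")
    xy = traj.positions[:, 0, :2]
    cx, cy, radius, resid = fit_circle_xy(xy[:, 0], xy[:, 1])
    if traj.velocities is not None:
        phase = np.unwrap(
            np.arctan2(traj.velocities[:, 0, 1], traj.velocities[:, 0, 0])
        )
    else:
        phase = np.unwrap(np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx))
    progress = float(np.abs(phase[-1] - phase[0]))
    if progress < min_angle_rad:
        raise InsufficientDataError(
            f"angular progress {progress:.3g} rad is too small for a period fit"
        )
    slope = np.polyfit(traj.times, phase, 1)[0]
    period = 2.0 * np.pi / abs(slope)
    if traj.velocities is not None:
        v_z = float(np.mean(traj.velocities[:, 0, 2]))
    else:
        v_z = float(
            np.polyfit(traj.times, traj.positions[:, 0, 2], 1)[0]
        )
    return CyclotronSummary(
        radius_nm=radius,
        period_ps=float(period),
        chirality=int(np.sign(slope)),
        v_z_nm_ps=v_z,
        fit_residual_nm=resid,
        center_nm=(cx, cy),
        omega_rad_ps=float(slope),
    )


def msd(
    traj: Trajectory,
    selection=None,
    t_max_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean squared displacement over sliding time origins, nm².

    MSD(τ) = ⟨|r(t+τ) − r(t)|²⟩ averaged over the selected particles and
    all origins; the lag grid runs from 0 to ``t_max_fraction`` of the run.
    Positions must be unwrapped (Trajectory stores them so by contract).
    """
    if traj.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames for an MSD")
    pos = traj.positions
    if selection is not None:
        pos = pos[:, np.asarray(selection), :]
    n_frames = pos.shape[0]
    max_lag = max(int(np.floor(t_max_fraction * (n_frames - 1))), 1)
    lags = np.arange(max_lag + 1)
    out = np.zeros(max_lag + 1)
    for k in lags[1:]:
        diff = pos[k:] - pos[:-k]
        out[k] = np.mean(np.sum(diff * diff, axis=2))
    return pd.DataFrame(
        {"lag_ps": lags * traj.dt_sample, "msd_nm2": out}
    )


def fit_diffusion(
    msd_series: pd.DataFrame,
    window_ps: tuple[float, float],
) -> DiffusionFit:
    """Least-squares Einstein fit on the requested lag window.

    D = slope/6 in nm²/ps, reported in m²/s (1 nm²/ps = 1.0e-6 m²/s), with
    the slope's standard error propagated.  Warns when the window shows the
    curvature of a non-diffusive (e.g. ballistic) regime.
    """
    t = np.asarray(msd_series["lag_ps"], dtype=float)
    y = np.asarray(msd_series["msd_nm2"], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("MSD time grid must be strictly increasing")
    lo, hi = window_ps
    mask = (t >= lo) & (t <= hi)
    if int(mask.sum()) < 5:
        raise InsufficientDataError("fit window must contain at least 5 points")
    res = stats.linregress(t[mask], y[mask])
    # curvature diagnostic: quadratic component vs linear one at mid-window
    quad = np.polyfit(t[mask], y[mask], 2)
    t_mid = 0.5 * (lo + hi)
    if abs(quad[0]) * t_mid**2 > 0.1 * abs(res.slope) * t_mid + 1e-30:
        warnings.warn(
            "MSD window appears non-linear (ballistic or caged regime); "
            "the Einstein fit may be biased",
            stacklevel=2,
        )
    d_nm2_ps = res.slope / 6.0
    return DiffusionFit(
        D_m2_s=d_nm2_ps * NM2_PER_PS_TO_M2_PER_S,
        D_se_m2_s=(res.stderr or 0.0) / 6.0 * NM2_PER_PS_TO_M2_PER_S,
        slope_nm2_ps=float(res.slope),
        intercept_nm2=float(res.intercept),
        window_ps=(float(lo), float(hi)),
        n_points=int(mask.sum()),
    )


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Optimal least-squares rotation (proper, via SVD) for centered coords."""
    h = mobile.T @ reference
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def rmsd(coords: np.ndarray, reference: np.ndarray, superpose: bool = True) -> float:
    """RMSD (nm) between two equal-size coordinate sets.

    With ``superpose`` the mobile set is first optimally translated and
    rotated onto the reference (Kabsch).
    """
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape:
        raise InvalidParameterError("coordinate sets must have identical shape")
    if superpose:
        mob = coords - coords.mean(axis=0)
        ref = reference - reference.mean(axis=0)
        rot = kabsch_rotation(mob, ref)
        diff = mob @ rot.T - ref
    else:
        diff = coords - reference
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | int = 0,
    selection=None,
    superpose: bool = True,
) -> pd.DataFrame:
    """Per-frame RMSD against a reference frame (index or coordinates)."""
    if isinstance(reference, (int, np.integer)):
        ref = traj.positions[int(reference)]
    else:
        ref = np.asarray(reference, dtype=float)
    sel = slice(None) if selection is None else np.asarray(selection)
    ref = ref[sel]
    values = [
        rmsd(traj.positions[k][sel], ref, superpose=superpose)
        for k in range(traj.n_frames)
    ]
    return pd.DataFrame({"time_ps": traj.times, "rmsd_nm": values})


@dataclass
class GyrationRadii:
    """Radius of gyration, total and resolved two ways.

    about_axis : RMS distance from the COM-parallel axis (e.g. about x uses
        (y−ȳ)² + (z−z̄)²) — the headline per-axis convention, satisfying
        Rg_total² = ½·Σ_axis Rg_about_axis².
    component : single-coordinate spread √(Σm(x−x̄)²/Σm), the alternative
        reading of a "per-axis" radius; Rg_total² = Σ_axis component².
    """

    total_nm: float
    about_axis_nm: np.ndarray  # (3,)
    component_nm: np.ndarray  # (3,)


def radius_of_gyration(
    positions: np.ndarray, masses: np.ndarray, selection=None
) -> GyrationRadii:
    """Mass-weighted radius of gyration of one frame (nm)."""
    pos = np.asarray(positions, dtype=float)
    m = np.asarray(masses, dtype=float)
    if selection is not None:
        sel = np.asarray(selection)
        pos, m = pos[sel], m[sel]
    if pos.shape[0] < 1 or np.sum(m) <= 0:
        raise InvalidParameterError("need >= 1 atom with positive total mass")
    com = (m[:, None] * pos).sum(axis=0) / m.sum()
    d = pos - com
    second = (m[:, None] * d * d).sum(axis=0) / m.sum()  # per-coordinate
    total = float(np.sqrt(second.sum()))
    about = np.sqrt(second.sum() - second)  # drop the axis coordinate
    return GyrationRadii(
        total_nm=total,
        about_axis_nm=about,
        component_nm=np.sqrt(second),
    )


def gyration_series(traj: Trajectory, masses, selection=None) -> pd.DataFrame:
    """Radius-of-gyration time series (total, about-axis and component)."""
    rows = []
    for k in range(traj.n_frames):
        g = radius_of_gyration(traj.positions[k], masses, selection)
        rows.append(
            {
                "time_ps": traj.times[k],
                "rg_total_nm": g.total_nm,
                "rg_about_x_nm": g.about_axis_nm[0],
                "rg_about_y_nm": g.about_axis_nm[1],
                "rg_about_z_nm": g.about_axis_nm[2],
                "rg_comp_x_nm": g.component_nm[0],
                "rg_comp_y_nm": g.component_nm[1],
                "rg_comp_z_nm": g.component_nm[2],
            }
        )
    return pd.DataFrame(rows)
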