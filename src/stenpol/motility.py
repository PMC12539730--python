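"""Centroid motility from a PKB kymograph via a viscoelastic cell model.

Supra-threshold PKB activity along the perimeter generates stress normal
to the cell surface.  The vector sum of these stresses, scaled into the
experimentally observed protrusive-stress range, drives a second-order
linear viscoelastic equation per axis:

    x'' + (k_c/γ_c) x' = (1/γ_c + 1/γ_a) σ̇_x + (k_c/γ_c) σ_x

The cell is a rigid circle (no shape change); the output displacement is
normalised post hoc so the maximum centroid speed equals 10 μm/min.
The linear system is advanced exactly (piecewise-constant stress with an
impulsive σ̇ contribution at each recording step), so the integration is
unconditionally stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Kymograph
from .params import ViscoParams

__all__ = [
    "Trajectory",
    "stress_from_pkb",
    "net_stress_series",
    "viscoelastic_response",
    "simulate_motility",
    "trajectory_metrics",
    "default_pkb_threshold",
]


@dataclass
class Trajectory:
    """Centroid positions over time, in μm."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


def stress_from_pkb(pkb_column: np.ndarray, threshold: float,
                    angles_deg: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-site outward-normal stress vectors, shape (n, 2).

    Sites with PKB above ``threshold`` push outward with magnitude
    proportional to their PKB level; all other sites contribute nothing.
    """
    pkb = np.asarray(pkb_column, float)
    n = pkb.shape[0]
    if angles_deg is None:
        angles_deg = 360.0 * np.arange(n) / n
    th = np.radians(angles_deg)
    mag = np.where(pkb > threshold, pkb, 0.0)
    return np.column_stack([mag * np.cos(th), mag * np.sin(th)])


def net_stress_series(pkb_kymo: np.ndarray, threshold: float,
                      params: ViscoParams = ViscoParams()) -> np.ndarray:
    """Net stress vector at each recorded time, scaled per run.

    The vector sum over the perimeter is rescaled so that the largest net
    stress magnitude over the run equals the top of the experimentally
    observed protrusive-stress range (``params.stress_max`` nN/μm).
    """
    n, nt = pkb_kymo.shape
    th = np.radians(360.0 * np.arange(n) / n)
    mag = np.where(pkb_kymo > threshold, pkb_kymo, 0.0)
    sx = (mag * np.cos(th)[:, None]).sum(axis=0)
    sy = (mag * np.sin(th)[:, None]).sum(axis=0)
    net = np.column_stack([sx, sy])
    peak = np.linalg.norm(net, axis=1).max()
    if peak > 0:
        net *= params.stress_max / peak
    return net


def viscoelastic_response(stress: np.ndarray, dt: float,
                          params: ViscoParams = ViscoParams()) -> np.ndarray:
    """Exact step response of the viscoelastic ODE for a piecewise-constant
    stress series; returns positions (len(stress)+1, 2), starting at 0.

    Each stress change contributes an impulsive velocity jump
    ``(1/γ_c + 1/γ_a) Δσ`` (the σ̇ term); between changes the velocity
    relaxes exponentially toward σ (the steady-state gain of the system is
    unity because both the drive and the damping carry k_c/γ_c).
    """
    stress = np.atleast_2d(np.asarray(stress, float))
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = params.k_c / params.gamma_c
    b = 1.0 / params.gamma_c + 1.0 / params.gamma_a
    ea = np.exp(-a * dt)
    nt = stress.shape[0]
    pos = np.zeros((nt + 1, 2))
    v = np.zeros(2)
    prev = np.zeros(2)
    x = np.zeros(2)
    for k in range(nt):
        s = stress[k]
        v = v + b * (s - prev)          # impulsive sigma-dot contribution
        # exact evolution with constant s over [0, dt]
        x = x + s * dt + (v - s) * (1.0 - ea) / a
        v = s + (v - s) * ea
        pos[k + 1] = x
        prev = s
    return pos


def default_pkb_threshold(basal_pkb: float, excited_pkb: float) -> float:
    """Midpoint between basal and excited PKB, the default force gate."""
    return 0.5 * (basal_pkb + excited_pkb)


def simulate_motility(kymo: Kymograph, threshold: Optional[float] = None,
                      params: ViscoParams = ViscoParams(),
                      speed_scale: Optional[float] = None) -> Trajectory:
    """Full pipeline: PKB kymograph → stresses → centroid trajectory.

    ``speed_scale`` overrides the per-run speed normalisation (pass the
    shared scale when normalising across a sweep); otherwise the maximum
    speed of this trajectory is set to ``params.max_speed`` μm/min.
    """
    pkb = kymo["pkb"]
    if threshold is None:
        from .meanfield import basal_equilibrium
        basal = basal_equilibrium(kymo.model).pkb
        excited = np.percentile(pkb, 99)
        threshold = default_pkb_threshold(basal, max(excited, basal))
    dt = kymo.record_interval
    net = net_stress_series(pkb, threshold, params)
    pos = viscoelastic_response(net, dt, params)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    vmax = steps.max() / dt * 60.0          # um/min
    if speed_scale is not None:
        pos = pos * speed_scale
    elif vmax > 0:
        pos = pos * (params.max_speed / vmax)
    t = np.arange(pos.shape[0]) * dt
    return Trajectory(t=t, x=pos[:, 0], y=pos[:, 1])


def trajectory_metrics(traj: Trajectory) -> dict:
    """Total distance, net displacement, efficiency and mean speed."""
    pts = traj.points()
    if pts.shape[0] < 2:
        raise ValueError("trajectory needs at least two points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(steps.sum())
    final = float(np.linalg.norm(pts[-1] - pts[0]))
    duration = float(traj.t[-1] - traj.t[0])
    return {
        "total_distance": total,
        "final_displacement": final,
        "efficiency": final / total if total > 0 else 0.0,
        "mean_speed": total / duration if duration > 0 else 0.0,
    }
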