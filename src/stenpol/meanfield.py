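"""Mean-field (well-mixed, noise-free) analysis of the excitable network.

With diffusion and noise removed, every auxiliary species is an explicit
function of Ras at equilibrium, so all equilibria are roots of a scalar
function of Ras.  This module finds them, classifies their stability from
the Jacobian of the full ODE system, measures activation thresholds by
bisection on instantaneous Ras perturbations, and scans feedback strengths
or the normalised PIP5K level (a scalar multiplying the PIP2 production
rate, with level 1 reproducing the reference system).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import FeedbackSpec, ModelSpec

__all__ = [
    "MeanFieldPoint",
    "solve_equilibrium",
    "basal_equilibrium",
    "rhs",
    "jacobian",
    "jacobian_fd",
    "activation_threshold",
    "scan_pip5k_level",
    "scan_grid",
    "instability_onset",
    "high_activity_onset",
    "threshold_peak_level",
]

_R_GRID = np.geomspace(1e-10, 20.0, 6000)
_MERGE_TOL = 1e-6
_NEUTRAL_TOL = 1e-12   # PIP5K conservation gives one structurally zero mode


@dataclass(frozen=True)
class MeanFieldPoint:
    """One equilibrium of the well-mixed system."""

    ras: float
    pip2: float
    pkb: float
    pact: Optional[float] = None
    pmyo: Optional[float] = None
    pten: Optional[float] = None
    pip5k_b: Optional[float] = None
    pip5k_un: Optional[float] = None
    leading_eigenvalue: float = np.nan
    residual: float = np.nan

    @property
    def stable(self) -> bool:
        return self.leading_eigenvalue < 0

    def vector(self) -> np.ndarray:
        vals = [self.ras, self.pip2, self.pkb]
        for v in (self.pact, self.pmyo, self.pten,
                  self.pip5k_b, self.pip5k_un):
            if v is not None:
                vals.append(v)
        return np.array(vals)


def _species_layout(fb: FeedbackSpec) -> List[str]:
    names = ["ras", "pip2", "pkb"]
    if fb.actin_enabled:
        names.append("pact")
    if fb.myosin_enabled:
        names.append("pmyo")
    if fb.tension_enabled:
        names.append("pten")
    if fb.pip5k_enabled:
        names += ["pip5k_b", "pip5k_un"]
    return names


def _release_rate(fb: FeedbackSpec, R: float) -> float:
    return fb.p7 * R * R / (1.0 + fb.p9 ** 2 * R * R)


def _pip5k_active_scalar(fb: FeedbackSpec, b: float, u: float) -> float:
    if fb.pip5k_mode == "bound":
        return b
    if fb.pip5k_mode == "unbound":
        return u
    return b + u


def rhs(y: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Right-hand side of the well-mixed ODE system (layout per feedback)."""
    p, fb = model.sten, model.feedback
    names = _species_layout(fb)
    d = dict(zip(names, y))
    R, P, K = d["ras"], d["pip2"], d["pkb"]
    gf, lf = 1.0, 1.0
    if fb.actin_enabled:
        gf *= 1.0 + fb.a_act * d["pact"]
    if fb.myosin_enabled:
        lf *= 1.0 + fb.a_myo * d["pmyo"]
    if fb.tension_enabled:
        if fb.tension_mode == "hydrolysis":
            lf *= 1.0 + fb.a_ten * d["pten"]
        else:
            gf /= 1.0 + fb.a_ten * d["pten"]
    b3_eff = model.pip2_production_scale * p.b3
    if fb.pip5k_enabled:
        b3_eff *= 1.0 + fb.a_pip5k * _pip5k_active_scalar(
            fb, d["pip5k_b"], d["pip5k_un"])
    out = {
        "ras": gf * (p.a3 / (1.0 + p.a4 ** 2 * P * P) + p.a5)
        - lf * (p.a1 + p.a2 * K) * R,
        "pip2": b3_eff - (p.b1 + p.b2 * R) * P,
        "pkb": p.c2 * R - p.c1 * K,
    }
    if fb.actin_enabled:
        out["pact"] = fb.p2 * K - fb.p1 * d["pact"]
    if fb.myosin_enabled:
        out["pmyo"] = fb.p4 * P - fb.p3 * d["pmyo"]
    if fb.tension_enabled:
        out["pten"] = -fb.p5 * d["pten"] + fb.p6 * K
    if fb.pip5k_enabled:
        r = _release_rate(fb, R)
        out["pip5k_b"] = -r * d["pip5k_b"] + fb.p8 * d["pip5k_un"]
        out["pip5k_un"] = r * d["pip5k_b"] - fb.p8 * d["pip5k_un"]
    return np.array([out[n] for n in names])


def jacobian(y: np.ndarray, model: ModelSpec) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs`."""
    p, fb = model.sten, model.feedback
    names = _species_layout(fb)
    idx = {n: i for i, n in enumerate(names)}
    d = dict(zip(names, y))
    R, P, K = d["ras"], d["pip2"], d["pkb"]
    m = len(names)
    J = np.zeros((m, m))

    gf_act = 1.0 + fb.a_act * d["pact"] if fb.actin_enabled else 1.0
    gf_ten = (1.0 / (1.0 + fb.a_ten * d["pten"])
              if fb.tension_enabled and fb.tension_mode == "production" else 1.0)
    gf = gf_act * gf_ten
    lf_myo = 1.0 + fb.a_myo * d["pmyo"] if fb.myosin_enabled else 1.0
    lf_ten = (1.0 + fb.a_ten * d["pten"]
              if fb.tension_enabled and fb.tension_mode == "hydrolysis" else 1.0)
    lf = lf_myo * lf_ten

    h = p.a3 / (1.0 + p.a4 ** 2 * P * P)
    hp = -p.a3 * 2.0 * p.a4 ** 2 * P / (1.0 + p.a4 ** 2 * P * P) ** 2
    gain = h + p.a5

    iR = idx["ras"]
    J[iR, idx["ras"]] = -lf * (p.a1 + p.a2 * K)
    J[iR, idx["pip2"]] = gf * hp
    J[iR, idx["pkb"]] = -lf * p.a2 * R
    if fb.actin_enabled:
        J[iR, idx["pact"]] = fb.a_act * gf_ten * gain
    if fb.myosin_enabled:
        J[iR, idx["pmyo"]] = -fb.a_myo * lf_ten * (p.a1 + p.a2 * K) * R
    if fb.tension_enabled:
        if fb.tension_mode == "hydrolysis":
            J[iR, idx["pten"]] = -fb.a_ten * lf_myo * (p.a1 + p.a2 * K) * R
        else:
            J[iR, idx["pten"]] = (-fb.a_ten * gf_act * gain
                                  / (1.0 + fb.a_ten * d["pten"]) ** 2)

    iP = idx["pip2"]
    J[iP, idx["ras"]] = -p.b2 * P
    J[iP, idx["pip2"]] = -(p.b1 + p.b2 * R)
    if fb.pip5k_enabled:
        base = model.pip2_production_scale * p.b3 * fb.a_pip5k
        if fb.pip5k_mode in ("bound", "combined"):
            J[iP, idx["pip5k_b"]] = base
        if fb.pip5k_mode in ("unbound", "combined"):
            J[iP, idx["pip5k_un"]] = base

    iK = idx["pkb"]
    J[iK, idx["ras"]] = p.c2
    J[iK, idx["pkb"]] = -p.c1

    if fb.actin_enabled:
        i = idx["pact"]
        J[i, idx["pkb"]] = fb.p2
        J[i, i] = -fb.p1
    if fb.myosin_enabled:
        i = idx["pmyo"]
        J[i, idx["pip2"]] = fb.p4
        J[i, i] = -fb.p3
    if fb.tension_enabled:
        i = idx["pten"]
        J[i, idx["pkb"]] = fb.p6
        J[i, i] = -fb.p5
    if fb.pip5k_enabled:
        ib, iu = idx["pip5k_b"], idx["pip5k_un"]
        r = _release_rate(fb, R)
        rp = fb.p7 * 2.0 * R / (1.0 + fb.p9 ** 2 * R * R) ** 2
        J[ib, idx["ras"]] = -rp * d["pip5k_b"]
        J[ib, ib] = -r
        J[ib, iu] = fb.p8
        J[iu, idx["ras"]] = rp * d["pip5k_b"]
        J[iu, ib] = r
        J[iu, iu] = -fb.p8
    return J


def jacobian_fd(y: np.ndarray, model: ModelSpec,
                eps: float = 1e-7) -> np.ndarray:
    """Finite-difference Jacobian (cross-check for the analytic one)."""
    y = np.asarray(y, float)
    m = len(y)
    J = np.zeros((m, m))
    f0 = rhs(y, model)
    for i in range(m):
        h = eps * max(1.0, abs(y[i]))
        yp = y.copy()
        yp[i] += h
        J[:, i] = (rhs(yp, model) - f0) / h
    return J


def _equilibrium_from_R(R: float, model: ModelSpec) -> np.ndarray:
    """Full state vector implied by a candidate equilibrium Ras value."""
    p, fb = model.sten, model.feedback
    K = p.c2 / p.c1 * R
    b3_eff = model.pip2_production_scale * p.b3
    b = u = None
    if fb.pip5k_enabled:
        r = _release_rate(fb, R)
        b = fb.p8 / (r + fb.p8)
        u = 1.0 - b
        b3_eff *= 1.0 + fb.a_pip5k * _pip5k_active_scalar(fb, b, u)
    P = b3_eff / (p.b1 + p.b2 * R)
    vals = [R, P, K]
    if fb.actin_enabled:
        vals.append(fb.p2 / fb.p1 * K)
    if fb.myosin_enabled:
        vals.append(fb.p4 / fb.p3 * P)
    if fb.tension_enabled:
        vals.append(fb.p6 / fb.p5 * K)
    if fb.pip5k_enabled:
        vals += [b, u]
    return np.array(vals)


def _scalar_balance(R: float, model: ModelSpec) -> float:
    y = _equilibrium_from_R(R, model)
    return rhs(y, model)[0]


def _leading_eig(J: np.ndarray) -> float:
    ev = np.linalg.eigvals(J).real
    ev = ev[np.abs(ev) > _NEUTRAL_TOL] if (np.abs(ev) <= _NEUTRAL_TOL).any() \
        else ev
    return float(ev.max()) if ev.size else 0.0


def solve_equilibrium(model: ModelSpec) -> List[MeanFieldPoint]:
    """All non-negative equilibria, sorted by Ras, with stability flags.

    Roots are located from sign changes of the reduced scalar balance on a
    dense logarithmic Ras grid and polished with Brent's method; duplicates
    within 1e-6 μM are merged.
    """
    vals = np.array([_scalar_balance(R, model) for R in _R_GRID])
    roots: List[float] = []
    for i in range(len(_R_GRID) - 1):
        if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) \
                and vals[i] * vals[i + 1] < 0:
            r = brentq(_scalar_balance, _R_GRID[i], _R_GRID[i + 1],
                       args=(model,), xtol=1e-14, rtol=1e-14)
            if not any(abs(r - q) < _MERGE_TOL for q in roots):
                roots.append(r)
    pts = []
    names = _species_layout(model.feedback)
    for r in sorted(roots):
        y = _equilibrium_from_R(r, model)
        resid = float(np.max(np.abs(rhs(y, model))))
        lam = _leading_eig(jacobian(y, model))
        kw = dict(zip(names, y))
        pts.append(MeanFieldPoint(**kw, leading_eigenvalue=lam,
                                  residual=resid))
    return pts


def basal_equilibrium(model: ModelSpec) -> MeanFieldPoint:
    """The lowest-Ras equilibrium (the resting state in the excitable
    regime).  Raises if no equilibrium is found."""
    pts = solve_equilibrium(model)
    if not pts:
        raise RuntimeError("no mean-field equilibrium found")
    return pts[0]


def _integrate(model: ModelSpec, y0: np.ndarray, t_end: float,
               dense: bool = False):
    sol = solve_ivp(lambda t, y: rhs(y, model), (0.0, t_end), y0,
                    method="LSODA", rtol=1e-8, atol=1e-12,
                    max_step=2.0, dense_output=dense)
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    return sol


def _excursion_peak(model: ModelSpec, point: MeanFieldPoint,
                    delta: float, t_end: float = 800.0) -> float:
    y0 = point.vector()
    y0[0] += delta
    sol = _integrate(model, y0, t_end)
    return float(sol.y[0].max())


def activation_threshold(model: ModelSpec,
                         point: Optional[MeanFieldPoint] = None,
                         criterion: str = "per-level",
                         reference: Optional[ModelSpec] = None,
                         probe: float = 1.0,
                         cap: float = 2.0,
                         tol: float = 1e-4):
    """Smallest instantaneous Ras perturbation that triggers an excursion.

    The trigger criterion is a mid-excursion Ras level: halfway between the
    basal equilibrium and an excited peak.  With ``criterion='per-level'``
    (default) the excited peak is probed from the system under study with a
    fixed large kick (``probe`` μM); with ``criterion='reference'`` it is
    taken once from ``reference`` (or the model itself).  Returns the
    threshold in μM, ``'unstable'`` for an unstable point, or ``'none'``
    when no perturbation up to ``cap`` μM triggers.
    """
    if point is None:
        point = basal_equilibrium(model)
    if not point.stable:
        return "unstable"
    if criterion == "per-level":
        peak = _excursion_peak(model, point, probe)
        crit = point.ras + 0.5 * (peak - point.ras)
    elif criterion == "reference":
        ref = reference if reference is not None else model
        ref_pt = basal_equilibrium(ref)
        peak = _excursion_peak(ref, ref_pt, probe)
        crit = ref_pt.ras + 0.5 * (peak - ref_pt.ras)
    else:
        raise ValueError("criterion must be 'per-level' or 'reference'")
    if _excursion_peak(model, point, cap) < crit:
        return "none"
    lo, hi = 0.0, cap
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _excursion_peak(model, point, mid) > crit:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _with_level(model: ModelSpec, level: float) -> ModelSpec:
    return replace(model, pip2_production_scale=level)


def _low_branch(model: ModelSpec) -> Optional[MeanFieldPoint]:
    pts = solve_equilibrium(model)
    return pts[0] if pts else None


def pip5k_reference_model(a_act: float = 1.0,
                          a_myo: float = 0.3) -> ModelSpec:
    """Actin+myosin model used for the PIP5K-level sensitivity analysis."""
    return ModelSpec(feedback=FeedbackSpec.model1(a_act, a_myo))


def scan_pip5k_level(levels: Sequence[float],
                     model: Optional[ModelSpec] = None,
                     thresholds: bool = True) -> pd.DataFrame:
    """Equilibria, stability and activation threshold vs PIP5K level."""
    model = model or pip5k_reference_model()
    rows = []
    for lev in levels:
        m = _with_level(model, lev)
        pts = solve_equilibrium(m)
        low = pts[0] if pts else None
        row = {
            "level": lev,
            "n_equilibria": len(pts),
            "ras_low": low.ras if low else np.nan,
            "lambda_low": low.leading_eigenvalue if low else np.nan,
            "ras_max_stable": max((p.ras for p in pts if p.stable),
                                  default=np.nan),
        }
        if thresholds:
            th = activation_threshold(m, low) if low else "unstable"
            row["threshold"] = th if isinstance(th, float) else np.nan
            row["threshold_flag"] = th if isinstance(th, str) else ""
        rows.append(row)
    return pd.DataFrame(rows)


def instability_onset(model: Optional[ModelSpec] = None,
                      lo: float = 0.2, hi: float = 1.0,
                      tol: float = 1e-3) -> float:
    """PIP5K level at which the low-Ras branch loses stability (leading
    Jacobian eigenvalue crosses zero) as the level decreases, by bisection."""
    model = model or pip5k_reference_model()
    cutoff = 10.0 * basal_equilibrium(_with_level(model, hi)).ras

    def stable_low(level: float) -> bool:
        pts = [p for p in solve_equilibrium(_with_level(model, level))
               if p.ras < cutoff]
        return bool(pts) and pts[0].stable

    if not stable_low(hi):
        raise RuntimeError(f"low branch already unstable at level {hi}")
    if stable_low(lo):
        raise RuntimeError(f"low branch still stable at level {lo}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stable_low(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def high_activity_onset(model: Optional[ModelSpec] = None,
                        lo: float = 0.2, hi: float = 1.0,
                        tol: float = 1e-3,
                        factor: float = 10.0,
                        settle_time: float = 6000.0) -> float:
    """Largest PIP5K level at which the attractor reached from the low
    state exceeds ``factor`` × the reference (level-1) basal Ras."""
    model = model or pip5k_reference_model()
    ref = basal_equilibrium(_with_level(model, 1.0)).ras

    def settles_high(level: float) -> bool:
        m = _with_level(model, level)
        low = _low_branch(m)
        if low is not None and low.stable:
            start = low.vector()
            start[0] *= 1.01        # nudge off the fixed point
        else:
            higher = _low_branch(_with_level(model, min(level + 0.05, hi)))
            start = (higher.vector() if higher is not None
                     else _equilibrium_from_R(ref, m))
        sol = _integrate(m, start, settle_time)
        return sol.y[0, -1] > factor * ref

    if settles_high(hi):
        raise RuntimeError(f"system already high at level {hi}")
    if not settles_high(lo):
        raise RuntimeError(f"system not high at level {lo}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if settles_high(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def threshold_peak_level(levels: Optional[Sequence[float]] = None,
                         model: Optional[ModelSpec] = None) -> float:
    """Location of the interior maximum of the activation threshold over a
    PIP5K-level grid (the biphasic peak)."""
    if levels is None:
        levels = np.arange(1.0, 8.0 + 1e-9, 0.25)
    df = scan_pip5k_level(levels, model=model, thresholds=True)
    th = df["threshold"].to_numpy()
    if np.all(np.isnan(th)):
        raise RuntimeError("no finite thresholds on the grid")
    return float(df["level"].iloc[int(np.nanargmax(th))])


def scan_grid(param1: str, values1: Sequence[float],
              param2: str, values2: Sequence[float],
              base: Optional[ModelSpec] = None) -> pd.DataFrame:
    """Equilibria over a 2-D grid of feedback strengths (bifurcation scan).

    ``param1``/``param2`` name FeedbackSpec strength fields (e.g. 'a_act',
    'a_myo', 'a_ten'); enabling flags are switched on automatically.
    """
    base = base or ModelSpec()
    rows = []
    flag = {"a_act": "actin_enabled", "a_myo": "myosin_enabled",
            "a_ten": "tension_enabled"}
    for v1 in values1:
        for v2 in values2:
            fb = replace(base.feedback, **{
                param1: v1, flag[param1]: True,
                param2: v2, flag[param2]: True})
            m = replace(base, feedback=fb)
            for pt in solve_equilibrium(m):
                rows.append({param1: v1, param2: v2, "ras": pt.ras,
                             "pip2": pt.pip2, "pkb": pt.pkb,
                             "leading_eigenvalue": pt.leading_eigenvalue,
                             "stable": pt.stable})
    return pd.DataFrame(rows)
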