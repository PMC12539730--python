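"""Stochastic reaction-diffusion integration of the excitable network.

The dynamical system lives on a periodic 1-D membrane lattice.  Three core
species (Ras, PIP2, PKB) follow coupled Langevin equations integrated with
an explicit Euler–Maruyama scheme; concentrations are clipped at zero after
each step.  Optional cytoskeletal feedback fields (P_act, P_myo, the scalar
tension variable P_ten, and the two PIP5K pools) are advanced with the same
scheme — P_act/P_myo carry the same reaction-based noise as the core
species, while P_ten and PIP5K are deterministic.  The PIP5K bound/unbound
exchange is advanced with its exact per-site solution (the exchange is
linear once Ras is frozen over a step), which conserves total PIP5K to
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from . import _kernel
from .params import (FeedbackSpec, Lattice, ModelSpec, SimSettings,
                     StenParams)

__all__ = [
    "MembraneState",
    "FeedbackEffects",
    "Kymograph",
    "IntegrationError",
    "reaction_terms",
    "langevin_amplitude",
    "periodic_laplacian",
    "step",
    "simulate",
    "CORE_SPECIES",
]

CORE_SPECIES = ("ras", "pip2", "pkb")
NOISY_SPECIES = ("ras", "pip2", "pkb", "pact", "pmyo")


class IntegrationError(RuntimeError):
    """Raised when a field becomes non-finite during integration."""


@dataclass
class MembraneState:
    """Concentrations of all dynamic species at one instant."""

    ras: np.ndarray
    pip2: np.ndarray
    pkb: np.ndarray
    pact: Optional[np.ndarray] = None
    pmyo: Optional[np.ndarray] = None
    pten: float = 0.0           # spatially uniform by construction
    pip5k_b: Optional[np.ndarray] = None
    pip5k_un: Optional[np.ndarray] = None
    t: float = 0.0

    def validate(self) -> None:
        n = self.ras.shape[0]
        for name in ("ras", "pip2", "pkb", "pact", "pmyo",
                     "pip5k_b", "pip5k_un"):
            f = getattr(self, name)
            if f is None:
                continue
            if f.shape != (n,):
                raise ValueError(f"field {name} has shape {f.shape}, "
                                 f"expected ({n},)")
            if np.any(f < 0):
                raise ValueError(f"field {name} contains negative values")

    def copy(self) -> "MembraneState":
        return MembraneState(
            ras=self.ras.copy(), pip2=self.pip2.copy(), pkb=self.pkb.copy(),
            pact=None if self.pact is None else self.pact.copy(),
            pmyo=None if self.pmyo is None else self.pmyo.copy(),
            pten=self.pten,
            pip5k_b=None if self.pip5k_b is None else self.pip5k_b.copy(),
            pip5k_un=None if self.pip5k_un is None else self.pip5k_un.copy(),
            t=self.t)


@dataclass(frozen=True)
class FeedbackEffects:
    """Multiplicative modifications of the core rate terms.

    All factors are identically 1 when every loop is disabled (or has zero
    strength), in which case the core network is recovered exactly.
    """

    ras_gain_factor: np.ndarray
    ras_loss_factor: np.ndarray
    pip2_gain_factor: np.ndarray

    @staticmethod
    def identity(n: int) -> "FeedbackEffects":
        one = np.ones(n)
        return FeedbackEffects(one, one.copy(), one.copy())


def feedback_effects(state: MembraneState, model: ModelSpec) -> FeedbackEffects:
    """Evaluate the multiplicative feedback factors for the current state."""
    fb = model.feedback
    n = state.ras.shape[0]
    gain = np.ones(n)
    loss = np.ones(n)
    if fb.actin_enabled:
        gain = gain * (1.0 + fb.a_act * state.pact)
    if fb.myosin_enabled:
        loss = loss * (1.0 + fb.a_myo * state.pmyo)
    if fb.tension_enabled:
        if fb.tension_mode == "hydrolysis":
            loss = loss * (1.0 + fb.a_ten * state.pten)
        else:
            gain = gain / (1.0 + fb.a_ten * state.pten)
    pip2_gain = np.full(n, model.pip2_production_scale)
    if fb.pip5k_enabled:
        from .feedback import pip5k_active
        active = pip5k_active(state.pip5k_b, state.pip5k_un, fb.pip5k_mode)
        pip2_gain = pip2_gain * (1.0 + fb.a_pip5k * active)
    return FeedbackEffects(gain, loss, pip2_gain)


def reaction_terms(state: MembraneState, params: StenParams,
                   fb: Optional[FeedbackEffects] = None
                   ) -> Dict[str, tuple]:
    """Per-species (gain, loss) fields of the core network.

    Gains and losses are returned separately because the Langevin amplitude
    is based on their sum.
    """
    state.validate()
    n = state.ras.shape[0]
    if fb is None:
        fb = FeedbackEffects.identity(n)
    ras_gain = fb.ras_gain_factor * (
        params.a3 / (1.0 + params.a4 ** 2 * state.pip2 ** 2) + params.a5)
    ras_loss = fb.ras_loss_factor * (params.a1 + params.a2 * state.pkb) * state.ras
    pip2_gain = fb.pip2_gain_factor * params.b3
    pip2_loss = (params.b1 + params.b2 * state.ras) * state.pip2
    pkb_gain = params.c2 * state.ras
    pkb_loss = params.c1 * state.pkb
    return {
        "ras": (ras_gain, ras_loss),
        "pip2": (np.broadcast_to(pip2_gain, (n,)) if np.ndim(pip2_gain) else
                 np.full(n, pip2_gain), pip2_loss),
        "pkb": (pkb_gain, pkb_loss),
    }


def langevin_amplitude(gain: np.ndarray, loss: np.ndarray,
                       alpha: float) -> np.ndarray:
    """Noise standard deviation ``alpha * sqrt(gain + loss)``, pointwise.

    The amplitude sums the magnitudes of production and degradation, so it
    vanishes only where the species is chemically inert.
    """
    gain = np.asarray(gain, float)
    loss = np.asarray(loss, float)
    if np.any(gain < 0) or np.any(loss < 0):
        raise ValueError("gain and loss must be non-negative")
    return alpha * np.sqrt(gain + loss)


def periodic_laplacian(f: np.ndarray, dx: float) -> np.ndarray:
    """Second-order central difference with wraparound on the ring."""
    return (np.roll(f, 1) + np.roll(f, -1) - 2.0 * f) / (dx * dx)


def _par_vector(model: ModelSpec) -> np.ndarray:
    p, fb = model.sten, model.feedback
    return np.array([
        p.a1, p.a2, p.a3, p.a4, p.a5, p.b1, p.b2, p.b3, p.c1, p.c2,
        p.D_ras, p.D_pip2, p.D_pkb, p.alpha,
        fb.a_act, fb.a_myo, fb.a_ten, fb.a_pip5k,
        fb.p1, fb.p2, fb.p3, fb.p4, fb.p5, fb.p6, fb.p7, fb.p8, fb.p9,
        fb.D_pact, fb.D_pmyo, fb.D_pip5k_b, fb.D_pip5k_un,
        model.pip2_production_scale])


def _flags(fb: FeedbackSpec) -> tuple:
    return (int(fb.actin_enabled), int(fb.myosin_enabled),
            int(fb.tension_enabled),
            _kernel.TEN_HYDROLYSIS if fb.tension_mode == "hydrolysis"
            else _kernel.TEN_PRODUCTION,
            int(fb.pip5k_enabled),
            {"bound": _kernel.P5K_BOUND, "unbound": _kernel.P5K_UNBOUND,
             "combined": _kernel.P5K_COMBINED}[fb.pip5k_mode])


def step(state: MembraneState, model: ModelSpec, dt: float, dx: float,
         noise: Optional[Dict[str, np.ndarray]] = None,
         rng: Optional[np.random.Generator] = None) -> MembraneState:
    """One explicit Euler–Maruyama step (NumPy reference implementation).

    ``noise`` maps species name to a standard-normal vector; species left
    out (or all of them, when ``noise`` is None and no ``rng`` is given)
    receive no stochastic increment.  ``simulate`` uses a compiled kernel
    that performs the identical update; the two are cross-checked in the
    test-suite.
    """
    p, fb = model.sten, model.feedback
    n = state.ras.shape[0]
    if noise is None:
        if rng is not None:
            noise = {s: rng.standard_normal(n) for s in NOISY_SPECIES}
        else:
            noise = {}
    z = {s: noise.get(s, np.zeros(n)) for s in NOISY_SPECIES}
    sdt = np.sqrt(dt)

    eff = feedback_effects(state, model)
    terms = reaction_terms(state, p, eff)

    out = state.copy()
    diff = {"ras": p.D_ras, "pip2": p.D_pip2, "pkb": p.D_pkb}
    for sp in CORE_SPECIES:
        g, l = terms[sp]
        f = getattr(state, sp)
        amp = langevin_amplitude(g, l, p.alpha)
        upd = (f + dt * (g - l + diff[sp] * periodic_laplacian(f, dx))
               + sdt * amp * z[sp])
        setattr(out, sp, np.where(upd < 0, 0.0, upd))

    if fb.actin_enabled:
        g, l = fb.p2 * state.pkb, fb.p1 * state.pact
        upd = (state.pact + dt * (g - l + fb.D_pact *
                                  periodic_laplacian(state.pact, dx))
               + sdt * langevin_amplitude(g, l, p.alpha) * z["pact"])
        out.pact = np.where(upd < 0, 0.0, upd)
    if fb.myosin_enabled:
        g, l = fb.p4 * state.pip2, fb.p3 * state.pmyo
        upd = (state.pmyo + dt * (g - l + fb.D_pmyo *
                                  periodic_laplacian(state.pmyo, dx))
               + sdt * langevin_amplitude(g, l, p.alpha) * z["pmyo"])
        out.pmyo = np.where(upd < 0, 0.0, upd)
    if fb.tension_enabled:
        out.pten = state.pten + dt * (-fb.p5 * state.pten
                                      + fb.p6 * float(np.mean(state.pkb)))
    if fb.pip5k_enabled:
        b = state.pip5k_b + dt * fb.D_pip5k_b * periodic_laplacian(
            state.pip5k_b, dx)
        u = state.pip5k_un + dt * fb.D_pip5k_un * periodic_laplacian(
            state.pip5k_un, dx)
        r = fb.p7 * state.ras ** 2 / (1.0 + fb.p9 ** 2 * state.ras ** 2)
        srate = r + fb.p8
        tot = b + u
        beq = fb.p8 / srate * tot
        b_new = beq + (b - beq) * np.exp(-srate * dt)
        out.pip5k_b = np.where(b_new < 0, 0.0, b_new)
        out.pip5k_un = np.where(tot - b_new < 0, 0.0, tot - b_new)

    out.t = state.t + dt
    _check_finite(out)
    return out


def _check_finite(state: MembraneState) -> None:
    for name in ("ras", "pip2", "pkb", "pact", "pmyo", "pip5k_b", "pip5k_un"):
        f = getattr(state, name)
        if f is None:
            continue
        bad = ~np.isfinite(f)
        if bad.any():
            site = int(np.argmax(bad))
            raise IntegrationError(
                f"non-finite {name} at site {site}, t={state.t:.3f} s")


@dataclass
class Kymograph:
    """Recorded space × time fields of one simulation.

    ``data`` maps species name to an array of shape ``(n_points, n_times)``.
    """

    data: Dict[str, np.ndarray]
    dx: float
    record_interval: float
    seed: int
    model: ModelSpec

    @property
    def n_points(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def n_times(self) -> int:
        return next(iter(self.data.values())).shape[1]

    @property
    def degrees_per_site(self) -> float:
        return 360.0 / self.n_points

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) * self.record_interval

    def __getitem__(self, species: str) -> np.ndarray:
        return self.data[species]


def initial_state(model: ModelSpec, lattice: Lattice) -> MembraneState:
    """Uniform basal state: noise-free mean-field equilibrium of the core
    species, feedback species at their equilibria given basal levels, PIP5K
    all bound with total 1 per site."""
    from .meanfield import basal_equilibrium
    pt = basal_equilibrium(model)
    n = lattice.n_points
    fb = model.feedback
    st = MembraneState(
        ras=np.full(n, pt.ras), pip2=np.full(n, pt.pip2),
        pkb=np.full(n, pt.pkb), t=0.0)
    if fb.actin_enabled:
        st.pact = np.full(n, (fb.p2 / fb.p1) * pt.pkb)
    if fb.myosin_enabled:
        st.pmyo = np.full(n, (fb.p4 / fb.p3) * pt.pip2)
    if fb.tension_enabled:
        st.pten = (fb.p6 / fb.p5) * pt.pkb
    if fb.pip5k_enabled:
        st.pip5k_b = np.ones(n)
        st.pip5k_un = np.zeros(n)
    return st


def _species_rngs(seed: int) -> Dict[str, np.random.Generator]:
    """One independent stream per noisy species.

    Keyed by (seed, species index) so that enabling a feedback loop never
    perturbs the noise seen by the core species.
    """
    return {sp: np.random.default_rng(np.random.SeedSequence((seed, k)))
            for k, sp in enumerate(NOISY_SPECIES)}


def simulate(model: ModelSpec, settings: SimSettings,
             initial: Optional[MembraneState] = None) -> Kymograph:
    """Integrate the model and record a kymograph.

    Starts from the uniform basal equilibrium unless ``initial`` is given;
    records every ``record_interval`` (the initial condition is the first
    column).  Identical seed and settings give a bitwise identical result.
    """
    settings.validate_stability(model.sten)
    lattice = settings.lattice
    n = lattice.n_points
    fb = model.feedback
    state = initial.copy() if initial is not None else initial_state(
        model, lattice)
    state.validate()

    species = list(CORE_SPECIES)
    if fb.actin_enabled:
        species.append("pact")
    if fb.myosin_enabled:
        species.append("pmyo")
    if fb.tension_enabled:
        species.append("pten")
    if fb.pip5k_enabled:
        species += ["pip5k_b", "pip5k_un"]

    n_rec = settings.n_steps // settings.steps_per_record
    out = {sp: np.empty((n, n_rec + 1)) for sp in species}

    def record(j: int) -> None:
        for sp in species:
            if sp == "pten":
                out[sp][:, j] = state.pten
            else:
                out[sp][:, j] = getattr(state, sp)

    record(0)
    rngs = _species_rngs(settings.seed)
    par = _par_vector(model)
    flags = _flags(fb)
    m = settings.steps_per_record
    zeros = np.zeros((m, n))
    pact = state.pact if state.pact is not None else np.zeros(n)
    pmyo = state.pmyo if state.pmyo is not None else np.zeros(n)
    p5b = state.pip5k_b if state.pip5k_b is not None else np.zeros(n)
    p5u = state.pip5k_un if state.pip5k_un is not None else np.zeros(n)

    for j in range(1, n_rec + 1):
        z = {sp: rngs[sp].standard_normal((m, n)) for sp in NOISY_SPECIES}
        state.pten = _kernel.advance_chunk(
            state.ras, state.pip2, state.pkb, pact, pmyo, state.pten,
            p5b, p5u,
            z["ras"], z["pip2"], z["pkb"],
            z["pact"] if fb.actin_enabled else zeros,
            z["pmyo"] if fb.myosin_enabled else zeros,
            par, settings.dt, lattice.dx, *flags)
        state.pact = pact if fb.actin_enabled else None
        state.pmyo = pmyo if fb.myosin_enabled else None
        state.pip5k_b = p5b if fb.pip5k_enabled else None
        state.pip5k_un = p5u if fb.pip5k_enabled else None
        state.t = j * settings.record_interval
        try:
            _check_finite(state)
        except IntegrationError as e:
            raise IntegrationError(f"{e} (integration failed)") from None
        record(j)

    return Kymograph(data=out, dx=lattice.dx,
                     record_interval=settings.record_interval,
                     seed=settings.seed, model=model)
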