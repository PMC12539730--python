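"""Parameter containers for the excitable-network and polarity models.

The core model couples three membrane species on a periodic 1-D lattice:
Ras (front activator), PIP2 (back inhibitor) and PKB (slow refractory
kinase).  Ras and PIP2 mutually inhibit each other, producing the positive
feedback required for excitability; PKB is produced by Ras and degrades it,
providing the delayed negative feedback.  Cytoskeletal feedback loops
(branched actin, myosin, cortical tension, PIP5K partitioning) modulate the
Ras/PIP2 rate terms multiplicatively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Lattice",
    "StenParams",
    "FeedbackSpec",
    "ViscoParams",
    "SimSettings",
    "ModelSpec",
    "TENSION_MODES",
    "PIP5K_MODES",
]

TENSION_MODES = ("hydrolysis", "production")
PIP5K_MODES = ("bound", "unbound", "combined")


@dataclass(frozen=True)
class Lattice:
    """Periodic 1-D membrane lattice.

    ``n_points`` perimeter sites with spacing ``dx`` (μm); site ``i`` sits at
    angle ``360 * i / n_points`` degrees.  Index arithmetic wraps modulo
    ``n_points``.
    """

    n_points: int = 126
    dx: float = 0.25

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError(f"n_points must be >= 8, got {self.n_points}")
        if self.dx <= 0:
            raise ValueError(f"dx must be positive, got {self.dx}")

    @property
    def circumference(self) -> float:
        return self.n_points * self.dx

    @property
    def degrees_per_site(self) -> float:
        return 360.0 / self.n_points

    def angles(self) -> np.ndarray:
        """Angular position of every site, degrees in [0, 360)."""
        return 360.0 * np.arange(self.n_points) / self.n_points


@dataclass(frozen=True)
class StenParams:
    """Rate constants of the three-species excitable network.

    Rates follow the reaction scheme

        d[Ras]/dt  = a3/(1 + a4^2 [PIP2]^2) + a5 - (a1 + a2 [PKB]) [Ras]
        d[PIP2]/dt = b3 - (b1 + b2 [Ras]) [PIP2]
        d[PKB]/dt  = c2 [Ras] - c1 [PKB]

    plus diffusion and concentration-dependent Langevin noise of amplitude
    ``alpha * sqrt(gain + loss)`` per species.

    Notes on defaults: the published parameter table lists the PIP2 constants
    with units that identify 0.4920 μM s⁻¹ as the zero-order production rate
    and 533.5 μM⁻¹ s⁻¹ as the Ras-stimulated hydrolysis coefficient, so the
    defaults here assign ``b3 = 0.4920`` (production) and ``b2 = 533.5``
    (hydrolysis); with the roles reversed the network has no excitable
    regime at all.  Similarly the diffusivities are set so that the lateral
    inhibitor PIP2 diffuses slightly (3x) faster than the activator Ras,
    which is the configuration that supports transient travelling waves.
    ``d_fast`` keeps the table's large diffusion constant available for
    variant experiments.
    """

    a1: float = 0.0333      # basal Ras deactivation, s^-1
    a2: float = 0.7125      # PKB-stimulated Ras deactivation, uM^-1 s^-1
    a3: float = 0.2850      # PIP2-gated Ras production, uM s^-1
    a4: float = 400.0       # PIP2 sensitivity of the Ras production gate, uM^-1
    a5: float = 1.28e-4     # leak Ras production, uM s^-1
    b1: float = 0.0036      # basal PIP2 turnover, s^-1
    b2: float = 533.5       # Ras-stimulated PIP2 hydrolysis, uM^-1 s^-1
    b3: float = 0.4920      # PIP2 production, uM s^-1
    c1: float = 0.0186      # PKB decay, s^-1
    c2: float = 0.2160      # Ras-driven PKB production, s^-1
    D_ras: float = 0.0075   # um^2/s
    D_pip2: float = 0.0225  # um^2/s; lateral inhibitor, slightly faster
    D_pkb: float = 0.0075   # um^2/s
    alpha: float = 0.091    # Langevin noise scale, dimensionless
    d_fast: float = 0.225   # um^2/s; table value retained for variants

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    @property
    def max_diffusivity(self) -> float:
        return max(self.D_ras, self.D_pip2, self.D_pkb)


@dataclass(frozen=True)
class FeedbackSpec:
    """Cytoskeletal feedback architecture and strengths.

    Four loops, each independently switchable:

    * branched actin (``actin``): P_act is produced by PKB and multiplies the
      Ras production term by ``(1 + a_act * P_act)`` — local positive feedback
      at the front.
    * myosin (``myosin``): P_myo is produced by PIP2 and multiplies the Ras
      degradation term by ``(1 + a_myo * P_myo)`` — local inhibition rooted at
      the rear (model 1).
    * tension (``tension``): a single spatially uniform variable P_ten driven
      by the spatial mean of PKB; in ``hydrolysis`` mode it scales Ras
      degradation by ``(1 + a_ten * P_ten)``, in ``production`` mode it scales
      Ras production by ``1 / (1 + a_ten * P_ten)`` — global inhibition
      (model 2 and its GEF-reduction variant).
    * PIP5K (``pip5k``): two-state dynamic partitioning; Ras releases
      membrane-bound PIP5K into a fast-diffusing unbound pool, total
      conserved.  The active pool (bound, unbound or their sum) scales PIP2
      production by ``(1 + a_pip5k * active)`` (model 3).
    """

    actin_enabled: bool = False
    a_act: float = 0.0          # uM^-1
    myosin_enabled: bool = False
    a_myo: float = 0.0          # uM^-1
    tension_enabled: bool = False
    a_ten: float = 0.0          # uM^-1
    tension_mode: str = "hydrolysis"
    pip5k_enabled: bool = False
    a_pip5k: float = 4.0        # uM^-1
    pip5k_mode: str = "combined"

    # loop rate constants (s^-1 except p7/p9) and diffusivities (um^2/s)
    p1: float = 0.0125
    p2: float = 0.0125
    p3: float = 0.0125
    p4: float = 0.0125
    p5: float = 0.0125
    p6: float = 0.0125
    p7: float = 1600.0          # PIP5K release, s^-1
    p8: float = 0.05            # PIP5K rebinding, s^-1
    p9: float = 0.025           # release saturation, uM^-1
    D_pact: float = 0.0075
    D_pmyo: float = 0.0013
    D_pip5k_b: float = 6.25e-4
    D_pip5k_un: float = 0.00125

    def __post_init__(self) -> None:
        if self.tension_mode not in TENSION_MODES:
            raise ValueError(f"tension_mode must be one of {TENSION_MODES}")
        if self.pip5k_mode not in PIP5K_MODES:
            raise ValueError(f"pip5k_mode must be one of {PIP5K_MODES}")
        for name in ("a_act", "a_myo", "a_ten", "a_pip5k"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def any_enabled(self) -> bool:
        return (self.actin_enabled or self.myosin_enabled
                or self.tension_enabled or self.pip5k_enabled)

    @staticmethod
    def model1(a_act: float, a_myo: float) -> "FeedbackSpec":
        """Actin positive + myosin local negative feedback."""
        return FeedbackSpec(actin_enabled=True, a_act=a_act,
                            myosin_enabled=True, a_myo=a_myo)

    @staticmethod
    def model2(a_act: float, a_ten: float,
               mode: str = "hydrolysis") -> "FeedbackSpec":
        """Actin positive + tension global negative feedback."""
        return FeedbackSpec(actin_enabled=True, a_act=a_act,
                            tension_enabled=True, a_ten=a_ten,
                            tension_mode=mode)

    @staticmethod
    def model3(a_act: float = 1.0, a_myo: float = 0.4,
               mode: str = "combined", a_pip5k: float = 4.0) -> "FeedbackSpec":
        """Actin + myosin + two-state PIP5K partitioning."""
        return FeedbackSpec(actin_enabled=a_act > 0, a_act=a_act,
                            myosin_enabled=a_myo > 0, a_myo=a_myo,
                            pip5k_enabled=True, pip5k_mode=mode,
                            a_pip5k=a_pip5k)


@dataclass(frozen=True)
class ViscoParams:
    """Viscoelastic cell-mechanics constants for the motility model."""

    gamma_a: float = 6.09   # nN s / um^3
    gamma_c: float = 0.064  # nN s / um^3
    k_c: float = 0.98       # nN / um^3
    stress_max: float = 5.0     # nN/um, upper end of protrusive stress range
    stress_min: float = 0.5     # nN/um
    max_speed: float = 10.0     # um/min, post-hoc speed normalisation


@dataclass(frozen=True)
class SimSettings:
    """Simulation control: duration, step, recording, seed, lattice."""

    duration: float = 1200.0
    dt: float = 0.01
    record_interval: float = 1.0
    seed: int = 0
    lattice: Lattice = field(default_factory=Lattice)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be > 0 and duration >= 0")
        n_sub = self.record_interval / self.dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("record_interval must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def steps_per_record(self) -> int:
        return int(round(self.record_interval / self.dt))

    def validate_stability(self, params: StenParams) -> None:
        bound = self.lattice.dx ** 2 / (2.0 * params.max_diffusivity)
        if self.dt >= bound:
            raise ValueError(
                f"dt={self.dt} violates the diffusion stability bound "
                f"dx^2/(2 max D) = {bound:.4g}")


@dataclass(frozen=True)
class ModelSpec:
    """Full model: core excitable-network parameters + feedback loops.

    ``pip2_production_scale`` multiplies the PIP2 production rate ``b3``; it
    implements the normalised "PIP5K level" axis of the mean-field scans
    (level 1 reproduces the reference system).
    """

    sten: StenParams = field(default_factory=StenParams)
    feedback: FeedbackSpec = field(default_factory=FeedbackSpec)
    pip2_production_scale: float = 1.0

    def to_dict(self) -> dict:
        return {
            "sten": dataclasses.asdict(self.sten),
            "feedback": dataclasses.asdict(self.feedback),
            "pip2_production_scale": self.pip2_production_scale,
        }

    @staticmethod
    def from_dict(d: dict) -> "ModelSpec":
        return ModelSpec(
            sten=StenParams(**d.get("sten", {})),
            feedback=FeedbackSpec(**d.get("feedback", {})),
            pip2_production_scale=d.get("pip2_production_scale", 1.0),
        )
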