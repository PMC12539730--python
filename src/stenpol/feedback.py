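"""Cytoskeletal feedback loops: rate terms and their effect on the core
network.

Four architectures are supported (see :class:`stenpol.params.FeedbackSpec`):
branched-actin positive feedback, myosin local inhibition, tension global
inhibition (two coupling variants) and two-state PIP5K dynamic
partitioning.  The reaction terms returned here are integrated by
:mod:`stenpol.core` with the same Euler–Maruyama scheme as the core
species; the local loops (P_act, P_myo) carry reaction-based Langevin
noise, the tension scalar and the PIP5K pools are deterministic.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .params import FeedbackSpec, PIP5K_MODES

__all__ = [
    "actin_rhs",
    "myosin_rhs",
    "tension_rhs",
    "pip5k_rhs",
    "pip5k_active",
]


def actin_rhs(pact: np.ndarray, pkb: np.ndarray,
              fb: FeedbackSpec = FeedbackSpec()) -> Tuple[np.ndarray, np.ndarray]:
    """Branched-actin pool: produced by PKB, first-order turnover.

    Returns (gain, loss).  The loop closes on Ras production through the
    factor ``1 + a_act * P_act``.
    """
    return fb.p2 * np.asarray(pkb, float), fb.p1 * np.asarray(pact, float)


def myosin_rhs(pmyo: np.ndarray, pip2: np.ndarray,
               fb: FeedbackSpec = FeedbackSpec()) -> Tuple[np.ndarray, np.ndarray]:
    """Myosin pool: produced by PIP2 (a rear signal), first-order turnover.

    Returns (gain, loss).  The loop closes on Ras degradation through the
    factor ``1 + a_myo * P_myo`` — inhibition rooted at the cell rear.
    """
    return fb.p4 * np.asarray(pip2, float), fb.p3 * np.asarray(pmyo, float)


def tension_rhs(pten: float, pkb_field: np.ndarray,
                fb: FeedbackSpec = FeedbackSpec()) -> float:
    """Time derivative of the spatially uniform tension variable.

    Tension integrates the *mean* PKB level around the whole membrane, so a
    protrusion anywhere inhibits everywhere (global inhibition).
    """
    return -fb.p5 * pten + fb.p6 * float(np.mean(pkb_field))


def pip5k_rhs(pip5k_b: np.ndarray, pip5k_un: np.ndarray, ras: np.ndarray,
              fb: FeedbackSpec = FeedbackSpec()
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Two-state PIP5K exchange terms: (b_gain, b_loss, un_gain, un_loss).

    Ras releases the membrane-bound form with a saturating (Hill-type)
    rate; the unbound form rebinds at a constant rate.  The exchange terms
    are equal and opposite, so the local total is conserved by the
    reactions.
    """
    ras = np.asarray(ras, float)
    release = (fb.p7 * ras ** 2 / (1.0 + fb.p9 ** 2 * ras ** 2)
               * np.asarray(pip5k_b, float))
    rebind = fb.p8 * np.asarray(pip5k_un, float)
    return rebind, release, release, rebind


def pip5k_active(pip5k_b: np.ndarray, pip5k_un: np.ndarray,
                 mode: str) -> np.ndarray:
    """The PIP5K pool that stimulates PIP2 production under ``mode``."""
    if mode == "bound":
        return np.asarray(pip5k_b, float)
    if mode == "unbound":
        return np.asarray(pip5k_un, float)
    if mode == "combined":
        return np.asarray(pip5k_b, float) + np.asarray(pip5k_un, float)
    raise ValueError(f"pip5k mode must be one of {PIP5K_MODES}, got {mode!r}")
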