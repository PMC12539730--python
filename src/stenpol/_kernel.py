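"""Numba inner loop for the stochastic reaction-diffusion integrator.

One call advances the full state by ``m`` Euler–Maruyama steps (one
recording interval).  Gaussian increments are drawn outside (NumPy
generators, one independent stream per species) and passed in, which keeps
trajectories reproducible and makes the noise streams of the three core
species independent of which feedback loops are switched on.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# tension_mode codes
TEN_HYDROLYSIS = 0
TEN_PRODUCTION = 1
# pip5k_mode codes
P5K_BOUND = 0
P5K_UNBOUND = 1
P5K_COMBINED = 2


@njit(cache=True)
def _lap(f, dx2, out):
    n = f.shape[0]
    for i in range(n):
        out[i] = (f[(i - 1) % n] - 2.0 * f[i] + f[(i + 1) % n]) / dx2


@njit(cache=True)
def advance_chunk(ras, pip2, pkb, pact, pmyo, pten, p5b, p5u,
                  z_ras, z_pip2, z_pkb, z_pact, z_pmyo,
                  par, dt, dx,
                  actin_on, myo_on, ten_on, ten_mode, p5k_on, p5k_mode):
    """Advance all fields in place by ``z_ras.shape[0]`` steps.

    ``par`` layout: [a1 a2 a3 a4 a5 b1 b2 b3 c1 c2 D_ras D_pip2 D_pkb alpha
    a_act a_myo a_ten a_pip5k p1..p9 D_pact D_pmyo D_p5b D_p5u b3_scale]

    Returns the updated scalar P_ten (everything else is modified in place).
    """
    (a1, a2, a3, a4, a5, b1, b2, b3, c1, c2,
     D_ras, D_pip2, D_pkb, alpha,
     a_act, a_myo, a_ten, a_p5k,
     p1, p2, p3, p4, p5, p6, p7, p8, p9,
     D_pact, D_pmyo, D_p5b, D_p5u, b3_scale) = (
        par[0], par[1], par[2], par[3], par[4], par[5], par[6], par[7],
        par[8], par[9], par[10], par[11], par[12], par[13], par[14],
        par[15], par[16], par[17], par[18], par[19], par[20], par[21],
        par[22], par[23], par[24], par[25], par[26], par[27], par[28],
        par[29], par[30], par[31])

    n = ras.shape[0]
    m = z_ras.shape[0]
    dx2 = dx * dx
    sdt = np.sqrt(dt)
    lap = np.empty(n)
    new = np.empty((8, n))

    for s in range(m):
        # ---- Ras -------------------------------------------------------
        _lap(ras, dx2, lap)
        for i in range(n):
            gf = 1.0
            if actin_on:
                gf = 1.0 + a_act * pact[i]
            lf = 1.0
            if myo_on:
                lf = lf * (1.0 + a_myo * pmyo[i])
            if ten_on:
                if ten_mode == TEN_HYDROLYSIS:
                    lf = lf * (1.0 + a_ten * pten)
                else:
                    gf = gf / (1.0 + a_ten * pten)
            g = gf * (a3 / (1.0 + a4 * a4 * pip2[i] * pip2[i]) + a5)
            l = lf * (a1 + a2 * pkb[i]) * ras[i]
            new[0, i] = (ras[i] + dt * (g - l + D_ras * lap[i])
                         + sdt * alpha * np.sqrt(g + l) * z_ras[s, i])

        # ---- PIP2 ------------------------------------------------------
        _lap(pip2, dx2, lap)
        for i in range(n):
            b3f = b3_scale
            if p5k_on:
                if p5k_mode == P5K_BOUND:
                    act = p5b[i]
                elif p5k_mode == P5K_UNBOUND:
                    act = p5u[i]
                else:
                    act = p5b[i] + p5u[i]
                b3f = b3f * (1.0 + a_p5k * act)
            g = b3f * b3
            l = (b1 + b2 * ras[i]) * pip2[i]
            new[1, i] = (pip2[i] + dt * (g - l + D_pip2 * lap[i])
                         + sdt * alpha * np.sqrt(g + l) * z_pip2[s, i])

        # ---- PKB -------------------------------------------------------
        _lap(pkb, dx2, lap)
        for i in range(n):
            g = c2 * ras[i]
            l = c1 * pkb[i]
            new[2, i] = (pkb[i] + dt * (g - l + D_pkb * lap[i])
                         + sdt * alpha * np.sqrt(g + l) * z_pkb[s, i])

        # ---- P_act -----------------------------------------------------
        if actin_on:
            _lap(pact, dx2, lap)
            for i in range(n):
                g = p2 * pkb[i]
                l = p1 * pact[i]
                new[3, i] = (pact[i] + dt * (g - l + D_pact * lap[i])
                             + sdt * alpha * np.sqrt(g + l) * z_pact[s, i])

        # ---- P_myo -----------------------------------------------------
        if myo_on:
            _lap(pmyo, dx2, lap)
            for i in range(n):
                g = p4 * pip2[i]
                l = p3 * pmyo[i]
                new[4, i] = (pmyo[i] + dt * (g - l + D_pmyo * lap[i])
                             + sdt * alpha * np.sqrt(g + l) * z_pmyo[s, i])

        # ---- P_ten (deterministic scalar) ------------------------------
        if ten_on:
            kmean = 0.0
            for i in range(n):
                kmean += pkb[i]
            kmean /= n
            pten = pten + dt * (-p5 * pten + p6 * kmean)

        # ---- PIP5K two-state exchange (exact) + diffusion --------------
        if p5k_on:
            _lap(p5b, dx2, lap)
            for i in range(n):
                new[5, i] = p5b[i] + dt * D_p5b * lap[i]
            _lap(p5u, dx2, lap)
            for i in range(n):
                new[6, i] = p5u[i] + dt * D_p5u * lap[i]
            for i in range(n):
                r = p7 * ras[i] * ras[i] / (1.0 + p9 * p9 * ras[i] * ras[i])
                srate = r + p8
                tot = new[5, i] + new[6, i]
                beq = p8 / srate * tot
                b_new = beq + (new[5, i] - beq) * np.exp(-srate * dt)
                new[5, i] = b_new
                new[6, i] = tot - b_new

        # ---- commit with clipping at zero ------------------------------
        # (written so that a NaN propagates instead of being clipped away)
        for i in range(n):
            ras[i] = 0.0 if new[0, i] < 0.0 else new[0, i]
            pip2[i] = 0.0 if new[1, i] < 0.0 else new[1, i]
            pkb[i] = 0.0 if new[2, i] < 0.0 else new[2, i]
        if actin_on:
            for i in range(n):
                pact[i] = 0.0 if new[3, i] < 0.0 else new[3, i]
        if myo_on:
            for i in range(n):
                pmyo[i] = 0.0 if new[4, i] < 0.0 else new[4, i]
        if p5k_on:
            for i in range(n):
                p5b[i] = 0.0 if new[5, i] < 0.0 else new[5, i]
                p5u[i] = 0.0 if new[6, i] < 0.0 else new[6, i]

    return pten
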