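"""Compiled Gillespie loops for the well-mixed and lattice tissue engines.

The kernels implement exactly the same event algebra as the step-level
functions in :mod:`fieldsim.model_core` and :mod:`fieldsim.spatial`; they
exist so that whole runs to a 10^9-cell detection threshold finish in
seconds.  All randomness comes from numba's internal Mersenne generator,
seeded once per kernel call with a 31-bit integer, so every run replays
bit-identically from its seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# phase exit codes
OK = 0
CENSORED = 1
FROZEN = 2
REDRAW_EXCEEDED = 3

REDRAW_CAP = 10_000


@njit(cache=True)
def _draw_daughter(n0, n1, ns1, r0, r1, rs1, mu1, mus1, mus):
    """Draw the cell type filling a vacancy, given candidate counts.

    Counts are the whole tissue in the well-mixed model or the dead
    cell's neighbourhood on the lattice.  A malignant (Type S) birth
    does not fill the vacancy: the draw repeats and the number of
    malignant births in the step is returned alongside the daughter.

    Returns (daughter, s_births): daughter in {0, 1, 2}, or -1 if the
    redraw cap was exhausted, or -2 if no cell can divide (F == 0).
    """
    F = r0 * n0 + r1 * n1 + rs1 * ns1
    if F <= 0.0:
        return -2, 0
    p0 = r0 * n0 * (1.0 - mu1) / F
    p1 = (r1 * n1 * (1.0 - mus1) + r0 * n0 * mu1) / F
    p2 = (rs1 * ns1 * (1.0 - mus) + r1 * n1 * mus1) / F
    births = 0
    for _ in range(REDRAW_CAP):
        u = np.random.random()
        if u < p0:
            return 0, births
        elif u < p0 + p1:
            return 1, births
        elif u < p0 + p1 + p2:
            return 2, births
        births += 1
    return -1, births


@njit(cache=True)
def well_mixed_phase(seed, N, d, r0, r1, rs1, rS, dS, mu1, mus1, mus,
                     threshold, switch_count, t_limit, X0, X1, XS1, XS):
    """Run one detection phase of the well-mixed hybrid model.

    Alternates tissue turnover with stochastic malignant birth/death
    until the malignant count XS reaches ``threshold`` or ``t_limit``
    elapses.  Once XS reaches ``switch_count`` (and the clone is
    supercritical) the remaining growth is exponential-deterministic
    while tissue turnover keeps running for that interval.

    Returns (status, t_end, X0, X1, XS1, XS).
    """
    np.random.seed(seed)
    t = 0.0
    dN = d * N
    while True:
        total = dN + (rS + dS) * XS
        if total <= 0.0:
            return FROZEN, t, X0, X1, XS1, XS
        t += np.random.exponential(1.0 / total)
        if t >= t_limit:
            return CENSORED, t_limit, X0, X1, XS1, XS
        u = np.random.random() * total
        if u < dN:
            v = np.random.random() * N
            if v < X0:
                dying = 0
            elif v < X0 + X1:
                dying = 1
            else:
                dying = 2
            daughter, births = _draw_daughter(X0, X1, XS1,
                                              r0, r1, rs1, mu1, mus1, mus)
            if daughter == -1:
                return REDRAW_EXCEEDED, t, X0, X1, XS1, XS
            if daughter == -2:
                return FROZEN, t, X0, X1, XS1, XS
            XS += births
            if dying == 0:
                X0 -= 1
            elif dying == 1:
                X1 -= 1
            else:
                XS1 -= 1
            if daughter == 0:
                X0 += 1
            elif daughter == 1:
                X1 += 1
            else:
                XS1 += 1
        elif u < dN + rS * XS:
            XS += 1.0
        else:
            XS -= 1.0
        if XS >= switch_count and rS > dS:
            # deterministic exponential growth to the threshold; the
            # tissue keeps turning over during that interval
            dt_s = np.log(threshold / XS) / (rS - dS)
            t_detect = t + dt_s
            if t_detect >= t_limit:
                dt_s = t_limit - t
            if dN > 0.0:
                tt = 0.0
                while True:
                    tt += np.random.exponential(1.0 / dN)
                    if tt >= dt_s:
                        break
                    v = np.random.random() * N
                    if v < X0:
                        dying = 0
                    elif v < X0 + X1:
                        dying = 1
                    else:
                        dying = 2
                    daughter, _ = _draw_daughter(X0, X1, XS1,
                                                 r0, r1, rs1, mu1, mus1, mus)
                    if daughter == -1:
                        return REDRAW_EXCEEDED, t + tt, X0, X1, XS1, XS
                    if daughter == -2:
                        return FROZEN, t + tt, X0, X1, XS1, XS
                    if dying == 0:
                        X0 -= 1
                    elif dying == 1:
                        X1 -= 1
                    else:
                        XS1 -= 1
                    if daughter == 0:
                        X0 += 1
                    elif daughter == 1:
                        X1 += 1
                    else:
                        XS1 += 1
            if t + dt_s >= t_limit:
                return CENSORED, t_limit, X0, X1, XS1, XS
            return OK, t_detect, X0, X1, XS1, threshold
        if XS >= threshold:
            return OK, t, X0, X1, XS1, XS


@njit(cache=True)
def spatial_phase(seed, grid, I, J, d, r0, r1, rs1, rS, dS, mu1, mus1, mus,
                  threshold, switch_count, t_limit, XS):
    """Run one detection phase of the lattice model.

    ``grid`` is a flat int8 array of length I*J holding cell-type codes
    {0, 1, 2} (2 encodes Type S-1); it is updated in place so the
    tissue persists across surgery.  Malignant cells live off-lattice
    in the scalar count XS.  Death sites are uniform over the lattice;
    the vacancy is filled by a fitness-weighted draw over the von
    Neumann neighbours only (wall boundary: no wraparound).

    Returns (status, t_end, XS).
    """
    np.random.seed(seed)
    N = I * J
    t = 0.0
    dN = d * N
    while True:
        total = dN + (rS + dS) * XS
        if total <= 0.0:
            return FROZEN, t, XS
        t += np.random.exponential(1.0 / total)
        if t >= t_limit:
            return CENSORED, t_limit, XS
        u = np.random.random() * total
        if u < dN:
            idx = np.random.randint(0, N)
            i = idx // J
            j = idx % J
            n0 = 0
            n1 = 0
            ns1 = 0
            if i > 0:
                c = grid[idx - J]
                if c == 0:
                    n0 += 1
                elif c == 1:
                    n1 += 1
                else:
                    ns1 += 1
            if i < I - 1:
                c = grid[idx + J]
                if c == 0:
                    n0 += 1
                elif c == 1:
                    n1 += 1
                else:
                    ns1 += 1
            if j > 0:
                c = grid[idx - 1]
                if c == 0:
                    n0 += 1
                elif c == 1:
                    n1 += 1
                else:
                    ns1 += 1
            if j < J - 1:
                c = grid[idx + 1]
                if c == 0:
                    n0 += 1
                elif c == 1:
                    n1 += 1
                else:
                    ns1 += 1
            daughter, births = _draw_daughter(n0, n1, ns1,
                                              r0, r1, rs1, mu1, mus1, mus)
            if daughter == -1:
                return REDRAW_EXCEEDED, t, XS
            if daughter == -2:
                return FROZEN, t, XS
            XS += births
            grid[idx] = daughter
        elif u < dN + rS * XS:
            XS += 1.0
        else:
            XS -= 1.0
        if XS >= switch_count and rS > dS:
            dt_s = np.log(threshold / XS) / (rS - dS)
            t_detect = t + dt_s
            if t_detect >= t_limit:
                dt_s = t_limit - t
            if dN > 0.0:
                tt = 0.0
                while True:
                    tt += np.random.exponential(1.0 / dN)
                    if tt >= dt_s:
                        break
                    idx = np.random.randint(0, N)
                    i = idx // J
                    j = idx % J
                    n0 = 0
                    n1 = 0
                    ns1 = 0
                    if i > 0:
                        c = grid[idx - J]
                        if c == 0:
                            n0 += 1
                        elif c == 1:
                            n1 += 1
                        else:
                            ns1 += 1
                    if i < I - 1:
                        c = grid[idx + J]
                        if c == 0:
                            n0 += 1
                        elif c == 1:
                            n1 += 1
                        else:
                            ns1 += 1
                    if j > 0:
                        c = grid[idx - 1]
                        if c == 0:
                            n0 += 1
                        elif c == 1:
                            n1 += 1
                        else:
                            ns1 += 1
                    if j < J - 1:
                        c = grid[idx + 1]
                        if c == 0:
                            n0 += 1
                        elif c == 1:
                            n1 += 1
                        else:
                            ns1 += 1
                    daughter, _ = _draw_daughter(n0, n1, ns1,
                                                 r0, r1, rs1, mu1, mus1, mus)
                    if daughter == -1:
                        return REDRAW_EXCEEDED, t + tt, XS
                    if daughter == -2:
                        return FROZEN, t + tt, XS
                    grid[idx] = daughter
            if t + dt_s >= t_limit:
                return CENSORED, t_limit, XS
            return OK, t_detect, threshold
        if XS >= threshold:
            return OK, t, XS


@njit(cache=True)
def birth_death_passage(seed, x0, rS, dS, target):
    """First-passage of a linear birth-death process from x0 to target.

    Returns (reached, t): reached is False when the clone went extinct
    before hitting the target.
    """
    np.random.seed(seed)
    x = x0
    t = 0.0
    while 0 < x < target:
        total = (rS + dS) * x
        t += np.random.exponential(1.0 / total)
        if np.random.random() * total < rS * x:
            x += 1
        else:
            x -= 1
    return x >= target, t
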