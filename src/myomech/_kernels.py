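"""Compiled inner loops for the cell-model stepping.

The numba JIT path is an exact transcription of
``ReducedCellModel.step_array``; a numpy fallback keeps the package usable
without numba.  Both paths are cross-checked in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore[misc]
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap


# parameter vector layout (must match ReducedCellModel._pvec)
(PG_NA, PE_NA, PG_K, PE_K, PG_L, PE_L, PK_REL, PK_UP, PV_CA, PKS_CA,
 PK_CA, PF0, PFP, PHP, PHM, PG0, PCA_TH) = range(17)


@njit(cache=True)
def _vtrap_s(x: float, y: float) -> float:
    xr = x / y
    if xr > 50.0:
        xr = 50.0
    elif xr < -50.0:
        xr = -50.0
    if abs(xr) < 1e-6:
        return y * (1.0 - xr / 2.0)
    return x / math.expm1(xr)


@njit(cache=True)
def advance_cells(Y, dt, n_steps, stim, cm, P):
    """Advance every row of Y (cells x 8 states) by n_steps of dt, in place.

    stim is the per-cell constant stimulus current over the block; cm the
    membrane capacitance (scalar, uF/cm^2).
    """
    n = Y.shape[0]
    for _ in range(n_steps):
        for i in range(n):
            V = Y[i, 0]
            # gate rates
            am = 0.1 * _vtrap_s(-(V + 40.0), 10.0)
            bm = 4.0 * math.exp(-(V + 65.0) / 18.0)
            ah = 0.07 * math.exp(-(V + 65.0) / 20.0)
            bh = 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))
            an = 0.01 * _vtrap_s(-(V + 55.0), 10.0)
            bn = 0.125 * math.exp(-(V + 65.0) / 80.0)
            # Rush-Larsen gate update
            tm = 1.0 / (am + bm)
            Y[i, 1] = am * tm + (Y[i, 1] - am * tm) * math.exp(-dt / tm)
            th = 1.0 / (ah + bh)
            Y[i, 2] = ah * th + (Y[i, 2] - ah * th) * math.exp(-dt / th)
            tn = 1.0 / (an + bn)
            Y[i, 3] = an * tn + (Y[i, 3] - an * tn) * math.exp(-dt / tn)
            # implicit-Euler membrane voltage
            gna = P[PG_NA] * Y[i, 1] ** 3 * Y[i, 2]
            gk = P[PG_K] * Y[i, 3] ** 4
            gtot = gna + gk + P[PG_L]
            erev = gna * P[PE_NA] + gk * P[PE_K] + P[PG_L] * P[PE_L]
            V = (V + dt / cm * (stim[i] + erev)) / (1.0 + dt / cm * gtot)
            Y[i, 0] = V
            # implicit calcium with release at updated V
            rel = P[PK_REL] / (1.0 + math.exp(-(V - P[PV_CA]) / P[PKS_CA]))
            ca = (Y[i, 4] + dt * rel) / (1.0 + dt * P[PK_UP])
            Y[i, 4] = ca
            # explicit crossbridge pools (Ca dead zone: no cycling at rest)
            cc = ca - P[PCA_TH]
            if cc < 0.0:
                cc = 0.0
            f = P[PF0] * cc * cc / (cc * cc + P[PK_CA] * P[PK_CA])
            D = Y[i, 5]
            A1 = Y[i, 6]
            A2 = Y[i, 7]
            Y[i, 5] = D + dt * (-f * D + P[PFP] * A1 + P[PG0] * A2)
            Y[i, 6] = A1 + dt * (f * D - (P[PFP] + P[PHP]) * A1
                                 + P[PHM] * A2)
            Y[i, 7] = A2 + dt * (P[PHP] * A1 - (P[PHM] + P[PG0]) * A2)


def advance_cells_numpy(model, Y, dt, n_steps, stim, cm):
    """Pure-numpy fallback with identical semantics."""
    for _ in range(n_steps):
        model.step_array(Y, dt, stim, cm)
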