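"""Compiled right-hand-side and Jacobian kernels for the trans-Golgi model.

The ODE stepper calls the vector field thousands of times per solve, so the
kernels take a single packed parameter vector and are numba-compiled when
numba is available; the pure-numpy implementations double as fallback and
as an independent cross-check in the tests.

Packed parameter layout (length 29)::

    p[0:12]   k1..k12          interaction rate constants (linear scale)
    p[12:17]  b_PKD*u0, b_CERT*u1, b_PI4K*u2, b_DAG, b_CER
    p[17:26]  degradation rates, state order
    p[26:29]  pool_cer, pool_pc, pool_pi
"""

from __future__ import annotations

import numpy as np


def rhs_py(t, x, p):
    PKD, PKDa, CERT, CERTa, PI4K, PI4Ka, PI4P, DAG, CER = x
    v1 = p[0] * DAG * PKD
    v2 = p[1] * PKDa
    v3 = p[2] * PKDa * PI4K
    v4 = p[3] * PI4Ka
    v5 = p[4] * PKDa * CERTa
    v6 = p[5] * PI4Ka * p[28]
    v7 = p[6] * PI4P * CERT
    v8 = p[7] * CERTa
    v9 = p[8] * CERTa * p[26]
    v10 = p[9] * PKDa * DAG
    v11 = p[10] * CER * p[27]
    v12 = p[11] * PI4P
    out = np.empty(9)
    out[0] = p[12] - v1 + v2 - p[17] * PKD
    out[1] = v1 - v2 - p[18] * PKDa
    out[2] = p[13] - v7 + v5 + v8 - p[19] * CERT
    out[3] = v7 - v5 - v8 - p[20] * CERTa
    out[4] = p[14] - v3 + v4 - p[21] * PI4K
    out[5] = v3 - v4 - p[22] * PI4Ka
    out[6] = v6 - v12 - p[23] * PI4P
    out[7] = p[15] + v11 - v10 - p[24] * DAG
    out[8] = p[16] + v9 - v11 - p[25] * CER
    return out


def jac_py(t, x, p):
    PKD, PKDa, CERT, CERTa, PI4K, PI4Ka, PI4P, DAG, CER = x
    J = np.zeros((9, 9))
    J[0, 0] = -p[0] * DAG - p[17]
    J[0, 1] = p[1]
    J[0, 7] = -p[0] * PKD
    J[1, 0] = p[0] * DAG
    J[1, 1] = -p[1] - p[18]
    J[1, 7] = p[0] * PKD
    J[2, 1] = p[4] * CERTa
    J[2, 2] = -p[6] * PI4P - p[19]
    J[2, 3] = p[4] * PKDa + p[7]
    J[2, 6] = -p[6] * CERT
    J[3, 1] = -p[4] * CERTa
    J[3, 2] = p[6] * PI4P
    J[3, 3] = -p[4] * PKDa - p[7] - p[20]
    J[3, 6] = p[6] * CERT
    J[4, 1] = -p[2] * PI4K
    J[4, 4] = -p[2] * PKDa - p[21]
    J[4, 5] = p[3]
    J[5, 1] = p[2] * PI4K
    J[5, 4] = p[2] * PKDa
    J[5, 5] = -p[3] - p[22]
    J[6, 5] = p[5] * p[28]
    J[6, 6] = -p[11] - p[23]
    J[7, 1] = -p[9] * DAG
    J[7, 7] = -p[9] * PKDa - p[24]
    J[7, 8] = p[10] * p[27]
    J[8, 3] = p[8] * p[26]
    J[8, 8] = -p[10] * p[27] - p[25]
    return J


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    rhs = njit(cache=True)(rhs_py)
    jac = njit(cache=True)(jac_py)
    HAVE_NUMBA = True
except Exception:  # numba absent or compilation refused
    rhs, jac = rhs_py, jac_py
    HAVE_NUMBA = False
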