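"""JIT-compiled inner loop for the online plasticity recursion.

The arithmetic here mirrors :func:`mblda.online.step` operation-for-operation
(same expressions, same order) so the compiled path and the pure-Python
reference path produce identical floating-point trajectories.
"""

import numpy as np
from numba import njit

VARIANT_STANDARD = 0
VARIANT_FIXED_ELL = 1
VARIANT_GRADED_DAN = 2


@njit(cache=False)
def run_stream(
    X,
    Y,
    w,
    mu0,
    b,
    zeta,
    ell,
    t,
    eta0,
    gamma,
    variant,
    ell_star,
    fixed_ell_bias,
    c_out,
    z_out,
    ell_out,
    eta_out,
):
    T, n = X.shape
    for i in range(T):
        x = X[i]
        y = Y[i]
        c = np.dot(w, x)
        z = c - b
        if z < 0.0:
            z = 0.0
        t += 1
        eta = eta0 / (1.0 + gamma * t)
        c_out[i] = c
        z_out[i] = z
        ell_out[i] = ell
        eta_out[i] = eta
        inv_t = 1.0 / t
        if y == 0.0:
            # DAN silent: homeostatic branch, in printed order
            # (statistics, then bias, then weights, then the counter).
            for j in range(n):
                mu0[j] = mu0[j] + inv_t * (x[j] - mu0[j])
            zeta = zeta + inv_t * (c - zeta)
            b = b + inv_t * (0.5 * c - b)
            cz = c - zeta
            for j in range(n):
                w[j] = w[j] + eta * (mu0[j] - cz * (x[j] - mu0[j]))
            ell = ell + 1
        else:
            # DAN active: one-sided depression scaled by elapsed time.
            ell_w = float(ell)
            ell_b = float(ell)
            if variant == VARIANT_FIXED_ELL:
                ell_w = ell_star
                if fixed_ell_bias:
                    ell_b = ell_star
            b = b + inv_t * (0.5 * ell_b * c - np.log(ell_b) - b)
            scale = eta * ell_w
            if variant == VARIANT_GRADED_DAN:
                scale = scale * y
            for j in range(n):
                w[j] = w[j] - scale * x[j]
            ell = 1
    return b, zeta, ell, t
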