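"""Compiled O(N^2) pair-sum kernel for the dipolar flow field.

Writes the dipole of swimmer j as the holomorphic conjugate complex velocity
f_j(z) = (If/pi) exp(i theta_j) / (z - z_j)^2, so that the velocity at z is
conj(f_j(z)) and the ambient-flow Jacobian follows from f_j'(z).  The kernel
accumulates, per swimmer i, the flow velocity, the projected Jacobian term
Omega_i = -(Re S sin 2theta_i + Im S cos 2theta_i) with S = sum_j f_j'(z_i),
and the global minimum pair distance for singularity checks.

Serial loop with a fixed accumulation order: runs are bitwise reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def dipole_pair_sums(x, theta, pref):
    n = x.shape[0]
    flow = np.zeros((n, 2))
    omega = np.zeros(n)
    ct = np.cos(theta)
    st = np.sin(theta)
    r2min = 1e300
    for i in range(n):
        fx = 0.0
        fy = 0.0
        sa = 0.0
        sb = 0.0
        xi0 = x[i, 0]
        xi1 = x[i, 1]
        for j in range(n):
            if j == i:
                continue
            dx = xi0 - x[j, 0]
            dy = xi1 - x[j, 1]
            r2 = dx * dx + dy * dy
            if r2 < r2min:
                r2min = r2
            inv_r4 = 1.0 / (r2 * r2)
            # velocity: pref * exp(-i theta_j) * z^2 / r^4, z = dx + i dy
            z2r = dx * dx - dy * dy
            z2i = 2.0 * dx * dy
            fx += (ct[j] * z2r + st[j] * z2i) * inv_r4
            fy += (ct[j] * z2i - st[j] * z2r) * inv_r4
            # f'(z_i) = -2 pref exp(i theta_j) conj(z)^3 / r^6
            c3r = dx * (dx * dx - 3.0 * dy * dy)
            c3i = -dy * (3.0 * dx * dx - dy * dy)
            inv_r6 = inv_r4 / r2
            sa += (ct[j] * c3r - st[j] * c3i) * inv_r6
            sb += (ct[j] * c3i + st[j] * c3r) * inv_r6
        flow[i, 0] = pref * fx
        flow[i, 1] = pref * fy
        omega[i] = 2.0 * pref * (sa * np.sin(2.0 * theta[i])
                                 + sb * np.cos(2.0 * theta[i]))
    return flow, omega, np.sqrt(r2min)
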