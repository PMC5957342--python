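"""Compiled inner loops for the Langevin integrator.

The BAOAB step and the pairwise force evaluation are the only hot paths
in the package; they are jitted with numba.  Every Hamiltonian that wants
the fast path exposes ``kernel_args()`` returning the flat parameter pack
consumed here; anything else falls back to the pure-Python loop in
:mod:`densassign.toy_model`, which computes identical trajectories.

Force modes
-----------
0  plain site potential (full LJ + Coulomb)
1  relative alchemical transformation (both end states soft-cored)
2  decouple_coulomb (full LJ, soft-cored scaled Coulomb)
3  decouple_lj (soft-cored scaled LJ, charges off)
4  restraint_on (full interactions; the lambda-scaled restraint enters
   through the pre-scaled restraint constant)
5  harmonic only (cage/restraint terms, no centers)

A particle landing exactly on a singular core produces a non-finite
force; the loop aborts and reports the offending step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["baoab_run"]


@njit(cache=False)
def _pair_force(r, eps, sig6, qq):
    """dU/dd of one LJ+Coulomb pair at distance r (no soft core)."""
    inv6 = sig6 / r**6
    return (4.0 * eps * (-12.0 * inv6 * inv6 + 6.0 * inv6) - qq / r) / r


@njit(cache=False)
def _force(
    x, f, centers, epsA, sig6A, qqA, epsB, sig6B, qqB,
    padA, padB, lam, mode, cage_k, site_center, rest_k, rest_c,
):
    for i in range(3):
        f[i] = -cage_k * (x[i] - site_center[i]) - rest_k * (x[i] - rest_c[i])
    n = centers.shape[0]
    if mode == 5 or n == 0:
        return
    for j in range(n):
        dx0 = x[0] - centers[j, 0]
        dx1 = x[1] - centers[j, 1]
        dx2 = x[2] - centers[j, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        r = np.sqrt(r2)
        du_dr = 0.0
        if mode == 0 or mode == 4:
            if epsA[j] == 0.0 and qqA[j] == 0.0:
                continue
            if r == 0.0:
                f[0] = np.inf
                return
            du_dr = _pair_force(r, epsA[j], sig6A[j], qqA[j])
        elif mode == 1:
            r6 = r2 * r2 * r2
            have_a = epsA[j] != 0.0 or qqA[j] != 0.0
            have_b = epsB[j] != 0.0 or qqB[j] != 0.0
            if not (have_a or have_b):
                continue
            r5 = r2 * r2 * r
            if have_a and lam < 1.0:
                dA = (padA + r6) ** (1.0 / 6.0)
                if dA == 0.0:
                    f[0] = np.inf
                    return
                dAr = r5 / dA**5
                du_dr += (1.0 - lam) * _pair_force(dA, epsA[j], sig6A[j], qqA[j]) * dAr
            if have_b and lam > 0.0:
                dB = (padB + r6) ** (1.0 / 6.0)
                if dB == 0.0:
                    f[0] = np.inf
                    return
                dBr = r5 / dB**5
                du_dr += lam * _pair_force(dB, epsB[j], sig6B[j], qqB[j]) * dBr
        elif mode == 2:
            if epsA[j] != 0.0:
                if r == 0.0:
                    f[0] = np.inf
                    return
                du_dr += _pair_force(r, epsA[j], sig6A[j], 0.0)
            if qqA[j] != 0.0 and lam < 1.0:
                r6 = r2 * r2 * r2
                dA = (padA + r6) ** (1.0 / 6.0)
                if dA == 0.0:
                    f[0] = np.inf
                    return
                dAr = (r2 * r2 * r) / dA**5
                du_dr += (1.0 - lam) * (-qqA[j] / dA**2) * dAr
        else:  # mode 3
            if epsA[j] == 0.0 or lam >= 1.0:
                continue
            r6 = r2 * r2 * r2
            dA = (padA + r6) ** (1.0 / 6.0)
            if dA == 0.0:
                f[0] = np.inf
                return
            dAr = (r2 * r2 * r) / dA**5
            du_dr += (1.0 - lam) * _pair_force(dA, epsA[j], sig6A[j], 0.0) * dAr
        if r > 0.0:
            scale = du_dr / r
            f[0] -= scale * dx0
            f[1] -= scale * dx1
            f[2] -= scale * dx2
        # r == 0 with soft-cored terms: direction degenerate, force 0


@njit(cache=False)
def baoab_run(
    x, v, noise, dt, mass, c1, c2, half, stride,
    centers, epsA, sig6A, qqA, epsB, sig6B, qqB,
    padA, padB, lam, mode, cage_k, site_center, rest_k, rest_c,
    rec_pos, rec_times,
):
    """Integrate the full trajectory in one call.

    Returns 0 on success, or the (1-based) step at which the force became
    non-finite.
    """
    n_steps = noise.shape[0]
    f = np.zeros(3)
    _force(x, f, centers, epsA, sig6A, qqA, epsB, sig6B, qqB,
           padA, padB, lam, mode, cage_k, site_center, rest_k, rest_c)
    for i in range(3):
        if not np.isfinite(f[i]):
            return -1
    half_dt = 0.5 * dt
    k = 0
    for step in range(1, n_steps + 1):
        for i in range(3):
            v[i] += half_dt / mass * f[i]
            x[i] += half_dt * v[i]
            if x[i] > half:
                x[i] = 2.0 * half - x[i]
                v[i] = -v[i]
            elif x[i] < -half:
                x[i] = -2.0 * half - x[i]
                v[i] = -v[i]
            v[i] = c1 * v[i] + c2 * noise[step - 1, i]
            x[i] += half_dt * v[i]
            if x[i] > half:
                x[i] = 2.0 * half - x[i]
                v[i] = -v[i]
            elif x[i] < -half:
                x[i] = -2.0 * half - x[i]
                v[i] = -v[i]
        _force(x, f, centers, epsA, sig6A, qqA, epsB, sig6B, qqB,
               padA, padB, lam, mode, cage_k, site_center, rest_k, rest_c)
        for i in range(3):
            if not np.isfinite(f[i]):
                return step
            v[i] += half_dt / mass * f[i]
        if step % stride == 0:
            for i in range(3):
                rec_pos[k, i] = x[i]
            rec_times[k] = step * dt
            k += 1
    return 0
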