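"""Compiled incremental-ratio kernel for the truncated N-mixture sum.

Implements the fast backend literally: the first term of the truncated sum
(at N0 = max y) is evaluated with full log pmfs, and every later term is
the previous one plus the closed-form log pmf ratios — one abundance ratio
and J detection ratios per step, all cheap arithmetic and table lookups.
The log-sum over terms is two-pass: record each log term and the running
maximum, then sum exp(term - max), skipping terms more than 45 log-units
below the maximum (relative contribution < 1e-19).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["nmix_fast"]


@njit(cache=True)
def nmix_fast(y, p, lam, K, within_bb, between_nb, theta_w, theta_b):
    S, J = y.shape
    out = np.empty(S)

    log_int = np.empty(K + 2)
    log_int[0] = 0.0
    for m in range(1, K + 2):
        log_int[m] = math.log(m)

    # abundance log ratio f(n+1)/f(n), the part that depends only on n
    lr_ab = np.empty(K)
    for n in range(K):
        if between_nb:
            lr_ab[n] = math.log(n + theta_b) - log_int[n + 1]
        else:
            lr_ab[n] = -log_int[n + 1]

    buf = np.empty(K + 1)
    cj = np.empty(J)  # per-visit constants hoisted out of the N loop
    for i in range(S):
        ymax = 0
        for j in range(J):
            if y[i, j] > ymax:
                ymax = y[i, j]

        # per-site constant of the abundance ratio
        if between_nb:
            ab_const = math.log(lam[i] / (lam[i] + theta_b))
        else:
            ab_const = math.log(lam[i])

        # anchor: full log pmfs at N0 = ymax
        if between_nb:
            t = (
                math.lgamma(ymax + theta_b)
                - math.lgamma(theta_b)
                - math.lgamma(ymax + 1.0)
                + theta_b * math.log(theta_b / (theta_b + lam[i]))
                + ymax * math.log(lam[i] / (theta_b + lam[i]))
            )
        else:
            t = ymax * math.log(lam[i]) - lam[i] - math.lgamma(ymax + 1.0)
        for j in range(J):
            yij = y[i, j]
            lc = (
                math.lgamma(ymax + 1.0)
                - math.lgamma(yij + 1.0)
                - math.lgamma(ymax - yij + 1.0)
            )
            if within_bb:
                a = p[i, j] * theta_w
                b = (1.0 - p[i, j]) * theta_w
                t += lc + (
                    math.lgamma(yij + a)
                    + math.lgamma(ymax - yij + b)
                    - math.lgamma(ymax + theta_w)
                ) - (
                    math.lgamma(a)
                    + math.lgamma(b)
                    - math.lgamma(theta_w)
                )
            else:
                t += (
                    lc
                    + yij * math.log(p[i, j])
                    + (ymax - yij) * math.log1p(-p[i, j])
                )

        buf[ymax] = t
        mx = t
        if within_bb:
            for j in range(J):
                cj[j] = (1.0 - p[i, j]) * theta_w  # beta shape b_ij
            for n in range(ymax, K):
                step = ab_const + lr_ab[n] + J * (
                    log_int[n + 1] - math.log(n + theta_w)
                )
                for j in range(J):
                    yij = y[i, j]
                    step += math.log(n - yij + cj[j]) - log_int[n + 1 - yij]
                t += step
                buf[n + 1] = t
                if t > mx:
                    mx = t
        else:
            c = 0.0
            for j in range(J):
                c += math.log1p(-p[i, j])
            for n in range(ymax, K):
                step = ab_const + lr_ab[n] + J * log_int[n + 1] + c
                for j in range(J):
                    step -= log_int[n + 1 - y[i, j]]
                t += step
                buf[n + 1] = t
                if t > mx:
                    mx = t

        s = 0.0
        for n in range(ymax, K + 1):
            d = buf[n] - mx
            if d > -45.0:
                s += math.exp(d)
        out[i] = mx + math.log(s)
    return out
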