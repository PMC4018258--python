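"""Compiled per-probe EM engine.

A row-by-row mirror of the reference numpy EM in :mod:`icdmr.mixture`:
identical deterministic median-split start and identical E/M updates, so
both engines follow the same parameter trajectory and land in the same
local optimum for every probe.  For speed the log-likelihood (used only
by the stopping rule) is evaluated every ``_CHECK_EVERY`` sweeps, so the
relative-change criterion is measured over that span — a slightly
stricter stop than the sweep-by-sweep check, never a looser one.

The fit from a single deterministic start is deliberate: the
two-component likelihood on non-differential probes has many local maxima
(tail-splitting solutions with extreme mixing weights can score higher),
and the fixed start keeps the per-probe solutions — and hence the null
concordance distribution — stable and reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PI_CLIP = 1e-10
_CHECK_EVERY = 8


@njit(cache=True, error_model="numpy")
def em_fit_rows(V, tol, max_iter, floor_scale):
    """Plain EM over every row of V; returns per-row parameter arrays."""
    t, n = V.shape
    out_pi = np.empty(t)
    out_mu_u = np.empty(t)
    out_mu_m = np.empty(t)
    out_s2 = np.empty(t)
    out_ll = np.empty(t)
    out_conv = np.zeros(t, dtype=np.bool_)
    out_iter = np.zeros(t, dtype=np.int64)

    half = n // 2
    for d in range(t):
        v = V[d]
        sv = 0.0
        sv2 = 0.0
        for j in range(n):
            sv += v[j]
            sv2 += v[j] * v[j]
        mean = sv / n
        rowvar = sv2 / n - mean * mean
        if rowvar < 0.0:
            rowvar = 0.0
        floor = floor_scale * (rowvar + 1e-12)

        # deterministic start: median split, means of the halves
        vs = np.sort(v)
        mu_u = 0.0
        for j in range(half):
            mu_u += vs[j]
        mu_u /= half
        mu_m = 0.0
        for j in range(half, n):
            mu_m += vs[j]
        mu_m /= n - half
        pi = 0.5
        ss = 0.0
        for j in range(half):
            ss += (vs[j] - mu_u) ** 2
        for j in range(half, n):
            ss += (vs[j] - mu_m) ** 2
        s2 = ss / n
        if s2 < floor:
            s2 = floor
        if s2 <= 0.0:
            s2 = 1e-300

        ll_old = -np.inf
        ll = -np.inf
        converged = False
        it = 0
        while it < max_iter and not converged:
            with_ll = (it + 1) % _CHECK_EVERY == 0 or it == max_iter - 1

            pi_c = pi
            if pi_c < _PI_CLIP:
                pi_c = _PI_CLIP
            elif pi_c > 1.0 - _PI_CLIP:
                pi_c = 1.0 - _PI_CLIP
            a = (mu_m - mu_u) / s2
            mid = 0.5 * (mu_m + mu_u)
            b = np.log(pi_c / (1.0 - pi_c))
            inv2 = 1.0 / (2.0 * s2)

            sg = 0.0
            sgv = 0.0
            sgv2 = 0.0
            acc = 0.0
            if with_ll:
                for j in range(n):
                    x = v[j]
                    z = b + (x - mid) * a
                    if z > 0.0:
                        e = np.exp(-z)
                        g = 1.0 / (1.0 + e)
                        acc += z + np.log1p(e)
                    else:
                        e = np.exp(z)
                        g = e / (1.0 + e)
                        acc += np.log1p(e)
                    du = x - mu_u
                    acc -= du * du * inv2
                    sg += g
                    gv = g * x
                    sgv += gv
                    sgv2 += gv * x
            else:
                for j in range(n):
                    x = v[j]
                    z = b + (x - mid) * a
                    if z > 0.0:
                        g = 1.0 / (1.0 + np.exp(-z))
                    else:
                        e = np.exp(z)
                        g = e / (1.0 + e)
                    sg += g
                    gv = g * x
                    sgv += gv
                    sgv2 += gv * x
            it += 1

            if with_ll:
                c0 = np.log(1.0 - pi_c) - 0.5 * np.log(2.0 * np.pi * s2)
                ll = n * c0 + acc
                if abs(ll - ll_old) <= tol * max(1.0, abs(ll)):
                    converged = True
                ll_old = ll

            # M-step (applied on the convergence sweep too, like the
            # reference path)
            s1g = n - sg
            pi = sg / n
            if sg > 1e-300:
                mu_m = sgv / sg
            if s1g > 1e-300:
                mu_u = (sv - sgv) / s1g
            ss_m = sgv2 - 2.0 * mu_m * sgv + sg * mu_m * mu_m
            ss_u = (sv2 - sgv2) - 2.0 * mu_u * (sv - sgv) + s1g * mu_u * mu_u
            s2 = (ss_m + ss_u) / n
            if s2 < floor:
                s2 = floor
            if s2 <= 0.0:
                s2 = 1e-300

        if mu_m < mu_u:
            mu_u, mu_m = mu_m, mu_u
            pi = 1.0 - pi
        out_pi[d] = pi
        out_mu_u[d] = mu_u
        out_mu_m[d] = mu_m
        out_s2[d] = s2
        out_ll[d] = ll
        out_conv[d] = converged
        out_iter[d] = it
    return out_pi, out_mu_u, out_mu_m, out_s2, out_ll, out_conv, out_iter
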