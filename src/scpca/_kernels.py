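"""Numba-compiled rank-1 solver for categorical/Bernoulli PCA.

The supervised permutation pipeline fits tens of thousands of latent_dim=1
models, so the alternating damped-Newton cycle is implemented here with fused
loops.  Two deviations from the step-by-step reference path in
:mod:`scpca.cpca` keep it fast while preserving the monotone-objective
guarantee:

* per SNP column, the loadings of all non-reference categories and the
  offsets are updated by one joint Newton step on the (2K)-dimensional column
  block (the reference path updates loading and offset blocks sequentially);
* the "before" objective of every damped acceptance test is accumulated
  during the gradient pass instead of being recomputed.

Cell probabilities and log-likelihoods use max-subtracted softmax, so large
natural parameters (separation) stay finite without clipping.  An optional
ridge penalty lambda/2 * sum theta^2 on the natural parameters (gauge
invariant: theta is untouched by the QR and recentering steps) bounds the
otherwise non-existent MLE under partial separation; with ridge = 0 the
solver maximizes the plain likelihood.  K is 2 for genotypes and 1 for the
Bernoulli reduction.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["fit_l1", "fit_l1_k2", "wald_t"]


@njit(cache=False, fastmath=True)
def _cell(codes, i, j, ui, V, mu, p, ridge):
    """Stable per-cell probabilities; returns the penalized cell objective.

    Fills ``p`` with the non-reference category probabilities; callers
    needing the natural parameters recompute them inline (one fused
    multiply-add each).
    """
    K = V.shape[0]
    a = 0.0
    obs_th = 0.0
    pen = 0.0
    for k in range(K):
        t = ui * V[k, j] + mu[k, j]
        p[k] = t
        if t > a:
            a = t
        if codes[i, j] == k + 1:
            obs_th = t
        pen += t * t
    z = 1.0 if a == 0.0 else math.exp(-a)
    for k in range(K):
        p[k] = math.exp(p[k] - a)
        z += p[k]
    for k in range(K):
        p[k] /= z
    return obs_th - a - math.log(z) - 0.5 * ridge * pen


@njit(cache=False, fastmath=True)
def _row_obj(codes, i, ui, V, mu, p, ridge):
    d = codes.shape[1]
    ll = 0.0
    for j in range(d):
        ll += _cell(codes, i, j, ui, V, mu, p, ridge)
    return ll


@njit(cache=False, fastmath=True)
def _col_obj_v(codes, j, u, vj, muj, p, ridge):
    """Column objective with explicit per-column parameters."""
    n = codes.shape[0]
    K = vj.shape[0]
    ll = 0.0
    for i in range(n):
        a = 0.0
        obs_th = 0.0
        pen = 0.0
        for k in range(K):
            t = u[i] * vj[k] + muj[k]
            if t > a:
                a = t
            if codes[i, j] == k + 1:
                obs_th = t
            p[k] = t
            pen += t * t
        z = 1.0 if a == 0.0 else math.exp(-a)
        for k in range(K):
            z += math.exp(p[k] - a)
        ll += obs_th - a - math.log(z) - 0.5 * ridge * pen
    return ll


@njit(cache=False, fastmath=True)
def _total_obj(codes, u, V, mu, p, ridge):
    n = codes.shape[0]
    ll = 0.0
    for i in range(n):
        ll += _row_obj(codes, i, u[i], V, mu, p, ridge)
    return ll


@njit(cache=False, fastmath=True)
def _solve_small(A, b, out):
    """Gaussian elimination with partial pivoting for tiny systems.

    Returns False (leaving ``out`` unreliable) when a pivot is numerically
    zero; A and b are modified in place.
    """
    m = A.shape[0]
    for col in range(m):
        piv = col
        best = abs(A[col, col])
        for r in range(col + 1, m):
            if abs(A[r, col]) > best:
                best = abs(A[r, col])
                piv = r
        if best < 1e-12:
            return False
        if piv != col:
            for c in range(m):
                A[col, c], A[piv, c] = A[piv, c], A[col, c]
            b[col], b[piv] = b[piv], b[col]
        for r in range(col + 1, m):
            f = A[r, col] / A[col, col]
            for c in range(col, m):
                A[r, c] -= f * A[col, c]
            b[r] -= f * b[col]
    for r in range(m - 1, -1, -1):
        acc = b[r]
        for c in range(r + 1, m):
            acc -= A[r, c] * out[c]
        out[r] = acc / A[r, r]
    return True


@njit(cache=False, fastmath=True)
def fit_l1(codes, u, V, mu, max_iter, tol, damping, ridge):
    """Alternating damped-Newton fit for latent_dim = 1.

    Update cycle: scores (per-sample scalar Newton) -> recentering ->
    stacked-loading normalization (the l = 1 QR step) -> joint loading/offset
    Newton per SNP column.  Every block step is halved until the block's
    objective contribution strictly improves.  Returns (u, V, mu, obj_trace,
    trace_len, converged).
    """
    n, d = codes.shape
    K = V.shape[0]
    m = 2 * K  # column block: (V_1..V_K, mu_1..mu_K)
    trace = np.empty(max_iter + 1)
    p = np.empty(K)
    trace[0] = _total_obj(codes, u, V, mu, p, ridge)
    converged = False
    n_tr = 1
    H = np.empty((m, m))
    g = np.empty(m)
    g_save = np.empty(m)
    vj_try = np.empty(K)
    muj_try = np.empty(K)
    for _it in range(max_iter):
        # ---- score update (independent scalar Newton per sample) ----
        for i in range(n):
            gs = 0.0
            hs = 0.0
            before = 0.0
            ui = u[i]
            for j in range(d):
                before += _cell(codes, i, j, ui, V, mu, p, ridge)
                pv = 0.0
                for k in range(K):
                    x = 1.0 if codes[i, j] == k + 1 else 0.0
                    t = ui * V[k, j] + mu[k, j]
                    gs += (x - p[k] - ridge * t) * V[k, j]
                    hs -= (p[k] + ridge) * V[k, j] * V[k, j]
                    pv += p[k] * V[k, j]
                hs += pv * pv
            if hs < -1e-12:
                delta = -gs / hs
            else:
                delta = 0.1 * gs  # flat Hessian: fixed gradient step
            if delta > 100.0:  # quasi-separated rows: cap so halving can land
                delta = 100.0
            elif delta < -100.0:
                delta = -100.0
            # skip converged rows: the attainable gain is ~ g*delta/2, and
            # a futile halving loop costs 21 objective evaluations
            if gs * delta < 4e-12:
                continue
            step = 1.0
            for _h in range(damping + 1):
                cand = u[i] + step * delta
                if _row_obj(codes, i, cand, V, mu, p, ridge) > before + 1e-12:
                    u[i] = cand
                    break
                step *= 0.5
        # ---- identifiability: shift the score mean into the offsets ----
        # theta is unchanged: (u - c) v + (mu + c v) = u v + mu.  Removes the
        # flat translation direction that block updates crawl along.
        c = 0.0
        for i in range(n):
            c += u[i]
        c /= n
        for i in range(n):
            u[i] -= c
        for k in range(K):
            for j in range(d):
                mu[k, j] += c * V[k, j]
        # ---- QR step: for l = 1, normalize the stacked loading vector ----
        s = 0.0
        for k in range(K):
            for j in range(d):
                s += V[k, j] * V[k, j]
        s = math.sqrt(s)
        if s > 1e-12:
            for k in range(K):
                for j in range(d):
                    V[k, j] /= s
            for i in range(n):
                u[i] *= s
        # ---- joint loading/offset Newton per SNP column ----
        total_obj = 0.0
        for j in range(d):
            for a in range(m):
                g[a] = 0.0
                for b in range(m):
                    H[a, b] = 0.0
            before = 0.0
            for i in range(n):
                ui = u[i]
                before += _cell(codes, i, j, ui, V, mu, p, ridge)
                for k in range(K):
                    x = 1.0 if codes[i, j] == k + 1 else 0.0
                    t = ui * V[k, j] + mu[k, j]
                    g[k] += (x - p[k] - ridge * t) * ui
                    g[K + k] += x - p[k] - ridge * t
                    for q in range(K):
                        w = -p[k] * p[q]
                        if k == q:
                            w += p[k]
                        # H blocks: [VV]= -sum u^2 W, [Vmu]= -sum u W, [mumu]= -sum W
                        H[k, q] -= ui * ui * w
                        H[k, K + q] -= ui * w
                        H[K + k, q] -= ui * w
                        H[K + k, K + q] -= w
                    # ridge curvature (diagonal in the category index)
                    H[k, k] -= ridge * ui * ui
                    H[k, K + k] -= ridge * ui
                    H[K + k, k] -= ridge * ui
                    H[K + k, K + k] -= ridge
            # freeze coordinates with flat curvature (e.g. a category with no
            # observations: p ~ 0 gives ~zero rows) so they cannot poison the
            # joint solve; their parameters simply stop moving
            for a in range(m):
                if H[a, a] > -1e-9 * n:
                    for b2 in range(m):
                        H[a, b2] = 0.0
                        H[b2, a] = 0.0
                    H[a, a] = -1.0
                    g[a] = 0.0
            delta = np.empty(m)
            for a in range(m):
                g_save[a] = g[a]  # _solve_small clobbers g
            ok = _solve_small(H, g, delta)
            if not ok:
                for a in range(m):
                    delta[a] = 0.1 * g_save[a]  # gradient fallback
            else:
                for a in range(m):
                    delta[a] = -delta[a]  # ascent: x - H^{-1} g
            dn = 0.0
            pred = 0.0
            for a in range(m):
                dn += delta[a] * delta[a]
                pred += g_save[a] * delta[a]
            dn = math.sqrt(dn)
            if dn > 100.0:  # cap quasi-separated column steps
                for a in range(m):
                    delta[a] *= 100.0 / dn
            if pred < 4e-12:  # converged column: skip the halving loop
                total_obj += before
                continue
            step = 1.0
            accepted = False
            for _h in range(damping + 1):
                for k in range(K):
                    vj_try[k] = V[k, j] + step * delta[k]
                    muj_try[k] = mu[k, j] + step * delta[K + k]
                after = _col_obj_v(codes, j, u, vj_try, muj_try, p, ridge)
                if after > before + 1e-12:
                    for k in range(K):
                        V[k, j] = vj_try[k]
                        mu[k, j] = muj_try[k]
                    total_obj += after
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                total_obj += before
        trace[n_tr] = total_obj
        n_tr += 1
        if abs(total_obj - trace[n_tr - 2]) < tol * (abs(trace[n_tr - 2]) + 1e-12):
            converged = True
            break
    return u, V, mu, trace, n_tr, converged


@njit(cache=False, fastmath=True)
def _row_obj_k2(codes, i, ui, V, mu, ridge):
    d = codes.shape[1]
    ll = 0.0
    for j in range(d):
        t1 = ui * V[0, j] + mu[0, j]
        t2 = ui * V[1, j] + mu[1, j]
        a = t1 if t1 > t2 else t2
        if a < 0.0:
            a = 0.0
        z = (1.0 if a == 0.0 else math.exp(-a)) + math.exp(t1 - a) + math.exp(t2 - a)
        obs = codes[i, j]
        obs_th = t1 if obs == 1 else (t2 if obs == 2 else 0.0)
        ll += obs_th - a - math.log(z) - 0.5 * ridge * (t1 * t1 + t2 * t2)
    return ll


@njit(cache=False, fastmath=True)
def _col_obj_k2(codes, j, u, v1, v2, m1, m2, ridge):
    n = codes.shape[0]
    ll = 0.0
    for i in range(n):
        t1 = u[i] * v1 + m1
        t2 = u[i] * v2 + m2
        a = t1 if t1 > t2 else t2
        if a < 0.0:
            a = 0.0
        z = (1.0 if a == 0.0 else math.exp(-a)) + math.exp(t1 - a) + math.exp(t2 - a)
        obs = codes[i, j]
        obs_th = t1 if obs == 1 else (t2 if obs == 2 else 0.0)
        ll += obs_th - a - math.log(z) - 0.5 * ridge * (t1 * t1 + t2 * t2)
    return ll


@njit(cache=False, fastmath=True)
def fit_l1_k2(codes, u, V, mu, max_iter, tol, damping, ridge):
    """Unrolled two-category (genotype) specialization of :func:`fit_l1`.

    Identical update cycle and acceptance rules; the category loops are
    scalarized, which roughly halves the fit cost at pipeline sizes.
    """
    n, d = codes.shape
    trace = np.empty(max_iter + 1)
    p2buf = np.empty(2)
    obj = 0.0
    for i in range(n):
        obj += _row_obj_k2(codes, i, u[i], V, mu, ridge)
    trace[0] = obj
    converged = False
    n_tr = 1
    H = np.empty((4, 4))
    g = np.empty(4)
    g_save = np.empty(4)
    delta4 = np.empty(4)
    for _it in range(max_iter):
        # ---- score update ----
        for i in range(n):
            ui = u[i]
            gs = 0.0
            hs = 0.0
            before = 0.0
            for j in range(d):
                v1 = V[0, j]
                v2 = V[1, j]
                t1 = ui * v1 + mu[0, j]
                t2 = ui * v2 + mu[1, j]
                a = t1 if t1 > t2 else t2
                if a < 0.0:
                    a = 0.0
                e0 = 1.0 if a == 0.0 else math.exp(-a)
                e1 = math.exp(t1 - a)
                e2 = math.exp(t2 - a)
                z = e0 + e1 + e2
                p1 = e1 / z
                p2 = e2 / z
                obs = codes[i, j]
                x1 = 1.0 if obs == 1 else 0.0
                x2 = 1.0 if obs == 2 else 0.0
                obs_th = t1 if obs == 1 else (t2 if obs == 2 else 0.0)
                before += obs_th - a - math.log(z) - 0.5 * ridge * (t1 * t1 + t2 * t2)
                gs += (x1 - p1 - ridge * t1) * v1 + (x2 - p2 - ridge * t2) * v2
                pv = p1 * v1 + p2 * v2
                hs += pv * pv - (p1 + ridge) * v1 * v1 - (p2 + ridge) * v2 * v2
            if hs < -1e-12:
                delta = -gs / hs
            else:
                delta = 0.1 * gs
            if delta > 100.0:
                delta = 100.0
            elif delta < -100.0:
                delta = -100.0
            if gs * delta < 4e-12:
                continue
            step = 1.0
            for _h in range(damping + 1):
                cand = ui + step * delta
                if _row_obj_k2(codes, i, cand, V, mu, ridge) > before + 1e-12:
                    u[i] = cand
                    break
                step *= 0.5
        # ---- recenter scores into offsets (theta unchanged) ----
        c = 0.0
        for i in range(n):
            c += u[i]
        c /= n
        for i in range(n):
            u[i] -= c
        for j in range(d):
            mu[0, j] += c * V[0, j]
            mu[1, j] += c * V[1, j]
        # ---- normalize the stacked loading vector ----
        s = 0.0
        for j in range(d):
            s += V[0, j] * V[0, j] + V[1, j] * V[1, j]
        s = math.sqrt(s)
        if s > 1e-12:
            for j in range(d):
                V[0, j] /= s
                V[1, j] /= s
            for i in range(n):
                u[i] *= s
        # ---- joint (V1, V2, mu1, mu2) Newton per column ----
        total_obj = 0.0
        for j in range(d):
            g0 = g1 = g2 = g3 = 0.0
            h00 = h01 = h02 = h03 = 0.0
            h11 = h12 = h13 = 0.0
            h22 = h23 = h33 = 0.0
            before = 0.0
            v1 = V[0, j]
            v2 = V[1, j]
            m1 = mu[0, j]
            m2 = mu[1, j]
            for i in range(n):
                ui = u[i]
                t1 = ui * v1 + m1
                t2 = ui * v2 + m2
                a = t1 if t1 > t2 else t2
                if a < 0.0:
                    a = 0.0
                e0 = 1.0 if a == 0.0 else math.exp(-a)
                e1 = math.exp(t1 - a)
                e2 = math.exp(t2 - a)
                z = e0 + e1 + e2
                p1 = e1 / z
                p2 = e2 / z
                obs = codes[i, j]
                x1 = 1.0 if obs == 1 else 0.0
                x2 = 1.0 if obs == 2 else 0.0
                obs_th = t1 if obs == 1 else (t2 if obs == 2 else 0.0)
                before += obs_th - a - math.log(z) - 0.5 * ridge * (t1 * t1 + t2 * t2)
                r1 = x1 - p1 - ridge * t1
                r2 = x2 - p2 - ridge * t2
                g0 += r1 * ui
                g1 += r2 * ui
                g2 += r1
                g3 += r2
                w11 = p1 * (1.0 - p1) + ridge
                w22 = p2 * (1.0 - p2) + ridge
                w12 = -p1 * p2
                uu = ui * ui
                h00 -= uu * w11
                h11 -= uu * w22
                h01 -= uu * w12
                h02 -= ui * w11
                h13 -= ui * w22
                h03 -= ui * w12
                h12 -= ui * w12
                h22 -= w11
                h33 -= w22
                h23 -= w12
            H[0, 0] = h00; H[0, 1] = h01; H[0, 2] = h02; H[0, 3] = h03
            H[1, 0] = h01; H[1, 1] = h11; H[1, 2] = h12; H[1, 3] = h13
            H[2, 0] = h02; H[2, 1] = h12; H[2, 2] = h22; H[2, 3] = h23
            H[3, 0] = h03; H[3, 1] = h13; H[3, 2] = h23; H[3, 3] = h33
            g[0] = g0; g[1] = g1; g[2] = g2; g[3] = g3
            for aa in range(4):
                if H[aa, aa] > -1e-9 * n:
                    for bb in range(4):
                        H[aa, bb] = 0.0
                        H[bb, aa] = 0.0
                    H[aa, aa] = -1.0
                    g[aa] = 0.0
                g_save[aa] = g[aa]
            ok = _solve_small(H, g, delta4)
            if not ok:
                for aa in range(4):
                    delta4[aa] = 0.1 * g_save[aa]
            else:
                for aa in range(4):
                    delta4[aa] = -delta4[aa]
            dn = 0.0
            pred = 0.0
            for aa in range(4):
                dn += delta4[aa] * delta4[aa]
                pred += g_save[aa] * delta4[aa]
            dn = math.sqrt(dn)
            if dn > 100.0:
                for aa in range(4):
                    delta4[aa] *= 100.0 / dn
            if pred < 4e-12:
                total_obj += before
                continue
            step = 1.0
            accepted = False
            for _h in range(damping + 1):
                after = _col_obj_k2(
                    codes, j, u,
                    v1 + step * delta4[0], v2 + step * delta4[1],
                    m1 + step * delta4[2], m2 + step * delta4[3], ridge,
                )
                if after > before + 1e-12:
                    V[0, j] = v1 + step * delta4[0]
                    V[1, j] = v2 + step * delta4[1]
                    mu[0, j] = m1 + step * delta4[2]
                    mu[1, j] = m2 + step * delta4[3]
                    total_obj += after
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                total_obj += before
        trace[n_tr] = total_obj
        n_tr += 1
        if abs(total_obj - trace[n_tr - 2]) < tol * (abs(trace[n_tr - 2]) + 1e-12):
            converged = True
            break
    return u, V, mu, trace, n_tr, converged


@njit(cache=False, fastmath=True)
def wald_t(x, y, max_iter, tol):
    """Two-parameter logistic IRLS; returns (t, converged).

    converged=False signals separation or non-convergence: the caller should
    refit with the penalized (Firth) path.
    """
    n = x.shape[0]
    m = 0.0
    for i in range(n):
        m += y[i]
    m /= n
    if m < 1e-6:
        m = 1e-6
    if m > 1 - 1e-6:
        m = 1 - 1e-6
    b0 = math.log(m / (1 - m))
    b1 = 0.0
    converged = False
    for _ in range(max_iter):
        g0 = 0.0
        g1 = 0.0
        s00 = 0.0
        s01 = 0.0
        s11 = 0.0
        for i in range(n):
            eta = b0 + b1 * x[i]
            if eta > 30.0:
                eta = 30.0
            elif eta < -30.0:
                eta = -30.0
            p = 1.0 / (1.0 + math.exp(-eta))
            w = p * (1.0 - p)
            r = y[i] - p
            g0 += r
            g1 += r * x[i]
            s00 += w
            s01 += w * x[i]
            s11 += w * x[i] * x[i]
        det = s00 * s11 - s01 * s01
        if det <= 1e-300:
            return 0.0, False
        d0 = (s11 * g0 - s01 * g1) / det
        d1 = (s00 * g1 - s01 * g0) / det
        b0 += d0
        b1 += d1
        if abs(d0) < tol and abs(d1) < tol:
            converged = True
            break
    if not converged or abs(b1) > 15.0:
        return 0.0, False
    s00 = 0.0
    s01 = 0.0
    s11 = 0.0
    for i in range(n):
        eta = b0 + b1 * x[i]
        if eta > 30.0:
            eta = 30.0
        elif eta < -30.0:
            eta = -30.0
        p = 1.0 / (1.0 + math.exp(-eta))
        w = p * (1.0 - p)
        s00 += w
        s01 += w * x[i]
        s11 += w * x[i] * x[i]
    det = s00 * s11 - s01 * s01
    if det <= 1e-300:
        return 0.0, False
    se1 = math.sqrt(s00 / det)
    return b1 / se1, True
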