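"""Numba inner loops: Gibbs sampling, penalized logistic paths, calibration.

Everything here is deliberately free of Python objects so it compiles to
tight machine code; the public wrappers live in :mod:`symptomnet.ising` and
:mod:`symptomnet.elasso`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "gibbs_chain",
    "lasso_path_binary",
    "lasso_path_dense",
    "calibration_rounds",
]


@njit(cache=True)
def gibbs_chain(tau, omega, n_keep, burn_in, thinning, uniforms, init):
    """Single-site Gibbs sweeps over a {0,1} Ising model.

    One sweep updates every node once from its conditional logit. After
    ``burn_in`` sweeps, every ``thinning``-th sweep is retained until
    ``n_keep`` samples are collected. ``uniforms`` must hold one draw per
    site update: (burn_in + (n_keep - 1) * thinning + 1) * p values.
    """
    p = tau.shape[0]
    x = init.astype(np.float64)
    out = np.empty((n_keep, p), dtype=np.int8)
    total = burn_in + (n_keep - 1) * thinning + 1
    idx = 0
    kept = 0
    for sweep in range(total):
        for i in range(p):
            s = tau[i]
            for j in range(p):
                s += omega[i, j] * x[j]
            pr = 1.0 / (1.0 + np.exp(-s))
            x[i] = 1.0 if uniforms[idx] < pr else 0.0
            idx += 1
        if sweep >= burn_in and (sweep - burn_in) % thinning == 0:
            for i in range(p):
                out[kept, i] = np.int8(x[i])
            kept += 1
    return out


@njit(cache=True, inline="always")
def _fill_G_column(col_idx, col_ptr, row_idx, row_ptr, w, G, k):
    """G[:, k] = sum_i w_i x_ik x_ij over the 1-entries of column k."""
    p = G.shape[0]
    for j in range(p):
        G[j, k] = 0.0
    for t in range(col_ptr[k], col_ptr[k + 1]):
        i = col_idx[t]
        wi = w[i]
        for s in range(row_ptr[i], row_ptr[i + 1]):
            G[row_idx[s], k] += wi


@njit(cache=True)
def lasso_path_binary(
    col_idx, col_ptr, row_idx, row_ptr, y, sw, n, p, lambdas, tol, max_outer, max_cd
):
    """L1-penalized logistic path for a strictly binary 0/1 design.

    Same objective as :func:`lasso_path_dense` — mean weighted negative
    log-likelihood + lam * sum |beta| with an unpenalized intercept — solved
    by cyclic coordinate descent on the IRLS quadratic approximation with
    warm starts along the decreasing lambda path. The design enters only
    through per-column/per-row CSR indices of the 1-entries, so each outer
    iteration aggregates sufficient statistics in O(nnz) and every
    coordinate-descent sweep then runs on p-vector arithmetic alone
    (covariance updates; cross-product columns are built lazily on
    activation).

    The outer loop stops once the IRLS step changes no linear predictor by
    more than sqrt(tol) (capped at 5e-3): near the optimum the IRLS step is
    a proximal Newton step, so the remaining error is of squared order.
    """
    n_lam = lambdas.shape[0]
    wsum = sw.sum()

    intercepts = np.zeros(n_lam)
    coefs = np.zeros((n_lam, p))
    n_iter = np.zeros(n_lam, dtype=np.int64)
    converged = np.zeros(n_lam, dtype=np.bool_)

    ybar = 0.0
    for i in range(n):
        ybar += sw[i] * y[i]
    ybar /= wsum
    beta0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, beta0)

    w = np.empty(n)
    U = np.empty(p)  # sum_i w_i x_ij z_i
    h = np.empty(p)  # sum_i w_i x_ij
    a = np.empty(p)  # h / wsum (curvature; x^2 = x for binary designs)
    G = np.zeros((p, p))  # weighted cross-products, built lazily per column
    have_G = np.zeros(p, dtype=np.bool_)
    dot = np.zeros(p)  # sum_k G[j, k] beta[k] over nonzero beta_k

    accept = np.sqrt(tol)
    if accept > 5e-3:
        accept = 5e-3
    if accept < tol:
        accept = tol

    for l in range(n_lam):
        lam = lambdas[l]
        ok = False
        outer = 0
        while outer < max_outer:
            outer += 1
            # ---- sufficient statistics of the quadratic at current beta ----
            # (the linear predictor is rebuilt row by row in the same pass;
            # its change against the previous IRLS iterate is the step size)
            U0 = 0.0
            W = 0.0
            dout = 0.0
            for j in range(p):
                U[j] = 0.0
                h[j] = 0.0
                have_G[j] = False
            for i in range(n):
                e = beta0
                for s in range(row_ptr[i], row_ptr[i + 1]):
                    e += beta[row_idx[s]]
                diff = abs(e - eta[i])
                if diff > dout:
                    dout = diff
                eta[i] = e
                mu = 1.0 / (1.0 + np.exp(-e))
                wi = mu * (1.0 - mu)
                if wi < 1e-5:
                    wi = 1e-5
                wv = sw[i] * wi
                zv = e + (y[i] - mu) / wi
                w[i] = wv
                wz = wv * zv
                U0 += wz
                W += wv
                for s in range(row_ptr[i], row_ptr[i + 1]):
                    j = row_idx[s]
                    U[j] += wz
                    h[j] += wv
            if outer > 1 and dout < accept:
                # the previous CD pass moved no linear predictor beyond the
                # proximal-Newton acceptance threshold: beta already stands
                ok = True
                break
            for j in range(p):
                a[j] = h[j] / wsum
                dot[j] = 0.0
            # batch-build G columns of the warm-start active set in one pass
            # over the rows (cheaper than per-column scatters)
            n_active = 0
            for k in range(p):
                if beta[k] != 0.0:
                    have_G[k] = True
                    n_active += 1
                    for j in range(p):
                        G[j, k] = 0.0
            if n_active > 0:
                for i in range(n):
                    wi = w[i]
                    for s in range(row_ptr[i], row_ptr[i + 1]):
                        k = row_idx[s]
                        if have_G[k]:
                            for s2 in range(row_ptr[i], row_ptr[i + 1]):
                                G[row_idx[s2], k] += wi
            hb = 0.0  # sum_k h_k beta_k
            for k in range(p):
                if beta[k] != 0.0:
                    bk = beta[k]
                    for j in range(p):
                        dot[j] += G[j, k] * bk
                    hb += h[k] * bk

            # ---- coordinate descent on p-vector statistics ----
            sweeps = 0
            dmax_total = 0.0
            while sweeps < max_cd:
                # full sweep: checks KKT for every coordinate
                d0 = (U0 - beta0 * W - hb) / W
                if d0 != 0.0:
                    beta0 += d0
                dmax = abs(d0)
                for j in range(p):
                    cj = (U[j] - beta0 * h[j] - dot[j] + h[j] * beta[j]) / wsum
                    if lam > 0.0:
                        if cj > lam:
                            bj = (cj - lam) / a[j]
                        elif cj < -lam:
                            bj = (cj + lam) / a[j]
                        else:
                            bj = 0.0
                    else:
                        bj = cj / a[j]
                    d = bj - beta[j]
                    if d != 0.0:
                        beta[j] = bj
                        if not have_G[j]:
                            have_G[j] = True
                            _fill_G_column(col_idx, col_ptr, row_idx, row_ptr, w, G, j)
                        for jj in range(p):
                            dot[jj] += G[jj, j] * d
                        hb += h[j] * d
                        ad = abs(d)
                        if ad > dmax:
                            dmax = ad
                sweeps += 1
                if dmax > dmax_total:
                    dmax_total = dmax
                if dmax < tol:
                    break
                # cycle over the nonzero coordinates until stable
                while sweeps < max_cd:
                    d0 = (U0 - beta0 * W - hb) / W
                    if d0 != 0.0:
                        beta0 += d0
                    dmax = abs(d0)
                    for j in range(p):
                        if beta[j] == 0.0:
                            continue
                        cj = (U[j] - beta0 * h[j] - dot[j] + h[j] * beta[j]) / wsum
                        if lam > 0.0:
                            if cj > lam:
                                bj = (cj - lam) / a[j]
                            elif cj < -lam:
                                bj = (cj + lam) / a[j]
                            else:
                                bj = 0.0
                        else:
                            bj = cj / a[j]
                        d = bj - beta[j]
                        if d != 0.0:
                            beta[j] = bj
                            for jj in range(p):
                                dot[jj] += G[jj, j] * d
                            hb += h[j] * d
                            ad = abs(d)
                            if ad > dmax:
                                dmax = ad
                    sweeps += 1
                    if dmax < tol:
                        break

            if dmax_total < tol:
                # coordinate descent left the warm start untouched: the
                # previous solution is already optimal at this lambda
                ok = True
                break

        n_iter[l] = outer
        converged[l] = ok
        intercepts[l] = beta0
        for j in range(p):
            coefs[l, j] = beta[j]

    return intercepts, coefs, n_iter, converged


@njit(cache=True)
def lasso_path_dense(X, y, sw, lambdas, tol, max_outer, max_cd):
    """Reference dense-design variant of the penalized path (general X).

    Identical objective and IRLS/coordinate-descent scheme as
    :func:`lasso_path_binary`, but with residual updates in O(n) per
    coordinate; used for non-binary designs and as an internal cross-check.
    """
    n, p = X.shape
    n_lam = lambdas.shape[0]
    wsum = sw.sum()

    intercepts = np.zeros(n_lam)
    coefs = np.zeros((n_lam, p))
    n_iter = np.zeros(n_lam, dtype=np.int64)
    converged = np.zeros(n_lam, dtype=np.bool_)

    ybar = 0.0
    for i in range(n):
        ybar += sw[i] * y[i]
    ybar /= wsum
    beta0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.full(n, beta0)

    w = np.empty(n)
    z = np.empty(n)
    a = np.empty(p)

    accept = np.sqrt(tol)
    if accept > 5e-3:
        accept = 5e-3
    if accept < tol:
        accept = tol

    for l in range(n_lam):
        lam = lambdas[l]
        ok = False
        outer = 0
        while outer < max_outer:
            outer += 1
            for i in range(n):
                mu = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = mu * (1.0 - mu)
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = sw[i] * wi
                z[i] = eta[i] + (y[i] - mu) / wi
            r = z - eta
            wssum = w.sum()
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * X[i, j] * X[i, j]
                a[j] = s / wsum

            sweeps = 0
            dmax_total = 0.0
            while sweeps < max_cd:
                num = 0.0
                for i in range(n):
                    num += w[i] * r[i]
                d0 = num / wssum
                if d0 != 0.0:
                    beta0 += d0
                    for i in range(n):
                        r[i] -= d0
                dmax = abs(d0)
                for j in range(p):
                    cj = 0.0
                    for i in range(n):
                        cj += w[i] * r[i] * X[i, j]
                    cj = cj / wsum + a[j] * beta[j]
                    if lam > 0.0:
                        if cj > lam:
                            bj = (cj - lam) / a[j]
                        elif cj < -lam:
                            bj = (cj + lam) / a[j]
                        else:
                            bj = 0.0
                    else:
                        bj = cj / a[j]
                    d = bj - beta[j]
                    if d != 0.0:
                        beta[j] = bj
                        for i in range(n):
                            r[i] -= d * X[i, j]
                        ad = abs(d)
                        if ad > dmax:
                            dmax = ad
                sweeps += 1
                if dmax > dmax_total:
                    dmax_total = dmax
                if dmax < tol:
                    break

            dout = 0.0
            for i in range(n):
                new_eta = z[i] - r[i]
                diff = abs(new_eta - eta[i])
                if diff > dout:
                    dout = diff
                eta[i] = new_eta
            if dout < accept or dmax_total < tol:
                ok = True
                break

        n_iter[l] = outer
        converged[l] = ok
        intercepts[l] = beta0
        for j in range(p):
            coefs[l, j] = beta[j]

    return intercepts, coefs, n_iter, converged


@njit(cache=True)
def calibration_rounds(w, tau, targets, tol, max_rounds):
    """Gauss-Seidel threshold calibration against exact enumeration.

    ``w`` holds the unnormalized state weights for the current ``tau`` (the
    coupling contribution is baked in). Each node update solves the monotone
    one-dimensional marginal equation in closed form, which is the fixed
    point the bisection on tau converges to. Returns (rounds_used, worst_err,
    worst_node); rounds_used is -1 when the tolerance was not reached.
    """
    n_states = w.shape[0]
    p = tau.shape[0]
    total = w.sum()
    worst = np.inf
    worst_node = -1
    for rnd in range(max_rounds):
        for i in range(p):
            # states with bit i set form contiguous blocks of length 2^i
            step = 1 << i
            acc = 0.0
            for start in range(step, n_states, 2 * step):
                for s in range(start, start + step):
                    acc += w[s]
            other = total - acc
            if acc <= 0.0 or other <= 0.0 or not np.isfinite(acc + other):
                # weight mass degenerated (under/overflow): abort as failed
                return -2, np.inf, i
            a0 = acc * np.exp(-tau[i])
            t_new = np.log(targets[i] * other / ((1.0 - targets[i]) * a0))
            delta = t_new - tau[i]
            if not np.isfinite(delta):
                return -2, np.inf, i
            # damp huge jumps so intermediate weights stay representable
            if delta > 30.0:
                delta = 30.0
            elif delta < -30.0:
                delta = -30.0
            if delta != 0.0:
                tau[i] = tau[i] + delta
                f = np.exp(delta)
                new_acc = 0.0
                for start in range(step, n_states, 2 * step):
                    for s in range(start, start + step):
                        w[s] *= f
                        new_acc += w[s]
                total = other + new_acc
        # renormalize so repeated rounds cannot overflow
        inv = 1.0 / total
        for s in range(n_states):
            w[s] *= inv
        total = 1.0
        # fresh convergence check
        worst = 0.0
        worst_node = -1
        for i in range(p):
            step = 1 << i
            acc = 0.0
            for start in range(step, n_states, 2 * step):
                for s in range(start, start + step):
                    acc += w[s]
            err = abs(acc / total - targets[i])
            if not np.isfinite(err):
                return -2, np.inf, i
            if err > worst:
                worst = err
                worst_node = i
        if worst <= tol:
            return rnd + 1, worst, worst_node
    return -1, worst, worst_node
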