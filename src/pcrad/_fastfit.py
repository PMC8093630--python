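"""Numba-compiled fitting kernels.

The exhaustive subset search evaluates every candidate covariate subset with
~n cross-validation refits, and the LOOCV lasso path refits a 100-value
penalty path once per left-out subject; these inner solvers are therefore
compiled with numba:

* ``newton_logit`` — unpenalized binomial logistic regression via damped
  Newton-Raphson (step halving on the negative log-likelihood).
* ``cv_logit_scores`` — out-of-fold predicted probabilities with per-fold
  standardization fitted on the training folds only.
* ``lasso_path`` — L1-penalized logistic regression along a decreasing
  penalty grid by cyclic coordinate descent on the IRLS quadratic
  approximation, warm starts, intercept unpenalized.
* ``loocv_deviance`` — mean leave-one-out held-out binomial deviance per
  penalty value.

Objective for the penalized path: (1/n) * negative log-likelihood
+ lam * sum_j |beta_j|, on columns standardized by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PMIN = 1e-12


@njit(cache=True)
def _nll(eta, y):
    total = 0.0
    for i in range(eta.shape[0]):
        # log(1 + exp(-|eta|)) form for numerical stability
        e = eta[i]
        if e > 0:
            total += np.log(1.0 + np.exp(-e)) + (1.0 - y[i]) * e
        else:
            total += np.log(1.0 + np.exp(e)) - y[i] * e
    return total


@njit(cache=True)
def newton_logit(X, y, max_iter=60, tol=1e-10, beta0=None, ridge=0.0):
    """Logistic MLE on a design X (including any intercept column).

    Returns (beta, converged).  Quasi-separated fits hit the iteration cap or
    the coefficient-magnitude guard and are flagged not converged.  ``beta0``
    warm-starts the iteration (e.g. from a full-data fit for CV refits);
    ``ridge`` adds an optional L2 penalty (ridge/2)*|beta|^2 per observation
    used only to stabilize warm-start fits under separation.
    """
    n, p = X.shape
    if beta0 is None:
        beta = np.zeros(p)
    else:
        beta = beta0.copy()
    eta = X @ beta
    converged = False
    for _ in range(max_iter):
        pr = 1.0 / (1.0 + np.exp(-eta))
        w = pr * (1.0 - pr)
        grad = X.T @ (y - pr) - n * ridge * beta
        H = (X * w.reshape(-1, 1)).T @ X
        for j in range(p):
            H[j, j] += 1e-12 + n * ridge
        delta = np.linalg.solve(H, grad)
        nll0 = _nll(eta, y) + 0.5 * n * ridge * np.sum(beta**2)
        step = 1.0
        beta_new = beta + delta
        eta_new = X @ beta_new
        for _ in range(30):
            if _nll(eta_new, y) + 0.5 * n * ridge * np.sum(beta_new**2) <= nll0 + 1e-12:
                break
            step *= 0.5
            beta_new = beta + step * delta
            eta_new = X @ beta_new
        maxd = np.max(np.abs(beta_new - beta))
        nll1 = _nll(eta_new, y) + 0.5 * n * ridge * np.sum(beta_new**2)
        beta = beta_new
        eta = eta_new
        if maxd < tol:
            converged = True
            break
        if nll0 - nll1 < 1e-12:
            # objective converged: either at the MLE or drifting under
            # quasi-separation with stable predictions
            converged = maxd < 1e-4
            break
    if np.max(np.abs(beta)) > 50.0:
        converged = False
    return beta, converged


@njit(cache=True)
def cv_logit_scores(X, y, fold_ids, n_folds, beta0=None):
    """Out-of-fold logistic probabilities with per-fold standardization.

    For each fold, columns of X are standardized using the training-fold mean
    and population sd (constant columns left unscaled), an intercept column is
    added, the model is fitted on the training folds and held-out subjects are
    scored.  Returns (scores, all_converged).
    """
    n, p = X.shape
    scores = np.empty(n)
    ok = True
    for f in range(n_folds):
        n_tr = 0
        for i in range(n):
            if fold_ids[i] != f:
                n_tr += 1
        Xtr = np.empty((n_tr, p + 1))
        ytr = np.empty(n_tr)
        k = 0
        for i in range(n):
            if fold_ids[i] != f:
                Xtr[k, 0] = 1.0
                for j in range(p):
                    Xtr[k, j + 1] = X[i, j]
                ytr[k] = y[i]
                k += 1
        mus = np.empty(p)
        sds = np.empty(p)
        for j in range(p):
            mu = np.mean(Xtr[:, j + 1])
            sd = np.std(Xtr[:, j + 1])
            if sd <= 0.0:
                mu, sd = 0.0, 1.0
            mus[j] = mu
            sds[j] = sd
            Xtr[:, j + 1] = (Xtr[:, j + 1] - mu) / sd
        beta, conv = newton_logit(Xtr, ytr, 15, 1e-9, beta0)
        if not conv:
            ok = False
        for i in range(n):
            if fold_ids[i] == f:
                eta = beta[0]
                for j in range(p):
                    eta += beta[j + 1] * (X[i, j] - mus[j]) / sds[j]
                scores[i] = 1.0 / (1.0 + np.exp(-eta))
    return scores, ok


@njit(cache=True)
def _soft(z, g):
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


@njit(cache=True)
def lasso_logit_single(X, y, lam, b0, beta, tol=1e-7, max_outer=100, max_inner=10_000):
    """One penalized solve at penalty ``lam`` starting from (b0, beta).

    Cyclic coordinate descent on successive IRLS quadratic approximations;
    mutates nothing (returns new b0, beta, converged).
    """
    n, p = X.shape
    beta = beta.copy()
    eta = b0 + X @ beta
    conv = False
    for _ in range(max_outer):
        pr = 1.0 / (1.0 + np.exp(-eta))
        for i in range(n):
            if pr[i] < 1e-8:
                pr[i] = 1e-8
            elif pr[i] > 1.0 - 1e-8:
                pr[i] = 1.0 - 1e-8
        w = pr * (1.0 - pr)
        z = eta + (y - pr) / w
        b0_start = b0
        beta_start = beta.copy()
        r = z - eta  # residual of the working response
        for _ in range(max_inner):
            maxd = 0.0
            # intercept (unpenalized)
            d0 = np.sum(w * r) / np.sum(w)
            if d0 != 0.0:
                b0 += d0
                r -= d0
                if abs(d0) > maxd:
                    maxd = abs(d0)
            for j in range(p):
                xj = X[:, j]
                wxx = np.sum(w * xj * xj) / n
                num = np.sum(w * xj * r) / n + wxx * beta[j]
                bnew = _soft(num, lam) / wxx
                d = bnew - beta[j]
                if d != 0.0:
                    beta[j] = bnew
                    r -= xj * d
                    if abs(d) > maxd:
                        maxd = abs(d)
            if maxd < tol:
                break
        eta = b0 + X @ beta
        outer_change = abs(b0 - b0_start)
        for j in range(p):
            ch = abs(beta[j] - beta_start[j])
            if ch > outer_change:
                outer_change = ch
        if outer_change < max(tol, 1e-9):
            conv = True
            break
    return b0, beta, conv


@njit(cache=True)
def lasso_path(X, y, lambdas, tol=1e-7):
    """L1-penalized logistic path by coordinate descent on IRLS approximations.

    X must be standardized (mean 0, sd 1 per column); the grid is traversed in
    decreasing order with warm starts.  Returns (intercepts, coefs
    [n_lambda x p], converged flags).
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    intercepts = np.empty(nl)
    coefs = np.empty((nl, p))
    converged = np.ones(nl, dtype=np.bool_)

    ybar = np.mean(y)
    if ybar <= 0.0 or ybar >= 1.0:
        ybar = min(max(ybar, _PMIN), 1.0 - _PMIN)
    b0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    for li in range(nl):
        b0, beta, conv = lasso_logit_single(X, y, lambdas[li], b0, beta, tol)
        intercepts[li] = b0
        coefs[li] = beta
        converged[li] = conv
    return intercepts, coefs, converged


@njit(cache=True)
def loocv_deviance(X, y, lambdas, tol=1e-7):
    """Mean leave-one-out held-out binomial deviance for each penalty value.

    For each left-out subject the path is refitted on the remaining n-1
    subjects (columns restandardized on the training subset) and the held-out
    deviance -2 log L(y_i | p_i) accumulated per lambda.  Each fold/penalty
    solve is warm-started from the full-data path solution at that penalty.
    """
    n, p = X.shape
    nl = lambdas.shape[0]
    dev = np.zeros(nl)

    # full-data path on standardized columns (warm-start source)
    Xs = np.empty((n, p))
    for j in range(p):
        mu = np.mean(X[:, j])
        sd = np.std(X[:, j])
        if sd <= 0.0:
            mu, sd = 0.0, 1.0
        Xs[:, j] = (X[:, j] - mu) / sd
    full_b0, full_coefs, _ = lasso_path(Xs, y, lambdas, tol)

    Xtr = np.empty((n - 1, p))
    ytr = np.empty(n - 1)
    for i in range(n):
        k = 0
        for t in range(n):
            if t != i:
                ytr[k] = y[t]
                for j in range(p):
                    Xtr[k, j] = X[t, j]
                k += 1
        mus = np.empty(p)
        sds = np.empty(p)
        for j in range(p):
            mus[j] = np.mean(Xtr[:, j])
            sd = np.std(Xtr[:, j])
            if sd <= 0.0:
                mus[j] = 0.0
                sd = 1.0
            sds[j] = sd
            Xtr[:, j] = (Xtr[:, j] - mus[j]) / sds[j]
        for li in range(nl):
            b0, beta, _ = lasso_logit_single(
                Xtr, ytr, lambdas[li], full_b0[li], full_coefs[li], tol
            )
            eta = b0
            for j in range(p):
                eta += beta[j] * (X[i, j] - mus[j]) / sds[j]
            pr = 1.0 / (1.0 + np.exp(-eta))
            if pr < _PMIN:
                pr = _PMIN
            elif pr > 1.0 - _PMIN:
                pr = 1.0 - _PMIN
            if y[i] > 0.5:
                dev[li] += -2.0 * np.log(pr)
            else:
                dev[li] += -2.0 * np.log(1.0 - pr)
    return dev / n
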