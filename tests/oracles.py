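"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — explicit matrix inverses, grid
searches, generic optimizers — and shares no code with the package's
fitting machinery, so agreement is evidence of correctness rather than of
shared bugs.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize


def batch_indicator(batch: np.ndarray) -> np.ndarray:
    levels = list(dict.fromkeys(batch.tolist()))
    Z = np.zeros((len(batch), len(levels)))
    for i, b in enumerate(batch):
        Z[i, levels.index(b)] = 1.0
    return Z


def naive_V(params, M, Z, n):
    s2m, s2b, s2e = params
    V = s2e * np.eye(n)
    if M is not None:
        V = V + s2m * M
    if Z is not None and Z.shape[1]:
        V = V + s2b * Z @ Z.T
    return V


def naive_reml_loglik(y, W, params, M=None, Z=None):
    """REML log-likelihood via explicit inverses (up to the same constant)."""
    n = y.size
    V = naive_V(params, M, Z, n)
    Vinv = np.linalg.inv(V)
    B = W.T @ Vinv @ W
    beta = np.linalg.solve(B, W.T @ Vinv @ y)
    r = y - W @ beta
    _, logdetV = np.linalg.slogdet(V)
    _, logdetB = np.linalg.slogdet(B)
    return -0.5 * (logdetV + logdetB + float(r @ Vinv @ r))


def grid_search_reml(y, W, M, Z=None, s2b=0.0, grid_max=None, step=0.01):
    """Exhaustive 2-D grid search over (sigma2_m, sigma2_e)."""
    if grid_max is None:
        grid_max = 2.0 * float(np.var(y, ddof=1))
    grid = np.arange(0.0, grid_max + step, step)
    best, best_ll = None, -np.inf
    for s2m, s2e in itertools.product(grid, grid[1:]):
        ll = naive_reml_loglik(y, W, (s2m, s2b, s2e), M=M, Z=Z)
        if ll > best_ll:
            best, best_ll = (s2m, s2e), ll
    return best, best_ll


def henderson_blup(y, W, M_train, Z, s2m, s2b, s2e):
    """Solve Henderson's mixed-model equations directly on the training data.

    Random effects: g ~ N(0, s2m * M_train) and u ~ N(0, s2b * I_B) with
    design Z. Returns (beta, g_train, u).
    """
    n = y.size
    lam_g = s2e * np.linalg.inv(s2m * M_train)
    blocks = [
        [W.T @ W, W.T @ np.eye(n), W.T @ Z],
        [W, np.eye(n) + lam_g, Z],
        [Z.T @ W, Z.T @ np.eye(n), Z.T @ Z + (s2e / s2b) * np.eye(Z.shape[1])],
    ]
    lhs = np.block(blocks)
    rhs = np.concatenate([W.T @ y, y, Z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    q = W.shape[1]
    return sol[:q], sol[q : q + n], sol[q + n :]


def naive_fit(y, W, M=None, Z=None):
    """Maximize the naive REML likelihood with a generic optimizer.

    Optimizes over log-variances (with components absent when their design
    is absent); returns (sigma2_m, sigma2_batch, sigma2_e).
    """
    n = y.size
    vary = float(np.var(y, ddof=1))
    has_m = M is not None
    has_b = Z is not None and Z.shape[1] > 0

    def unpack(x):
        i = 0
        s2m = np.exp(x[i]) if has_m else 0.0
        i += has_m
        s2b = np.exp(x[i]) if has_b else 0.0
        i += has_b
        return s2m, s2b, np.exp(x[i])

    def neg(x):
        try:
            return -naive_reml_loglik(y, W, unpack(x), M=M, Z=Z)
        except np.linalg.LinAlgError:
            return np.inf

    x0 = np.log(np.full(1 + has_m + has_b, vary / (1 + has_m + has_b)))
    best = None
    for scale in (1.0, 0.1, 3.0):
        res = optimize.minimize(neg, x0 + np.log(scale), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    return unpack(best.x)


def naive_predict(y, W, M_full, train, test, batch, params, Wt=None):
    """BLUP predictions for the test set via explicit V inverse."""
    s2m, s2b, s2e = params
    Z = batch_indicator(batch[train]) if batch is not None else None
    V = naive_V(params, M_full[np.ix_(train, train)], Z, train.size)
    Vinv = np.linalg.inv(V)
    B = W[train].T @ Vinv @ W[train]
    beta = np.linalg.solve(B, W[train].T @ Vinv @ y[train])
    r = y[train] - W[train] @ beta
    pred = W[test] @ beta
    if s2m > 0:
        pred = pred + s2m * M_full[np.ix_(test, train)] @ Vinv @ r
    if s2b > 0 and batch is not None:
        u = s2b * Z.T @ Vinv @ r
        train_levels = list(dict.fromkeys(batch[train].tolist()))
        for k, i in enumerate(test):
            b = batch[i]
            if b in train_levels:
                pred[k] += u[train_levels.index(b)]
    return pred


def naive_cv(y, W, M_full, batch, n_splits, train_fraction, seed, make_split):
    """Independent re-implementation of the Monte-Carlo CV procedure."""
    rng = np.random.default_rng(seed)
    n = y.size
    deltas = []
    for _ in range(n_splits):
        train, test = make_split(n, train_fraction, rng)
        Zb = batch_indicator(batch[train]) if batch is not None else None
        pb = naive_fit(y[train], W[train], M=None, Z=Zb)
        pm = naive_fit(y[train], W[train], M=M_full[np.ix_(train, train)], Z=Zb)
        pred_b = naive_predict(y, W, M_full * 0.0, train, test, batch, pb)
        pred_m = naive_predict(y, W, M_full, train, test, batch, pm)
        r2b = np.corrcoef(pred_b, y[test])[0, 1] ** 2 if np.std(pred_b) > 0 else 0.0
        r2m = np.corrcoef(pred_m, y[test])[0, 1] ** 2 if np.std(pred_m) > 0 else 0.0
        deltas.append(r2m - r2b)
    return float(np.mean(deltas))
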