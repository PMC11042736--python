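"""Independent re-implementations used as oracles by the test suite.

These deliberately re-derive each quantity step by step (loops, dense grids)
rather than reusing the library's vectorized code paths.
"""

import numpy as np
from scipy.stats import rankdata

from cleavemap.diff import _nb_loglik


def naive_tmm(y, N, trim_m=0.30, trim_a=0.05):
    """Step-by-step trimmed-mean-of-M-values recomputation."""
    y = np.asarray(y, float)
    N = np.asarray(N, float)
    q75 = [np.quantile(y[:, j] / N[j], 0.75) for j in range(y.shape[1])]
    ref = int(np.argmin([abs(q - np.mean(q75)) for q in q75]))
    logf = []
    for j in range(y.shape[1]):
        if j == ref:
            logf.append(0.0)
            continue
        M, W, A = [], [], []
        for i in range(y.shape[0]):
            if y[i, j] > 0 and y[i, ref] > 0:
                pj, pr = y[i, j] / N[j], y[i, ref] / N[ref]
                M.append(np.log2(pj / pr))
                A.append(0.5 * np.log2(pj * pr))
                W.append(
                    (N[j] - y[i, j]) / (N[j] * y[i, j])
                    + (N[ref] - y[i, ref]) / (N[ref] * y[i, ref])
                )
        M, A, W = map(np.array, (M, A, W))
        n = len(M)
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        rm, ra = rankdata(M), rankdata(A)
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        f = np.sum(M[keep] / W[keep]) / np.sum(1.0 / W[keep])
        logf.append(0.0 if abs(f) < 1e-6 else f)
    factors = 2.0 ** np.array(logf)
    return factors / np.exp(np.mean(np.log(factors)))


def textbook_bh(p):
    """Benjamini-Hochberg step-up, written as the textbook procedure."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def grid_search_lrt(y, phi, n_split=3, n_grid=20001):
    """Dense grid-search NB maximum-likelihood LRT oracle (equal offsets)."""
    y = np.asarray(y, float)
    grid = np.concatenate(
        [[1e-8], np.exp(np.linspace(np.log(1e-3), np.log(300), n_grid))]
    )

    def best(yy):
        ll = _nb_loglik(yy[None, :, None], grid[None, None, :], phi).sum(axis=1)
        return ll.max()

    llf = best(y[:n_split]) + best(y[n_split:])
    lln = best(y)
    return max(2 * (llf - lln), 0.0)


def poisson_deviance_lrt(y, n_split=3):
    """Closed-form Poisson deviance statistic for the two-group contrast."""
    y = np.asarray(y, float)
    mu_full = np.r_[
        np.repeat(y[:n_split].mean(), n_split),
        np.repeat(y[n_split:].mean(), len(y) - n_split),
    ]
    mu_null = np.repeat(y.mean(), len(y))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_full = np.where(y > 0, y * np.log(y / mu_full), 0.0)
        t_null = np.where(y > 0, y * np.log(y / mu_null), 0.0)
    return 2 * (t_null.sum() - t_full.sum())
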