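"""Independent brute-force and textbook references used to validate the
package.  Nothing here shares code with istclean's own implementations."""

import itertools

import numpy as np
from scipy.stats import poisson


def poisson_mixture_loglik(x, pi, lam_e, lam_c):
    """Direct-probability mixture log-likelihood (no log-sum-exp)."""
    p = pi * poisson.pmf(x, lam_e) + (1 - pi) * poisson.pmf(x, lam_c)
    return float(np.log(p).sum())


def textbook_poisson_mixture_em(
    x, pi0, lam_e0, lam_c0, tol=1e-10, max_iter=2000
):
    """Classic two-component Poisson mixture EM with closed-form M-step.

    Independent of the package: responsibilities via direct pmf ratios,
    rates as responsibility-weighted means.
    """
    x = np.asarray(x, dtype=float)
    pi, le, lc = float(pi0), float(lam_e0), float(lam_c0)
    ll_prev = -np.inf
    for _ in range(max_iter):
        a = pi * poisson.pmf(x, le)
        b = (1 - pi) * poisson.pmf(x, lc)
        tot = a + b
        tot[tot == 0] = 1e-300
        r = a / tot
        ll = float(np.log(tot).sum())
        if abs(ll - ll_prev) < tol * (abs(ll) + 1e-300):
            break
        ll_prev = ll
        pi = float(np.clip(r.mean(), 1e-4, 1 - 1e-4))
        le = max(float((r * x).sum() / max(r.sum(), 1e-12)), 1e-6)
        lc = max(float(((1 - r) * x).sum() / max((1 - r).sum(), 1e-12)), 1e-6)
        if lc > le:
            le, lc = lc, le
            pi = 1 - pi
    return pi, le, lc, ll


def grid_search_poisson_mixture(x, n_pi=22, n_lam=22):
    """Best mixture log-likelihood over a ~10⁴-point (π, λ_e, λ_c) grid."""
    x = np.asarray(x, dtype=float)
    lam_hi = x.max() + 1.0
    pis = np.linspace(0.02, 0.98, n_pi)
    lams = np.geomspace(1e-3, lam_hi, n_lam)
    best = -np.inf
    pmfs = {i: poisson.pmf(x, l) for i, l in enumerate(lams)}
    for i, j in itertools.product(range(n_lam), range(n_lam)):
        if lams[j] > lams[i]:
            continue  # enforce lam_e >= lam_c, halves the grid
        pe, pc = pmfs[i], pmfs[j]
        for pi in pis:
            p = pi * pe + (1 - pi) * pc
            if (p > 0).all():
                ll = float(np.log(p).sum())
                if ll > best:
                    best = ll
    return best


def best_two_partition_gaussian(values, var_floor):
    """Exhaustive maximum-likelihood hard 2-partition of a 1-D sample.

    Scans every nonempty/co-nonempty subset split (feasible for <= ~15
    points) and scores the complete-data Gaussian mixture likelihood.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    best_ll, best_mask = -np.inf, None
    for bits in range(1, 2**n - 1):
        mask = np.array([(bits >> k) & 1 for k in range(n)], dtype=bool)
        g1, g2 = values[mask], values[~mask]
        w = len(g1) / n
        ll = 0.0
        for grp, wk in ((g1, w), (g2, 1 - w)):
            v = max(grp.var(), var_floor)
            ll += (
                len(grp) * np.log(wk)
                - 0.5 * len(grp) * np.log(2 * np.pi * v)
                - 0.5 * ((grp - grp.mean()) ** 2).sum() / v
            )
        if ll > best_ll:
            best_ll, best_mask = ll, mask
    low_is_in_mask = values[best_mask].mean() < values[~best_mask].mean()
    background = best_mask if low_is_in_mask else ~best_mask
    return np.flatnonzero(background), best_ll
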