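"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive each rule from scratch (plain loops, grid
enumeration, direct likelihood evaluation) and share no code with the
package implementation they check.
"""

import numpy as np
from scipy import stats


def oracle_labels(categories, min_duration=2):
    """Exposure labels by direct enumeration of the event/CDI/split rule."""
    sev_map = {"D1": 1, "D2": 2, "D3": 3, "D4": 4}
    n = len(categories)
    labels = ["WET" if str(c).startswith("W") else "NONE" for c in categories]
    i = 0
    while i < n:
        if categories[i] in sev_map:
            j = i
            while j < n and categories[j] in sev_map:
                j += 1
            if j - i >= min_duration:
                sev = [sev_map[c] for c in categories[i:j]]
                cum = [sum(sev[: k + 1]) for k in range(len(sev))]
                half = cum[-1] / 2
                worsening = {k for k in range(len(sev)) if cum[k] <= half}
                if not worsening:
                    worsening = {0}
                split = max(worsening)
                for k, s in enumerate(sev):
                    bucket = "M2SD" if s <= 2 else "S2ED"
                    phase = "WRS" if k <= split else "IMP"
                    labels[i + k] = f"{bucket}_{phase}"
            i = j
        else:
            i += 1
    return labels


def nb2_loglik(y, X, offset, beta, alpha):
    """Direct NB2 log-likelihood evaluation."""
    mu = np.exp(X @ beta + offset)
    r = 1.0 / alpha
    p = r / (r + mu)
    return stats.nbinom.logpmf(y, r, p).sum()


def grid_search_mle(y, X, offset, beta_lo, beta_hi, alpha_grid, rounds=8, width=41):
    """Nested coordinate-sweep grid maximisation of the NB2 likelihood.

    Windows shrink geometrically across rounds so the final resolution
    is far below 0.01 per coefficient.
    """
    k = X.shape[1]
    best_beta, best_alpha, best_ll = np.zeros(k), alpha_grid[0], -np.inf
    for a in alpha_grid:
        beta = np.full(k, (beta_lo + beta_hi) / 2.0)
        w = (beta_hi - beta_lo) / 2.0
        for _ in range(rounds):
            for j in range(k):
                grid = np.linspace(beta[j] - w, beta[j] + w, width)
                lls = [nb2_loglik(y, X, offset, np.r_[beta[:j], g, beta[j + 1:]], a)
                       for g in grid]
                beta[j] = grid[int(np.argmax(lls))]
            w *= 0.4
        ll = nb2_loglik(y, X, offset, beta, a)
        if ll > best_ll:
            best_ll, best_beta, best_alpha = ll, beta.copy(), a
    return best_beta, best_alpha, best_ll


def reml_grid_oracle(y, se, tau2_hi=0.5, n=50_001):
    """Direct restricted-likelihood maximisation on a fine tau2 grid."""
    y, v = np.asarray(y), np.asarray(se) ** 2
    best = (-np.inf, None, None)
    for tau2 in np.linspace(0.0, tau2_hi, n):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        ll = -0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                     + np.sum(w * (y - mu) ** 2))
        if ll > best[0]:
            best = (ll, tau2, mu)
    return best[2], best[1]
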