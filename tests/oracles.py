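"""Independent brute-force oracles used to validate the package's statistics."""

import itertools

import numpy as np


def bh_stepup(pvalues, alpha=0.05):
    """Hand-executed Benjamini-Hochberg step-up: returns (reject mask, adjusted p).

    Sort the m p-values ascending; find the largest i with
    p_(i) <= (i/m) * alpha and reject hypotheses 1..i. Adjusted p-values
    are the running minimum from the top of p_(i) * m / i.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresholds = alpha * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresholds)[0]
    k = below.max() + 1 if below.size else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, ranked[i] * m / (i + 1))
        adj[order[i]] = running
    return reject, adj


def pooled_t(sample1, sample2):
    """Classical two-sample pooled-variance t statistic and two-sided p."""
    from scipy.stats import t as tdist

    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    n1, n2 = a.size, b.size
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, 2 * tdist.sf(abs(t), df)


def mannwhitney_exact(sample1, sample2):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments
    (tie-free samples only; feasible for small combined sizes)."""
    a = np.asarray(sample1, dtype=float)
    b = np.asarray(sample2, dtype=float)
    u_obs = sum((x > y) for x in a for y in b)
    pooled = np.concatenate([a, b])
    n1 = a.size
    us = []
    for combo in itertools.combinations(range(pooled.size), n1):
        ga = pooled[list(combo)]
        gb = np.delete(pooled, list(combo))
        us.append(sum((x > y) for x in ga for y in gb))
    us = np.asarray(us)
    mean_u = a.size * b.size / 2.0
    p = np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u))
    return u_obs, p


def pcr_predict(train_x, train_y, test_x, k):
    """Principal-component regression via raw SVD and normal equations."""
    train_x = np.asarray(train_x, dtype=float)
    test_x = np.asarray(test_x, dtype=float)
    y = np.asarray(train_y, dtype=float)
    mu = train_x.mean(axis=0)
    u, s, vt = np.linalg.svd(train_x - mu, full_matrices=False)
    comp = vt[:k]
    s_train = (train_x - mu) @ comp.T
    s_test = (test_x - mu) @ comp.T
    d = np.column_stack([np.ones(len(y)), s_train])
    beta = np.linalg.solve(d.T @ d, d.T @ y)
    return beta[0] + s_test @ beta[1:]
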