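"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by a route deliberately different from
the package implementation: exact rational enumeration for the HWE test,
direct Newton maximisation of the logistic likelihood, from-scratch greedy
re-scanning for clumping/pruning, and explicit configuration enumeration
for the regional colocalisation posteriors.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by exact rational enumeration


def hwe_exact_p_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational two-sided HWE p-value (conditions on allele counts)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_bb + n_ab
    rare = min(na, 2 * n - na)
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        homr = (rare - h) // 2
        homc = n - h - homr
        weights[h] = Fraction(
            (2**h) * math.factorial(n),
            math.factorial(homr) * math.factorial(h) * math.factorial(homc),
        )
    total = sum(weights.values())
    obs = weights[n_ab]
    p = sum(w for w in weights.values() if w <= obs) / total
    return float(min(p, Fraction(1)))


# ---------------------------------------------------------------------------
# Direct Newton maximisation of the logistic log-likelihood


def newton_logistic(y: np.ndarray, x: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 200):
    """Fit logistic regression by straightforward Newton iteration.

    Returns (beta vector, standard errors, final log-likelihood).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    beta = np.zeros(x.shape[1])
    for _ in range(max_iter):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = x.T @ (y - mu)
        w = mu * (1.0 - mu)
        hess = x.T @ (x * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    ll = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return beta, np.sqrt(np.diag(cov)), ll


def nagelkerke_oracle(ll_model: float, ll0: float, n: int) -> float:
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - ll_model) / n)
    return r2_cs / (1.0 - math.exp(2.0 * ll0 / n))


# ---------------------------------------------------------------------------
# Brute-force greedy clumping / pruning


def greedy_select_oracle(
    keys: np.ndarray,
    ids: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    r2: np.ndarray,
    r2_max: float,
    window: float,
) -> list:
    """From-scratch greedy selection: each round re-scans every remaining
    candidate for the best rank, takes it, and drops window-mates above the
    r² threshold.  ``r2`` is the full pairwise matrix."""
    alive = np.ones(len(keys), dtype=bool)
    picked = []
    while alive.any():
        cand = np.flatnonzero(alive)
        # best rank, ties broken by id
        best = min(cand, key=lambda i: (keys[i], ids[i]))
        picked.append(best)
        alive[best] = False
        for j in np.flatnonzero(alive):
            if (
                chrom[j] == chrom[best]
                and abs(pos[j] - pos[best]) <= window
                and r2[best, j] > r2_max
            ):
                alive[j] = False
    return [ids[i] for i in picked]


def pairwise_r2_oracle(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlations over jointly observed samples."""
    m = dosages.shape[1]
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            both = ~np.isnan(dosages[:, i]) & ~np.isnan(dosages[:, j])
            xi, xj = dosages[both, i], dosages[both, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            out[i, j] = np.corrcoef(xi, xj)[0, 1] ** 2
    return out


# ---------------------------------------------------------------------------
# Colocalisation posteriors by explicit configuration enumeration


def coloc_enumeration_oracle(z1, se1, z2, se2, p1, p2, p12, w1, w2):
    """Enumerate every causal configuration of a block explicitly.

    Configurations: none; variant i causal for trait 1 only; for trait 2
    only; the same i for both; distinct (i, j).  Plain-float arithmetic
    (valid for moderate |z|).
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    se1 = np.asarray(se1, float)
    se2 = np.asarray(se2, float)
    m = len(z1)

    def abf(z, se, w):
        v = se**2
        r = w / (v + w)
        return math.sqrt(1.0 - r) * math.exp(z**2 * r / 2.0)

    bf1 = [abf(z1[i], se1[i], w1) for i in range(m)]
    bf2 = [abf(z2[i], se2[i], w2) for i in range(m)]
    total_prior = m * (p1 + p2 + p12) + m * (m - 1) * p1 * p2
    s = [1.0 - total_prior, 0.0, 0.0, 0.0, 0.0]
    for i in range(m):
        s[1] += p1 * bf1[i]
        s[2] += p2 * bf2[i]
        s[3] += p12 * bf1[i] * bf2[i]
        for j in range(m):
            if j != i:
                s[4] += p1 * p2 * bf1[i] * bf2[j]
    s = np.array(s)
    return s / s.sum()


# ---------------------------------------------------------------------------
# Explicit shuffle permutation for the overlap test


def permutation_pvalue_shuffle_oracle(p1, p2, p_t, B, rng) -> float:
    """Literal index-shuffle implementation of the overlap permutation."""
    from comorbigen.overlap import chi2_2x2

    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    lo1 = p1 < p_t
    n = len(p1)

    def chi2_of(lo2):
        a = int((lo1 & lo2).sum())
        b = int((lo1 & ~lo2).sum())
        c = int((~lo1 & lo2).sum())
        d = n - a - b - c
        try:
            return chi2_2x2(a, b, c, d)[0]
        except Exception:
            return 0.0

    obs = chi2_of(p2 < p_t)
    count = 0
    lo2 = p2 < p_t
    for _ in range(B):
        perm = rng.permutation(n)
        if chi2_of(lo2[perm]) >= obs:
            count += 1
    return count / B
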