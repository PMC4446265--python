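"""Independent reference implementations used to validate the package.

Everything here is deliberately written by a different route than the
implementation it checks: brute force, exhaustive enumeration, generic
numeric optimization, or direct textbook formulas.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import minimize

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", ".": "."}


def rc(pattern: str) -> str:
    return "".join(COMP[c] for c in reversed(pattern))


def exhaustive_canonical_patterns(k: int, max_run: int) -> set[str]:
    """All canonical wildcard patterns by generate-canonicalize-dedupe."""
    out: set[str] = set()
    for n_wild in range(0, max_run + 1):
        for start in range(1, k - n_wild) if n_wild else [0]:
            positions = set(range(start, start + n_wild))
            for letters in itertools.product("ACGT", repeat=k - n_wild):
                it = iter(letters)
                pat = "".join("." if i in positions else next(it) for i in range(k))
                out.add(min(pat, rc(pat)))
    return out


def count_pattern_occurrences(pattern: str, seq: str) -> int:
    """Positions where the pattern OR its reverse complement matches."""
    k = len(pattern)
    n = 0
    for p in range(len(seq) - k + 1):
        window = seq[p:p + k]
        if "N" in window:
            continue
        for q in {pattern, rc(pattern)}:
            if all(c == "." or c == w for c, w in zip(q, window)):
                n += 1
                break
    return n


def pairwise_auroc(scores, labels) -> float:
    """O(n^2) probability that a positive outscores a negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels > 0]
    neg = scores[labels < 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def bh_stepup(p: np.ndarray, alpha: float) -> np.ndarray:
    """Brute-force Benjamini-Hochberg rejection set at level alpha."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= alpha * rank / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def average_linkage_clusters(D: np.ndarray, G: int) -> list[set[int]]:
    """Naive agglomerative average-linkage clustering of a distance matrix."""
    clusters: list[set[int]] = [{i} for i in range(len(D))]
    while len(clusters) > G:
        best = None
        best_d = np.inf
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if d < best_d - 1e-12:
                    best_d = d
                    best = (a, b)
        a, b = best
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return clusters


def logistic_loss_direct(w, X, y) -> float:
    """Plain summed logistic loss, term by term."""
    total = 0.0
    for xi, yi in zip(np.asarray(X), np.asarray(y)):
        total += float(np.log1p(np.exp(-yi * float(np.dot(w, xi)))))
    return total


def min_unpenalized_logistic(X, y) -> float:
    """High-accuracy minimum of the plain logistic loss (L-BFGS)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def f(w):
        return np.logaddexp(0.0, -y * (X @ w)).sum()

    def g(w):
        return X.T @ (-y / (1.0 + np.exp(y * (X @ w))))

    res = minimize(f, np.zeros(X.shape[1]), jac=g, method="L-BFGS-B",
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return float(res.fun)


def _group_arrays(group_of, G):
    gid = np.asarray(group_of) - 1
    lg = np.bincount(gid, minlength=G).astype(float)
    return gid, lg


def min_sgl_objective(X, y, group_of, G, lam1, lam2, exponent=0.5) -> float:
    """Generic-minimizer value of the penalized logistic objective.

    Graduated smoothing of both nonsmooth terms followed by L-BFGS at
    each level; returns the exact (unsmoothed) objective at the final
    point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    gid, lg = _group_arrays(group_of, G)
    gw = lg ** exponent
    w = np.zeros(X.shape[1])
    for eps in (1e-2, 1e-4, 1e-6, 1e-8, 1e-10):
        def f(w):
            gn = np.sqrt(np.bincount(gid, weights=w ** 2, minlength=G) + eps ** 2)
            return (np.logaddexp(0.0, -y * (X @ w)).sum()
                    + lam1 * (gw * gn).sum()
                    + lam2 * np.sqrt(w ** 2 + eps ** 2).sum())

        def g(w):
            gn = np.sqrt(np.bincount(gid, weights=w ** 2, minlength=G) + eps ** 2)
            grad = X.T @ (-y / (1.0 + np.exp(y * (X @ w))))
            return (grad + lam1 * gw[gid] * w / gn[gid]
                    + lam2 * w / np.sqrt(w ** 2 + eps ** 2))

        w = minimize(f, w, jac=g, method="L-BFGS-B",
                     options={"maxiter": 20000, "ftol": 1e-17, "gtol": 1e-12}).x
    gn = np.sqrt(np.bincount(gid, weights=w ** 2, minlength=G))
    return float(np.logaddexp(0.0, -y * (X @ w)).sum()
                 + lam1 * (gw * gn).sum() + lam2 * np.abs(w).sum())


def prox_argmin_numeric(v, group_of, G, tlam1, tlam2, exponent=0.5) -> np.ndarray:
    """Numeric argmin of 0.5||w-v||^2 + t*(group + l1 penalties).

    Graduated smoothing with an exact-Hessian trust-region Newton
    polish; the strong convexity of the quadratic makes the final point
    accurate to ~1e-8.
    """
    v = np.asarray(v, dtype=float)
    gid, lg = _group_arrays(group_of, G)
    gw = lg ** exponent
    w = v.copy()
    for eps in (1e-2, 1e-5, 1e-8, 1e-11):
        def f(w):
            gn = np.sqrt(np.bincount(gid, weights=w ** 2, minlength=G) + eps ** 2)
            return (0.5 * ((w - v) ** 2).sum() + tlam1 * (gw * gn).sum()
                    + tlam2 * np.sqrt(w ** 2 + eps ** 2).sum())

        def g(w):
            gn = np.sqrt(np.bincount(gid, weights=w ** 2, minlength=G) + eps ** 2)
            return ((w - v) + tlam1 * gw[gid] * w / gn[gid]
                    + tlam2 * w / np.sqrt(w ** 2 + eps ** 2))

        def h(w):
            gn = np.sqrt(np.bincount(gid, weights=w ** 2, minlength=G) + eps ** 2)
            H = np.diag(1.0 + tlam1 * gw[gid] / gn[gid]
                        + tlam2 * eps ** 2 / (w ** 2 + eps ** 2) ** 1.5)
            for gi in range(G):
                m = np.nonzero(gid == gi)[0]
                H[np.ix_(m, m)] -= tlam1 * gw[gi] * np.outer(w[m], w[m]) / gn[gi] ** 3
            return H

        w = minimize(f, w, jac=g, hess=h, method="trust-exact",
                     options={"gtol": 1e-14, "maxiter": 2000}).x
    return w


def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


def random_sgl_instance(rng: np.random.Generator, n=60, p=30, G=5):
    """A random non-degenerate two-class count-style instance."""
    X = rng.poisson(1.0, (n, p)).astype(float)
    y = rng.choice([-1, 1], n)
    while len(set(y)) < 2:
        y = rng.choice([-1, 1], n)
    group_of = np.concatenate([np.arange(1, G + 1), rng.integers(1, G + 1, p - G)])
    rng.shuffle(group_of)
    return X, y, group_of
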