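"""Independent brute-force reference implementations for the metrics.

Deliberately written with explicit Python loops and textbook formulas
(no shared code with the package) so they can serve as oracles.
"""

from __future__ import annotations

import math


def sample_sd(values) -> float:
    """Textbook n-1 sample standard deviation."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    if den == 0.0:
        return math.nan
    return num / den


def median(values) -> float:
    s = sorted(values)
    n = len(s)
    if n % 2 == 1:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) / 2


def brute_diff_spread(rows, pairs):
    """rows: list of per-gene expression lists; pairs: (k, l) array indices."""
    sds = []
    for k, l in pairs:
        d = [row[k] - row[l] for row in rows]
        sds.append(sample_sd(d))
    return sum(sds) / len(sds), median(sds)


def brute_abs_spread(rows):
    P = len(rows[0])
    sds = [sample_sd([row[k] for row in rows]) for k in range(P)]
    return sum(sds) / len(sds), median(sds)


def brute_corr_summary(rows):
    """Mean/median pairwise Pearson r; pairs with a constant gene excluded."""
    n = len(rows)
    rs = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            r = pearson(rows[i], rows[j])
            if not math.isnan(r):
                rs.append(r)
    if not rs:
        return math.nan, math.nan
    return sum(rs) / len(rs), median(rs)


def brute_pc1(rows):
    """lambda_1 / trace from a full eigendecomposition of the covariance."""
    import numpy as np

    X = np.asarray(rows, dtype=float)
    cov = np.cov(X, ddof=1)
    cov = np.atleast_2d(cov)
    eig = np.linalg.eigvalsh(cov)
    total = float(eig.sum())
    if total == 0.0:
        return math.nan
    return float(eig[-1] / total)


def brute_descendant_closure(direct, edges):
    """Propagated sets by exhaustive path-following over child->parent edges.

    direct: term -> set of genes; edges: list of (child, parent).
    Returns term -> direct genes of the term plus of every term from
    which a parent-path reaches it.
    """
    terms = set(direct)
    for c, p in edges:
        terms.add(c)
        terms.add(p)
    parents = {t: set() for t in terms}
    for c, p in edges:
        parents[c].add(p)

    def ancestors(t):
        out = set()
        stack = [t]
        while stack:
            cur = stack.pop()
            for p in parents[cur]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    closure = {t: set(direct.get(t, ())) for t in terms}
    for t in terms:
        for anc in ancestors(t):
            closure[anc] |= direct.get(t, set())
    return closure
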