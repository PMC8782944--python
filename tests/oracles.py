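"""Independent brute-force / closed-form oracles used by the test suite.

Everything here is deliberately naive and self-contained so it cannot share
a code path (or a bug) with the package under test.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np


def mannwhitney_exact_p(a, b) -> float:
    """Two-sided Mann-Whitney p by exhaustive enumeration of all labelings.

    p = fraction of C(n, n1) group assignments whose min(U, n1*n2 - U) is
    at most the observed one (ranks computed once on the pooled sample).
    """
    from scipy.stats import rankdata

    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = rankdata(pooled)

    def min_u(idx) -> float:
        u = np.sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2
        return min(u, n1 * n2 - u)

    observed = min_u(range(n1))
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        hits += min_u(idx) <= observed + 1e-12
        total += 1
    return hits / total


def pearson_edge_set(columns: dict[str, np.ndarray], threshold: float) -> set:
    """All-pairs |Pearson r| > threshold filter, straight off the formula."""
    edges = set()
    names = sorted(columns)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            x, y = columns[a], columns[b]
            xc, yc = x - x.mean(), y - y.mean()
            r = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
            if abs(r) > threshold:
                edges.add(frozenset((a, b)))
    return edges


def dense_eigencentrality(adjacency: np.ndarray) -> np.ndarray:
    """Principal eigenvector of a symmetric non-negative adjacency via a
    full dense eigendecomposition, normalized so the maximum entry is 1."""
    values, vectors = np.linalg.eigh(adjacency)
    vec = np.abs(vectors[:, np.argmax(values)])
    return vec / vec.max()


def enumerate_vertices(S: np.ndarray, bounds: list[tuple[float, float]],
                       tol: float = 1e-9) -> np.ndarray:
    """All vertices of the polytope {v : S v = 0, lb <= v <= ub}.

    A vertex is a basic feasible solution: fix enough variables at a finite
    bound so the remaining square-ish system has a unique solution, solve,
    keep feasible points, deduplicate.
    """
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    vertices = []
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        S_free = S[:, free]
        if free and np.linalg.matrix_rank(S_free) < len(free):
            continue
        choices = []
        for j in fixed:
            lo, hi = bounds[j]
            opts = [x for x in (lo, hi) if np.isfinite(x)]
            if not opts:
                break
            choices.append(sorted(set(opts)))
        else:
            for assignment in product(*choices) if choices else [()]:
                v = np.zeros(n)
                for j, val in zip(fixed, assignment):
                    v[j] = val
                rhs = -S[:, list(fixed)] @ np.array(assignment) if fixed else np.zeros(m)
                if free:
                    sol, residual, *_ = np.linalg.lstsq(S_free, rhs, rcond=None)
                    if np.max(np.abs(S_free @ sol - rhs)) > tol:
                        continue
                    v[free] = sol
                ok = all(
                    bounds[j][0] - tol <= v[j] <= bounds[j][1] + tol
                    for j in range(n)
                )
                if ok and np.max(np.abs(S @ v)) <= tol:
                    vertices.append(v)
    if not vertices:
        return np.empty((0, n))
    unique = []
    for v in vertices:
        if not any(np.allclose(v, u, atol=1e-7) for u in unique):
            unique.append(v)
    return np.array(unique)


def ddct_recompute(ct_rows: list[dict], control_group: str) -> list[float]:
    """Spreadsheet-style ddCt fold recomputation, plain Python arithmetic."""
    dcts = [row["ct_target"] - row["ct_reference"] for row in ct_rows]
    control = [d for d, row in zip(dcts, ct_rows) if row["group"] == control_group]
    control_mean = sum(control) / len(control)
    return [2.0 ** (-(d - control_mean)) for d in dcts]


def hypergeom_tail_direct(overlap: int, M: int, K: int, n: int) -> float:
    """P(X >= overlap) by direct combinatorial summation."""
    from math import comb

    total = comb(M, n)
    acc = 0
    for k in range(overlap, min(K, n) + 1):
        acc += comb(K, k) * comb(M - K, n - k)
    return acc / total
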