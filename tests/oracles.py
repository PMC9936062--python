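"""Independent brute-force oracles used to validate the fast implementations.

Each oracle deliberately avoids the code path it checks: per-base boolean
arrays for interval arithmetic, full 3^n path enumeration for HMM decoding,
exact rational hypergeometric enumeration for the Fisher test, 2^n subset
enumeration for maximal cliques, and full permutation enumeration for the
Spearman p-value.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb, factorial

import numpy as np

from cnvburden.intervals import GenomicInterval

# ---------------------------------------------------------------- intervals


def per_base_overlap(a: GenomicInterval, b: GenomicInterval, limit: int = 100_000) -> int:
    """Overlap length by materializing per-base boolean arrays."""
    if a.chrom != b.chrom:
        return 0
    arr_a = np.zeros(limit, dtype=bool)
    arr_b = np.zeros(limit, dtype=bool)
    arr_a[a.start : a.end] = True
    arr_b[b.start : b.end] = True
    return int((arr_a & arr_b).sum())


def per_base_union_length(ivs, limit: int = 100_000) -> int:
    """Union size by per-base flags, one array per chromosome."""
    arrays: dict[str, np.ndarray] = {}
    for iv in ivs:
        arr = arrays.setdefault(iv.chrom, np.zeros(limit, dtype=bool))
        arr[iv.start : iv.end] = True
    return int(sum(arr.sum() for arr in arrays.values()))


def per_base_overlap_fraction(query: GenomicInterval, refs, limit: int = 100_000) -> float:
    cov = np.zeros(limit, dtype=bool)
    for r in refs:
        if r.chrom == query.chrom:
            cov[r.start : r.end] = True
    return float(cov[query.start : query.end].sum() / query.length)


# ---------------------------------------------------------------- HMM paths


def exhaustive_best_path(z, targets, hp) -> tuple[np.ndarray, float, float]:
    """Argmax state path by enumerating all 3^n paths.

    Returns (best path, best log-prob, runner-up log-prob); the runner-up
    lets callers assert the argmax is unique before comparing paths.
    """
    z = np.asarray(z, dtype=float)
    n = len(targets)
    mids = np.array([(t.start + t.end) / 2.0 for t in targets])
    gaps = np.abs(np.diff(mids))
    means = np.array([-hp.emission_shift, 0.0, hp.emission_shift])
    loglik = -0.5 * (z[:, None] - means[None, :]) ** 2 - 0.5 * np.log(2 * np.pi)
    paths = np.array(
        np.meshgrid(*[range(3)] * n, indexing="ij")
    ).reshape(n, -1).T  # (3^n, n)
    emis = loglik[np.arange(n)[None, :], paths].sum(axis=1)
    scores = hp.initial_log_probs[paths[:, 0]] + emis
    for t in range(1, n):
        loga = hp.transition_log_matrix(gaps[t - 1])
        scores += loga[paths[:, t - 1], paths[:, t]]
    order = np.argsort(scores)
    best, second = order[-1], order[-2] if len(order) > 1 else order[-1]
    return paths[best], float(scores[best]), float(scores[second])


# ------------------------------------------------------------------- Fisher


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided point-probability Fisher p as an exact rational."""
    r1, r2, c1 = a + b, c + d, a + c
    obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        w = comb(r1, k) * comb(r2, c1 - k)
        if w <= obs:
            total += w
    return Fraction(total, comb(r1 + r2, c1))


# ------------------------------------------------------------------ cliques


def brute_force_maximal_cliques(nodes, edges) -> set[frozenset]:
    """All maximal cliques by 2^n subset enumeration (n <= ~15)."""
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for x, y in edges:
        adj[x].add(y)
        adj[y].add(x)
    n = len(nodes)
    cliques = []
    for mask in range(1, 1 << n):
        members = [nodes[i] for i in range(n) if mask >> i & 1]
        if all(
            b in adj[a] for a, b in itertools.combinations(members, 2)
        ):
            cliques.append(set(members))
    maximal = set()
    for c in cliques:
        if not any(c < other for other in cliques):
            maximal.add(frozenset(c))
    return maximal


def brute_force_mcc(nodes, edges) -> dict:
    scores = {v: 0 for v in nodes}
    for clique in brute_force_maximal_cliques(nodes, edges):
        w = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


# ----------------------------------------------------------------- Spearman


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _pearson(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def spearman_permutation_p(x, y) -> tuple[float, float]:
    """(rho, two-sided p) by enumerating every permutation of y."""
    rx, ry = _midranks(x), _midranks(y)
    rho = _pearson(rx, ry)
    hits = total = 0
    for perm in itertools.permutations(ry):
        if abs(_pearson(rx, list(perm))) >= abs(rho) - 1e-12:
            hits += 1
        total += 1
    return rho, hits / total
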