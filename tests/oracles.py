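"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (closed
forms, exhaustive enumeration, truncated series) and never calls into
trialflow, so agreement between package and oracle is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# M/M/c queue (Erlang-C)
# ---------------------------------------------------------------------------


def erlang_b(c: int, a: float) -> float:
    """Erlang blocking probability by the stable recurrence."""
    b = 1.0
    for n in range(1, c + 1):
        b = a * b / (n + a * b)
    return b


def erlang_c(c: int, a: float) -> float:
    """Probability an arrival waits in an M/M/c queue with offered load a."""
    rho = a / c
    b = erlang_b(c, a)
    return b / (1.0 - rho * (1.0 - b))


def mmc_mean_wait(lam: float, mean_service: float, c: int) -> float:
    """Mean queueing delay Wq of an M/M/c queue (days)."""
    a = lam * mean_service
    rho = a / c
    if rho >= 1.0:
        raise ValueError("unstable queue")
    pw = erlang_c(c, a)
    return pw * mean_service / (c * (1.0 - rho))


def mmc_mean_queue_length(lam: float, mean_service: float, c: int) -> float:
    """Time-average number waiting Lq = λ·Wq."""
    return lam * mmc_mean_wait(lam, mean_service, c)


# ---------------------------------------------------------------------------
# digraph centralities by exhaustive enumeration
# ---------------------------------------------------------------------------


def all_digraphs(n: int):
    """Every simple digraph on nodes 0..n-1 (no self-loops), as edge sets."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    for bits in range(2 ** len(pairs)):
        yield {pairs[k] for k in range(len(pairs)) if bits >> k & 1}


def _distances(n: int, edges: set) -> list[list[float]]:
    """All-pairs geodesic distances by Floyd–Warshall on unit weights."""
    inf = math.inf
    d = [[0.0 if i == j else (1.0 if (i, j) in edges else inf) for j in range(n)]
         for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def brute_degree(n: int, edges: set) -> dict[int, tuple[int, int]]:
    return {v: (sum(1 for (i, j) in edges if j == v),
                sum(1 for (i, j) in edges if i == v)) for v in range(n)}


def brute_harmonic_closeness(n: int, edges: set) -> dict[int, tuple[float, float]]:
    """(in, out) harmonic closeness: Σ 1/d over reachable pairs."""
    d = _distances(n, edges)
    out = {}
    for v in range(n):
        inc = sum(1.0 / d[u][v] for u in range(n) if u != v and math.isfinite(d[u][v]))
        outc = sum(1.0 / d[v][u] for u in range(n) if u != v and math.isfinite(d[v][u]))
        out[v] = (inc, outc)
    return out


def brute_betweenness(n: int, edges: set) -> dict[int, float]:
    """σ_st(v)/σ_st summed over ordered pairs, by enumerating simple paths."""
    adj = {i: [j for j in range(n) if (i, j) in edges] for i in range(n)}
    d = _distances(n, edges)

    def geodesics(s, t):
        """All shortest s→t paths by depth-first search bounded by d[s][t]."""
        target_len = d[s][t]
        if not math.isfinite(target_len):
            return []
        paths = []

        def walk(node, path):
            if node == t:
                if len(path) - 1 == target_len:
                    paths.append(list(path))
                return
            if len(path) - 1 >= target_len:
                return
            for nxt in adj[node]:
                if nxt not in path and (len(path) - 1) + 1 + d[nxt][t] == target_len:
                    path.append(nxt)
                    walk(nxt, path)
                    path.pop()

        walk(s, [s])
        return paths

    bt = dict.fromkeys(range(n), 0.0)
    for s, t in itertools.permutations(range(n), 2):
        paths = geodesics(s, t)
        if not paths:
            continue
        sigma = len(paths)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bt[v] += through / sigma
    return bt


def brute_bonacich(n: int, edges: set, beta: float, terms: int = 200) -> dict[int, float]:
    """Power index via the truncated series Σ_{k≥0} β^k A^{k+1} 1, rescaled."""
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = 1.0
        a[j, i] = 1.0
    np.fill_diagonal(a, 0.0)
    acc = np.zeros(n)
    term = a @ np.ones(n)
    acc += term
    for k in range(1, terms):
        term = beta * (a @ term)
        acc += term
    ssq = float(acc @ acc)
    if ssq == 0.0:
        return dict.fromkeys(range(n), 0.0)
    alpha = math.sqrt(n / ssq)
    return {v: float(alpha * acc[v]) for v in range(n)}


def spectral_radius(n: int, edges: set) -> float:
    a = np.zeros((n, n))
    for i, j in edges:
        a[i, j] = 1.0
        a[j, i] = 1.0
    np.fill_diagonal(a, 0.0)
    if not a.any():
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvalsh(a))))


# ---------------------------------------------------------------------------
# pooled-variance t test
# ---------------------------------------------------------------------------


def pooled_t(x, y) -> float:
    """Hand-computed equal-variance two-sample t statistic."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny)))
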