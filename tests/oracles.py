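"""Independent oracles used to cross-check the production implementations.

Everything here deliberately avoids the code paths it is used to verify:
W1 via exact rational min-cost flow (networkx network simplex) and via
exhaustive enumeration of transportation-polytope vertices; Spearman via
manual ranking plus the Pearson product-moment formula; Benjamini-Hochberg
via the literal step-up definition.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np
from scipy import stats

from braincurv import BrainNetwork


# ---------------------------------------------------------------------------
# Exact W1 via min-cost flow on integer-scaled masses
# ---------------------------------------------------------------------------

def exact_node_measure(network: BrainNetwork, x: int) -> dict[int, Fraction]:
    """mu_x as exact rationals; requires integer-valued weights."""
    row = network.weights[x]
    support = np.flatnonzero(row > 0)
    assert np.array_equal(row, np.round(row)), "oracle needs integer weights"
    degree = int(row[support].sum())
    return {int(y): Fraction(int(row[y]), degree) for y in support}


def mcf_wasserstein1(
    mu: dict[int, Fraction], nu: dict[int, Fraction], distances: np.ndarray
) -> float:
    """W1 between rational measures with integer ground distances, exactly.

    Scales both measures by the common denominator and solves integer
    min-cost flow with networkx's network simplex; the result is a ratio
    of integers, converted to float only at the end.
    """
    denom = math.lcm(
        *[m.denominator for m in mu.values()],
        *[m.denominator for m in nu.values()],
    )
    graph = nx.DiGraph()
    for i, mass in mu.items():
        graph.add_node(("s", i), demand=-int(mass * denom))
    for j, mass in nu.items():
        graph.add_node(("t", j), demand=int(mass * denom))
    for i in mu:
        for j in nu:
            d = distances[i, j]
            assert np.isfinite(d) and d == int(d)
            graph.add_edge(("s", i), ("t", j), weight=int(d))
    cost, _ = nx.network_simplex(graph)
    return float(Fraction(cost, denom))


def oracle_edge_curvature(network: BrainNetwork, x: int, y: int) -> float:
    """Hop-metric Ollivier-Ricci curvature via the exact flow oracle."""
    graph = nx.from_numpy_array(network.weights)
    hop = dict(nx.all_pairs_shortest_path_length(graph))
    n = network.n_nodes
    distances = np.full((n, n), np.inf)
    for a, row in hop.items():
        for b, d in row.items():
            distances[a, b] = d
    w1 = mcf_wasserstein1(
        exact_node_measure(network, x), exact_node_measure(network, y), distances
    )
    return 1.0 - w1 / distances[x, y]


# ---------------------------------------------------------------------------
# Brute-force W1 via transportation-polytope vertex enumeration
# ---------------------------------------------------------------------------

def polytope_vertex_w1(
    mu_masses: np.ndarray, nu_masses: np.ndarray, ground: np.ndarray
) -> float:
    """Minimum cost over all basic feasible solutions (polytope vertices).

    Every vertex of the transportation polytope has at most m+n-1 positive
    cells, so enumerating all cell subsets of that size and solving the
    marginal equations visits every vertex. Only viable for tiny supports.
    """
    m, n = ground.shape
    cells = list(itertools.product(range(m), range(n)))
    n_basic = m + n - 1
    b = np.concatenate([mu_masses, nu_masses])
    best = np.inf
    for subset in itertools.combinations(cells, n_basic):
        a = np.zeros((m + n, n_basic))
        for k, (i, j) in enumerate(subset):
            a[i, k] = 1.0
            a[m + j, k] = 1.0
        x, *_ = np.linalg.lstsq(a, b, rcond=None)
        if np.abs(a @ x - b).max() > 1e-10 or (x < -1e-10).any():
            continue
        cost = sum(ground[i, j] * x[k] for k, (i, j) in enumerate(subset))
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# Rank-correlation and multiple-testing oracles
# ---------------------------------------------------------------------------

def manual_ranks(values) -> np.ndarray:
    """Average ranks computed from first principles (1-based)."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = np.empty(len(values))
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def manual_spearman(x, y) -> tuple[float, float]:
    """Rank both vectors by hand, then apply the Pearson formula and the
    two-sided t approximation."""
    rx, ry = manual_ranks(x), manual_ranks(y)
    n = len(rx)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    r = float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, float(2 * stats.t.sf(abs(t), df=n - 2))


def stepup_bh(pvalues, alpha: float):
    """Benjamini-Hochberg exactly as defined: find the largest k with
    p_(k) <= alpha*k/m, reject the k smallest; q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    q_sorted = np.empty(m)
    running = np.inf
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, reject
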