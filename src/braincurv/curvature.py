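"""Ollivier-Ricci curvature on weighted graphs.

The curvature of an edge compares how far apart the one-step random-walk
neighborhoods of its endpoints are, relative to the endpoints themselves:

    k(x, y) = 1 - W1(mu_x, mu_y) / d(x, y)

where ``d`` is the graph metric (hop count by default), ``mu_x`` is the
probability measure placing mass ``w_xy / d_x`` on each neighbor ``y`` of
``x`` (``d_x`` the weighted degree), and ``W1`` is the Wasserstein-1 /
Earth Mover's Distance between the two measures under the ground metric
``d``. Positive curvature means the neighborhoods are closer than their
centers — many triangles, strong feedback, a robust connection; negative
curvature marks tree-like, fragile bridges.

The random walk is *non-lazy*: no mass stays at the base node. Much
published software defaults to a lazy walk with idleness 0.5 — the two
conventions give different numbers, so the choice is stated here once.

The node-level scalar curvature contracts edge curvature the way scalar
curvature contracts the Ricci tensor:

    S(x) = sum_y mu_x(y) * k(x, y)   over neighbors y of x,

a convex combination of the incident edge curvatures.

W1 is solved exactly as a minimum-cost transportation linear program over
the two (small) neighbor supports with ground distances taken on the full
graph; scipy's HiGHS backend is the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog
from scipy.sparse.csgraph import shortest_path

from .io import BrainNetwork

MetricKind = Literal["hop", "weighted"]

#: Feasibility tolerance for the transport linear program.
LP_TOL = 1e-9


class CurvatureError(ValueError):
    """Curvature is undefined for the requested node or edge."""


# ---------------------------------------------------------------------------
# Graph metric
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphMetric:
    """All-pairs distances on a network.

    ``hop`` counts edges on the shortest path (every positive-weight edge has
    length 1); ``weighted`` uses edge length ``1/w`` so that strong
    connections are short. Unreachable pairs hold ``inf``.
    """

    distances: np.ndarray = field(repr=False)
    metric_kind: MetricKind = "hop"

    def is_reachable(self, x: int, y: int) -> bool:
        return bool(np.isfinite(self.distances[x, y]))


def compute_graph_metric(
    network: BrainNetwork, metric_kind: MetricKind = "hop"
) -> GraphMetric:
    """All-pairs shortest-path distances under the chosen edge length."""
    w = network.weights
    if metric_kind == "hop":
        graph = sparse.csr_matrix((w > 0).astype(float))
        dist = shortest_path(graph, method="D", unweighted=True, directed=False)
    elif metric_kind == "weighted":
        lengths = np.zeros_like(w)
        mask = w > 0
        lengths[mask] = 1.0 / w[mask]
        dist = shortest_path(
            sparse.csr_matrix(lengths), method="D", directed=False
        )
    else:
        raise ValueError(f"unknown metric_kind {metric_kind!r}")
    return GraphMetric(distances=dist, metric_kind=metric_kind)


# ---------------------------------------------------------------------------
# Node probability measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityMeasure:
    """One-step non-lazy random-walk distribution at a node.

    ``support`` lists the neighbors of ``base_node``; ``masses[i]`` is the
    probability of stepping to ``support[i]``, i.e. edge weight over weighted
    degree. The base node itself carries no mass.
    """

    base_node: int
    support: np.ndarray
    masses: np.ndarray
    weighted_degree: float


def node_measure(network: BrainNetwork, x: int) -> ProbabilityMeasure:
    """The measure mu_x(y) = w_xy / d_x over neighbors y of x."""
    row = network.weights[x]
    support = np.flatnonzero(row > 0)
    degree = float(row[support].sum())
    if support.size == 0 or degree <= 0:
        raise CurvatureError(
            f"node {x} ({network.node_ids[x]}) is isolated; "
            "its random-walk measure is undefined"
        )
    return ProbabilityMeasure(
        base_node=x,
        support=support,
        masses=row[support] / degree,
        weighted_degree=degree,
    )


# ---------------------------------------------------------------------------
# Wasserstein-1 by linear programming
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportPlan:
    """An optimal transport plan and its cost (the W1 value).

    Only the cost is unique in general; degenerate problems admit many
    optimal plans with the same cost.
    """

    cost: float
    sources: np.ndarray
    targets: np.ndarray
    plan: np.ndarray = field(repr=False)


def wasserstein1(
    mu: ProbabilityMeasure, nu: ProbabilityMeasure, metric: GraphMetric
) -> TransportPlan:
    """Minimum-cost transport between two node measures.

    Solves the transportation LP
    ``min sum_ij d(i, j) T_ij  s.t.  T 1 = mu, T' 1 = nu, T >= 0``
    restricted to the two supports, with ground distances from the full
    graph. Raises if any source-target pair is unreachable (the measures
    then live in different components and no finite-cost plan exists).
    """
    ground = metric.distances[np.ix_(mu.support, nu.support)]
    if not np.isfinite(ground).all():
        i, j = np.argwhere(~np.isfinite(ground))[0]
        raise CurvatureError(
            f"nodes {mu.support[i]} and {nu.support[j]} are in different "
            "components; W1 is infinite"
        )
    m, n = ground.shape
    # Marginal constraints; one row is redundant but HiGHS copes.
    row_idx = np.repeat(np.arange(m), n)
    col_idx = np.tile(np.arange(n), m) + m
    cells = np.arange(m * n)
    a_eq = sparse.coo_matrix(
        (
            np.ones(2 * m * n),
            (np.concatenate([row_idx, col_idx]), np.concatenate([cells, cells])),
        ),
        shape=(m + n, m * n),
    ).tocsr()
    b_eq = np.concatenate([mu.masses, nu.masses])
    res = linprog(
        ground.ravel(),
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=(0, None),
        method="highs",
    )
    if res.status != 0:
        raise CurvatureError(f"transport LP failed: {res.message}")
    plan = res.x.reshape(m, n)
    return TransportPlan(
        cost=float(res.fun),
        sources=mu.support.copy(),
        targets=nu.support.copy(),
        plan=plan,
    )


# ---------------------------------------------------------------------------
# Edge and scalar curvature
# ---------------------------------------------------------------------------

def edge_curvature(
    network: BrainNetwork,
    x: int,
    y: int,
    metric: GraphMetric,
    _measures: dict[int, ProbabilityMeasure] | None = None,
) -> float:
    """k(x, y) = 1 - W1(mu_x, mu_y) / d(x, y) for an edge with w_xy > 0."""
    if network.weights[x, y] <= 0:
        raise CurvatureError(f"no edge between nodes {x} and {y}")
    if _measures is not None:
        mu, nu = _measures[x], _measures[y]
    else:
        mu, nu = node_measure(network, x), node_measure(network, y)
    d_xy = metric.distances[x, y]
    w1 = wasserstein1(mu, nu, metric).cost
    return 1.0 - w1 / d_xy


@dataclass(frozen=True)
class CurvatureResult:
    """Edge curvatures keyed by (i, j) with i < j, and per-node scalars."""

    edge_curvature: dict[tuple[int, int], float]
    scalar_curvature: dict[int, float]
    metric_kind: MetricKind = "hop"


def scalar_curvature(
    network: BrainNetwork, edge_curvatures: CurvatureResult, x: int
) -> float:
    """Contract edge curvature to a node: S(x) = sum_y mu_x(y) k(x, y)."""
    mu = node_measure(network, x)  # raises for isolated nodes
    total = 0.0
    for y, mass in zip(mu.support, mu.masses):
        key = (min(x, int(y)), max(x, int(y)))
        total += mass * edge_curvatures.edge_curvature[key]
    return total


def all_edge_curvatures(
    network: BrainNetwork, metric_kind: MetricKind = "hop"
) -> CurvatureResult:
    """Curvature for every positive-weight edge and every non-isolated node.

    Distances and node measures are computed once and shared across edges.
    Keys are unordered pairs stored lower-index-first, in sorted order, so
    downstream output files are reproducible byte for byte.
    """
    metric = compute_graph_metric(network, metric_kind)
    edges = network.edges()
    measures: dict[int, ProbabilityMeasure] = {}
    for i, j in edges:
        for node in (i, j):
            if node not in measures:
                measures[node] = node_measure(network, node)
    edge_k: dict[tuple[int, int], float] = {}
    for i, j in edges:
        try:
            edge_k[(i, j)] = edge_curvature(network, i, j, metric, measures)
        except CurvatureError as exc:
            raise CurvatureError(
                f"edge ({network.node_ids[i]}, {network.node_ids[j]}): {exc}"
            ) from exc
    result = CurvatureResult(edge_curvature=edge_k, scalar_curvature={},
                             metric_kind=metric_kind)
    for x in sorted(measures):
        mu = measures[x]
        total = 0.0
        for y, mass in zip(mu.support, mu.masses):
            key = (min(x, int(y)), max(x, int(y)))
            total += mass * edge_k[key]
        result.scalar_curvature[x] = total
    return result


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def curvature_tables(
    network: BrainNetwork, result: CurvatureResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge and node curvature tables with deterministic row order."""
    edge_rows = [
        {
            "node_a": network.node_ids[i],
            "node_b": network.node_ids[j],
            "weight": network.weights[i, j],
            "curvature": k,
        }
        for (i, j), k in sorted(result.edge_curvature.items())
    ]
    node_rows = [
        {"node": network.node_ids[x], "scalar_curvature": s}
        for x, s in sorted(result.scalar_curvature.items())
    ]
    edge_cols = ["node_a", "node_b", "weight", "curvature"]
    node_cols = ["node", "scalar_curvature"]
    return (
        pd.DataFrame(edge_rows, columns=edge_cols),
        pd.DataFrame(node_rows, columns=node_cols),
    )


def write_curvature_tables(
    network: BrainNetwork,
    result: CurvatureResult,
    edge_path: str | Path,
    node_path: str | Path,
) -> None:
    edges, nodes = curvature_tables(network, result)
    edges.to_csv(edge_path, sep="\t", index=False, float_format="%.17g")
    nodes.to_csv(node_path, sep="\t", index=False, float_format="%.17g")
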