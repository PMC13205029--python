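"""Graph indexes of the binary HF network: PageRank, density, node entropy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cte import BinaryAdjacency

__all__ = [
    "GraphIndexes",
    "pagerank",
    "graph_density",
    "node_entropy",
    "temporal_node_entropy",
    "graph_indexes",
]

#: Entropy floor (bits) so H can safely divide the HF* coefficient.
ENTROPY_FLOOR = 0.01


@dataclass
class GraphIndexes:
    pr: np.ndarray
    density: float
    entropy: np.ndarray
    damping: float
    n_iterations: int
    entropy_mode: str


def pagerank(
    adj: BinaryAdjacency,
    d: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int]:
    """Damped PageRank by power iteration on the directed HF network.

    PR(i) = (1-d)/N + d * sum_{j -> i} PR(j)/C(j), with the mass of dangling
    nodes (C(j) = 0) redistributed uniformly so the scores remain a
    probability distribution (sum = 1).  Returns (pr, iterations); raises on
    non-convergence (max-abs change >= tol after max_iter sweeps).
    """
    if not (0 < d < 1):
        raise ValueError(f"damping must lie in (0, 1), got {d}")
    n = adj.n_nodes
    if n < 1:
        raise ValueError("graph must have at least one node")
    M = adj.Mbin.astype(float)
    out_deg = M.sum(axis=1)
    dangling = out_deg == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(out_deg[:, None] > 0, M / np.where(out_deg == 0, 1, out_deg)[:, None], 0.0)
    pr = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        inflow = T.T @ pr + pr[dangling].sum() / n
        new = (1 - d) / n + d * inflow
        if np.max(np.abs(new - pr)) < tol:
            return new, it
        pr = new
    raise RuntimeError(f"PageRank power iteration did not converge in {max_iter} sweeps")


def graph_density(adj: BinaryAdjacency) -> float:
    """Directed density |E| / (N (N-1)); the diagonal never counts."""
    n = adj.n_nodes
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return adj.n_edges / (n * (n - 1))


def _binary_entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


def node_entropy(
    adj: BinaryAdjacency, i: int, mode: str = "node", floor: float = ENTROPY_FLOOR
) -> float:
    """Shannon entropy (bits) of node i's binary connectivity pattern.

    ``"node"`` (default): Bernoulli entropy of the node's empirical
    link-presence probability p_i = (in-degree + out-degree) / (2 (N-1)),
    i.e. over its 2(N-1) possible incident links.  ``"global"``: the same
    construction on the whole graph's N(N-1) link indicators (identical for
    every node).  The result is clamped below at ``floor`` bits so it can
    divide the HF* coefficient even for perfectly ordered patterns.
    """
    n = adj.n_nodes
    if n < 2:
        raise ValueError("entropy needs at least 2 nodes")
    if mode == "node":
        deg = int(adj.Mbin[i].sum() + adj.Mbin[:, i].sum())
        p = deg / (2 * (n - 1))
    elif mode == "global":
        p = adj.n_edges / (n * (n - 1))
    else:
        raise ValueError(f"unknown entropy mode {mode!r}")
    return max(_binary_entropy(p), floor)


def temporal_node_entropy(
    adjacencies: list[BinaryAdjacency], i: int, floor: float = ENTROPY_FLOOR
) -> float:
    """Entropy of node i's incident-link states pooled across a window stack
    of adjacencies (the temporal reading of the connectivity-pattern
    entropy); needs at least two frames to be meaningful."""
    if len(adjacencies) < 1:
        raise ValueError("at least one adjacency is required")
    states = []
    for adj in adjacencies:
        n = adj.n_nodes
        inc = np.concatenate([np.delete(adj.Mbin[i], i), np.delete(adj.Mbin[:, i], i)])
        states.append(inc)
    p = float(np.concatenate(states).mean())
    return max(_binary_entropy(p), floor)


def graph_indexes(
    adj: BinaryAdjacency,
    damping: float = 0.85,
    entropy_mode: str = "node",
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> GraphIndexes:
    """PageRank, density and per-node entropy of one binary adjacency."""
    pr, iters = pagerank(adj, d=damping, tol=tol, max_iter=max_iter)
    dens = graph_density(adj)
    ent = np.array([node_entropy(adj, i, mode=entropy_mode) for i in range(adj.n_nodes)])
    return GraphIndexes(
        pr=pr,
        density=dens,
        entropy=ent,
        damping=damping,
        n_iterations=iters,
        entropy_mode=entropy_mode,
    )
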