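"""Brute-force reference optimizer for tiny networks.

Enumerates every node-state assignment in {-1, 0, +1}^n, keeps the causally
consistent ones (every nonzero non-root state must be derivable from the
roots through sign-consistent edges, which a monotone closure certifies as
acyclic), and minimizes the same objective the ILP engine optimizes.  Cost is
3^n assignments, so this is only usable for n up to ~12 nodes; it exists as
an independent cross-check of the ILP path, not as a solver.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from causalnet.core import (
    InputError,
    MeasurementSet,
    NodePenaltyWeights,
    PerturbationSet,
    SignedNetwork,
    UNKNOWN,
)

_MAX_NODES = 13


def enumerate_consistent(
    pkn: SignedNetwork,
    roots: Mapping[str, int],
) -> tuple[list[str], np.ndarray]:
    """All causally consistent state assignments.

    Returns the sorted node order and a (n_consistent, n_nodes) matrix of
    states.  ``roots`` maps root nodes to +1/-1 (state fixed) or UNKNOWN
    (state free); root nodes need no causal support, every other node with a
    nonzero state must be reachable from already-supported nodes through a
    sign-consistent edge.
    """
    nodes = sorted(pkn.nodes)
    n = len(nodes)
    if n > _MAX_NODES:
        raise InputError(f"exhaustive enumeration limited to {_MAX_NODES} nodes")
    idx = {v: j for j, v in enumerate(nodes)}

    # all 3^n assignments by base-3 counting
    grid = np.indices((3,) * n).reshape(n, -1).T - 1  # values in {-1,0,1}
    mask = np.ones(len(grid), dtype=bool)
    for v, eff in roots.items():
        if eff in (1, -1):
            mask &= grid[:, idx[v]] == eff
    grid = grid[mask]

    placed = np.zeros(grid.shape, dtype=bool)
    for v in roots:
        placed[:, idx[v]] = True
    placed |= grid == 0  # zero states need no support
    edge_idx = [(idx[s], idx[t], sign) for s, t, sign in pkn.edges]
    for _ in range(n):
        before = placed.sum()
        for i, j, sign in edge_idx:
            support = placed[:, i] & (grid[:, i] != 0) & (grid[:, i] * sign == grid[:, j])
            placed[:, j] |= support
        if placed.sum() == before:
            break
    consistent = placed.all(axis=1)
    return nodes, grid[consistent]


def assignment_objectives(
    nodes: list[str],
    states: np.ndarray,
    measured: Mapping[str, tuple[float, int]],
    gamma: Mapping[str, float] | NodePenaltyWeights,
    beta: float,
    penalty_free: Iterable[str] = (),
) -> np.ndarray:
    """Vectorized objective over a matrix of assignments."""
    idx = {v: j for j, v in enumerate(nodes)}
    get_gamma = gamma.__getitem__ if isinstance(gamma, NodePenaltyWeights) else (
        lambda v: gamma.get(v, 0.0)  # type: ignore[union-attr]
    )
    free = set(penalty_free)
    obj = np.zeros(len(states))
    for v, (alpha, m) in measured.items():
        obj += alpha * np.abs(states[:, idx[v]] - m)
    for v in nodes:
        if v in free:
            continue
        g = get_gamma(v)
        col = states[:, idx[v]]
        obj += beta * (1.0 - g) * (col == 1)
        obj += beta * (1.0 + g) * (col == -1)
    return obj


def exhaustive_optimum(
    pkn: SignedNetwork,
    ms: MeasurementSet,
    gamma: NodePenaltyWeights,
    perturb: PerturbationSet,
    beta: float,
    penalty_free: Iterable[str] = (),
) -> tuple[float, list[dict[str, int]]]:
    """Optimal objective and all optimal state assignments, by enumeration."""
    measured = {
        v: (m.alpha, m.m) for v, m in ms.entries.items() if v in pkn.nodes
    }
    nodes, states = enumerate_consistent(pkn, perturb.targets)
    if not len(states):
        raise InputError("no consistent assignment (conflicting fixed roots)")
    obj = assignment_objectives(nodes, states, measured, gamma, beta, penalty_free)
    best = float(obj.min())
    optima = [
        {v: int(row[j]) for j, v in enumerate(nodes)}
        for row in states[np.isclose(obj, best, atol=1e-9)]
    ]
    return best, optima


def exhaustive_inverse_optimum(
    pkn: SignedNetwork,
    ms: MeasurementSet,
    gamma: NodePenaltyWeights,
    beta: float,
) -> tuple[float, list[dict[str, int]]]:
    """Inverse-mode reference: every entry point may independently take any
    root effect in {-1, UNKNOWN-as-off, +1}.

    Mirrors the engine's artificial-root construction: candidate entry points
    are the zero-in-degree nodes (all nodes if none exist); enumeration treats
    each entry point as an unconstrained root (no causal support needed, free
    state) while all other nodes require support, and no node is exempt from
    the node penalty except none (the artificial root itself never appears).
    """
    with_in = {t for _, t, _ in pkn.edges}
    entries = sorted(v for v in pkn.nodes if v not in with_in) or sorted(pkn.nodes)
    roots = {v: UNKNOWN for v in entries}
    measured = {
        v: (m.alpha, m.m) for v, m in ms.entries.items() if v in pkn.nodes
    }
    nodes, states = enumerate_consistent(pkn, roots)
    obj = assignment_objectives(nodes, states, measured, gamma, beta)
    best = float(obj.min())
    optima = [
        {v: int(row[j]) for j, v in enumerate(nodes)}
        for row in states[np.isclose(obj, best, atol=1e-9)]
    ]
    return best, optima
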