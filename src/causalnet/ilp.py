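"""Causal-reasoning integer linear program and solution-pool enumeration.

Given a signed, directed prior knowledge network (PKN), discretized TF
measurements m_j with mismatch weights alpha_j, a node penalty beta and
per-node penalty adjustments gamma_j, the engine selects node states
x_j in {-1, 0, +1} and a supporting set of edges minimizing

    sum_j alpha_j * |x_j - m_j|
  + sum_j beta * (1 - gamma_j) * x_j^+  +  sum_j beta * (1 + gamma_j) * x_j^-

subject to causal consistency: every non-root node with a nonzero state must
receive its state through a sign-consistent incoming edge from an already
explained node, with an acyclic propagation order certified by integer depth
variables.  In Standard mode the roots are the known perturbation targets;
in Inverse mode an artificial root is connected to candidate entry points
with edges of both signs and the chosen edge signs are reported as the
inferred perturbation effects.

Variables (all integer): per node j the state indicators up_j, down_j
(x_j = up_j - down_j) and a depth dist_j in [0, N]; per edge e the carry
indicators carry_plus_e / carry_minus_e marking that e transmits an up- or
down-regulating signal to its target.

Constraints:
  C1  up_j + down_j <= 1
  C2  sign-consistent transmission: an edge can only carry the signal its
      source state and edge sign produce
  C3  causation: a non-root node may only take a state delivered by >= 1
      carrying incoming edge
  C4  acyclicity: dist increases strictly along carrying edges (big-M = N)
  C5  roots: dist = 0; a +1/-1 effect fixes the state; an unknown effect
      leaves the state free but exempts the node from C3
  C6  an edge carries at most one signal
  C7  edge relevance: a carry requires the target to take the matching state

Near-optimal alternatives are enumerated by re-solving with a no-good cut
excluding each incumbent's binary pattern while the objective stays within
``relgap`` of the optimum, then thinned to the most diverse subset by greedy
max-min Hamming distance on the node-state vectors.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from causalnet.core import (
    InputError,
    MeasurementSet,
    NodePenaltyWeights,
    PerturbationSet,
    SignedNetwork,
    SolverConfig,
    UNKNOWN,
)

logger = logging.getLogger("causalnet")

ARTIFICIAL_ROOT = "__perturbation_root__"
_EPS = 1e-9


@dataclass
class IlpProblem:
    """Assembled ILP: variable layout, objective, base constraints, metadata."""

    nodes: list[str]                       # ordered; may include ARTIFICIAL_ROOT
    edges: list[tuple[str, str, int]]      # ordered; may include root edges
    c: np.ndarray                          # objective coefficients
    obj_constant: float                    # sum of alpha_j, added back on report
    a_rows: list[int]
    a_cols: list[int]
    a_vals: list[float]
    row_lb: list[float]
    row_ub: list[float]
    var_lb: np.ndarray
    var_ub: np.ndarray
    roots: dict[str, int]                  # node -> effect (+1/-1/UNKNOWN)
    measured: dict[str, tuple[float, int]] # node -> (alpha, m)
    gamma: dict[str, float]
    beta: float
    mode: str
    artificial_root: str | None = None

    # -- variable layout: [up(n), down(n), cp(E), cm(E), dist(n)] -----------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_binary(self) -> int:
        return 2 * self.n_nodes + 2 * self.n_edges

    @property
    def n_vars(self) -> int:
        return self.n_binary + self.n_nodes

    def up(self, j: int) -> int:
        return j

    def down(self, j: int) -> int:
        return self.n_nodes + j

    def cp(self, e: int) -> int:
        return 2 * self.n_nodes + e

    def cm(self, e: int) -> int:
        return 2 * self.n_nodes + self.n_edges + e

    def dist(self, j: int) -> int:
        return self.n_binary + j


@dataclass(frozen=True)
class SolutionNetwork:
    """One consistent sub-network: node states, used edges, objective."""

    states: dict[str, int]                          # every PKN node, -1/0/+1
    used_edges: tuple[tuple[str, str, int], ...]    # carrying edges
    objective_value: float
    roots: dict[str, int] = field(default_factory=dict)  # justification roots
    inferred_perturbations: dict[str, int] = field(default_factory=dict)

    def nonzero(self) -> dict[str, int]:
        return {v: s for v, s in self.states.items() if s != 0}


@dataclass
class SolutionPool:
    """Near-optimal solutions within relgap of the best objective."""

    solutions: list[SolutionNetwork]
    best_objective: float
    config: SolverConfig
    measured_nodes: frozenset[str] = frozenset()
    input_nodes: frozenset[str] = frozenset()
    optimal: bool = True   # False when the time limit cut enumeration short

    def __len__(self) -> int:
        return len(self.solutions)


@dataclass
class PoolSummary:
    """Aggregate over one or more pools: mean node states, edge usage rates."""

    node_activity: dict[str, float]
    edge_frequency: dict[tuple[str, str, int], float]
    n_solutions: int

    def state_signs(self) -> dict[str, int]:
        """Consensus states: sign of the average activity."""
        return {v: int(np.sign(a)) for v, a in self.node_activity.items()}


def eq2_objective(
    states: Mapping[str, int],
    measured: Mapping[str, tuple[float, int]],
    gamma: Mapping[str, float] | NodePenaltyWeights,
    beta: float,
) -> float:
    """Recompute the objective from node states alone (audit path)."""
    get_gamma = gamma.__getitem__ if isinstance(gamma, NodePenaltyWeights) else (
        lambda v: gamma.get(v, 0.0)  # type: ignore[union-attr]
    )
    total = 0.0
    for v, (alpha, m) in measured.items():
        total += alpha * abs(states.get(v, 0) - m)
    for v, s in states.items():
        if s == 1:
            total += beta * (1.0 - get_gamma(v))
        elif s == -1:
            total += beta * (1.0 + get_gamma(v))
    return total


# ---------------------------------------------------------------------------
# problem construction
# ---------------------------------------------------------------------------

def _assemble(
    nodes: list[str],
    edges: list[tuple[str, str, int]],
    measured: dict[str, tuple[float, int]],
    gamma_map: dict[str, float],
    roots: dict[str, int],
    beta: float,
    mode: str,
    artificial_root: str | None,
) -> IlpProblem:
    n, ne = len(nodes), len(edges)
    idx = {v: j for j, v in enumerate(nodes)}
    prob = IlpProblem(
        nodes=nodes, edges=edges,
        c=np.zeros(2 * n + 2 * ne + n),
        obj_constant=0.0,
        a_rows=[], a_cols=[], a_vals=[], row_lb=[], row_ub=[],
        var_lb=np.zeros(2 * n + 2 * ne + n),
        var_ub=np.ones(2 * n + 2 * ne + n),
        roots=dict(roots), measured=dict(measured), gamma=dict(gamma_map),
        beta=beta, mode=mode, artificial_root=artificial_root,
    )
    big_m = float(n)
    for j in range(n):
        prob.var_ub[prob.dist(j)] = big_m

    # objective: mismatch terms alpha*(1 - m*(up - down)) + node penalties
    for v, (alpha, m) in measured.items():
        j = idx[v]
        prob.obj_constant += alpha
        prob.c[prob.up(j)] += -alpha * m
        prob.c[prob.down(j)] += alpha * m
    for v in nodes:
        if v == artificial_root:
            continue  # the artificial root carries no node penalty
        j = idx[v]
        g = gamma_map.get(v, 0.0)
        prob.c[prob.up(j)] += beta * (1.0 - g)
        prob.c[prob.down(j)] += beta * (1.0 + g)

    def add_row(cols: Sequence[int], vals: Sequence[float], lb: float, ub: float) -> None:
        r = len(prob.row_lb)
        prob.a_rows.extend([r] * len(cols))
        prob.a_cols.extend(cols)
        prob.a_vals.extend(vals)
        prob.row_lb.append(lb)
        prob.row_ub.append(ub)

    # C1: up + down <= 1
    for j in range(n):
        add_row([prob.up(j), prob.down(j)], [1.0, 1.0], -np.inf, 1.0)

    # C2 (source side) and C7 (target side), C6: per edge
    for e, (src, tgt, sign) in enumerate(edges):
        i, j = idx[src], idx[tgt]
        src_up = prob.up(i) if sign == 1 else prob.down(i)
        src_dn = prob.down(i) if sign == 1 else prob.up(i)
        add_row([prob.cp(e), src_up], [1.0, -1.0], -np.inf, 0.0)   # C2+
        add_row([prob.cm(e), src_dn], [1.0, -1.0], -np.inf, 0.0)   # C2-
        add_row([prob.cp(e), prob.up(j)], [1.0, -1.0], -np.inf, 0.0)    # C7+
        add_row([prob.cm(e), prob.down(j)], [1.0, -1.0], -np.inf, 0.0)  # C7-
        add_row([prob.cp(e), prob.cm(e)], [1.0, 1.0], -np.inf, 1.0)     # C6
        # C4: dist_tgt - dist_src - M*(cp + cm) >= 1 - M
        add_row(
            [prob.dist(j), prob.dist(i), prob.cp(e), prob.cm(e)],
            [1.0, -1.0, -big_m, -big_m],
            1.0 - big_m, np.inf,
        )

    # C3: causation for non-root nodes
    incoming: dict[int, list[int]] = {j: [] for j in range(n)}
    for e, (_, tgt, _) in enumerate(edges):
        incoming[idx[tgt]].append(e)
    for v in nodes:
        if v in roots:
            continue
        j = idx[v]
        cps = [prob.cp(e) for e in incoming[j]]
        cms = [prob.cm(e) for e in incoming[j]]
        add_row([prob.up(j), *cps], [1.0] + [-1.0] * len(cps), -np.inf, 0.0)
        add_row([prob.down(j), *cms], [1.0] + [-1.0] * len(cms), -np.inf, 0.0)

    # C5: roots — dist = 0 and state fixing
    for v, eff in roots.items():
        j = idx[v]
        prob.var_ub[prob.dist(j)] = 0.0
        if eff == 1:
            prob.var_lb[prob.up(j)] = 1.0
            prob.var_ub[prob.down(j)] = 0.0
        elif eff == -1:
            prob.var_lb[prob.down(j)] = 1.0
            prob.var_ub[prob.up(j)] = 0.0
        # UNKNOWN: free state, exempt from C3 (handled above)
    return prob


def build_ilp(
    pkn: SignedNetwork,
    ms: MeasurementSet,
    gamma: NodePenaltyWeights,
    perturb: PerturbationSet,
    cfg: SolverConfig,
) -> IlpProblem:
    """Standard mode: known perturbation targets are the causal roots."""
    if not perturb.targets:
        raise InputError(
            "standard mode requires >= 1 perturbation target; "
            "use inverse mode when the targets are unknown"
        )
    ms = ms.restrict_to(pkn.nodes)
    if not ms.entries:
        raise InputError("no measured TF overlaps the network nodes")
    nodes = sorted(pkn.nodes)
    edges = sorted(pkn.edges)
    measured = {v: (m.alpha, m.m) for v, m in ms.entries.items()}
    return _assemble(
        nodes, edges, measured, dict(gamma.gamma), dict(perturb.targets),
        cfg.beta, "standard", None,
    )


def build_inverse(
    pkn: SignedNetwork,
    ms: MeasurementSet,
    gamma: NodePenaltyWeights,
    cfg: SolverConfig,
) -> IlpProblem:
    """Inverse mode: infer the perturbation through an artificial root.

    The root is fixed active at depth 0 and connected by candidate edges of
    both signs to every zero-in-degree node (to all nodes when the network
    has none); the root and its edges carry no node penalty and are stripped
    from reported solutions, the chosen edge signs becoming the inferred
    perturbation effects.
    """
    ms = ms.restrict_to(pkn.nodes)
    nodes = sorted(pkn.nodes)
    edges = sorted(pkn.edges)
    root = ARTIFICIAL_ROOT
    while root in pkn.nodes:
        root += "_"
    with_in = {tgt for _, tgt, _ in edges}
    entry_points = [v for v in nodes if v not in with_in]
    if not entry_points:
        logger.warning(
            "network has no zero-in-degree node; connecting the artificial "
            "root to all nodes"
        )
        entry_points = list(nodes)
    for v in entry_points:
        edges.append((root, v, 1))
        edges.append((root, v, -1))
    nodes = nodes + [root]
    measured = {v: (m.alpha, m.m) for v, m in ms.entries.items()}
    return _assemble(
        nodes, edges, measured, dict(gamma.gamma), {root: 1},
        cfg.beta, "inverse", root,
    )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

def _solve_once(
    prob: IlpProblem,
    cuts: list[tuple[np.ndarray, float]],
    time_limit: float,
) -> tuple[int, np.ndarray | None, float]:
    """One MILP solve (HiGHS) with the current no-good cuts."""
    n_rows = len(prob.row_lb) + len(cuts)
    rows = list(prob.a_rows)
    cols = list(prob.a_cols)
    vals = list(prob.a_vals)
    lb = list(prob.row_lb)
    ub = list(prob.row_ub)
    r = len(prob.row_lb)
    for coef, cut_lb in cuts:
        nz = np.nonzero(coef)[0]
        rows.extend([r] * len(nz))
        cols.extend(nz.tolist())
        vals.extend(coef[nz].tolist())
        lb.append(cut_lb)
        ub.append(np.inf)
        r += 1
    a = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_rows, prob.n_vars)
    )
    res = milp(
        c=prob.c,
        constraints=[LinearConstraint(a, lb, ub)],
        integrality=np.ones(prob.n_vars),
        bounds=Bounds(prob.var_lb, prob.var_ub),
        options={"time_limit": max(time_limit, 1.0), "presolve": True},
    )
    if res.x is None:
        return res.status, None, np.nan
    return res.status, np.round(res.x).astype(int), float(res.fun)


def _extract_solution(prob: IlpProblem, x: np.ndarray) -> SolutionNetwork:
    n = prob.n_nodes
    states: dict[str, int] = {}
    for j, v in enumerate(prob.nodes):
        states[v] = int(x[prob.up(j)] - x[prob.down(j)])
    used: list[tuple[str, str, int]] = []
    inferred: dict[str, int] = {}
    for e, edge in enumerate(prob.edges):
        if x[prob.cp(e)] + x[prob.cm(e)] >= 1:
            if prob.artificial_root is not None and edge[0] == prob.artificial_root:
                inferred[edge[1]] = edge[2]
            else:
                used.append(edge)
    if prob.artificial_root is not None:
        states.pop(prob.artificial_root, None)
        roots = dict(inferred)
    else:
        roots = dict(prob.roots)
    obj = eq2_objective(states, prob.measured, prob.gamma, prob.beta)
    return SolutionNetwork(
        states=states,
        used_edges=tuple(used),
        objective_value=obj,
        roots=roots,
        inferred_perturbations=inferred,
    )


def _no_good_cut(prob: IlpProblem, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Linear cut excluding this exact (up, down, carry) binary pattern."""
    coef = np.zeros(prob.n_vars)
    ones = 0
    for b in range(prob.n_binary):
        if x[b] == 1:
            coef[b] = -1.0
            ones += 1
        else:
            coef[b] = 1.0
    return coef, 1.0 - ones


def _diverse_subset(
    solutions: list[SolutionNetwork], capacity: int, node_order: list[str]
) -> list[SolutionNetwork]:
    """Greedy max-min Hamming selection on node-state vectors; keeps the
    optimum first, ties broken by pool order."""
    if len(solutions) <= capacity:
        return solutions
    mat = np.array(
        [[s.states[v] for v in node_order] for s in solutions], dtype=int
    )
    chosen = [0]
    remaining = list(range(1, len(solutions)))
    # min Hamming distance of each remaining candidate to the chosen set
    min_d = np.array([(mat[i] != mat[0]).sum() for i in remaining])
    while len(chosen) < capacity:
        pick_pos = int(np.argmax(min_d))
        pick = remaining.pop(pick_pos)
        min_d = np.delete(min_d, pick_pos)
        chosen.append(pick)
        if remaining:
            d_new = np.array([(mat[i] != mat[pick]).sum() for i in remaining])
            min_d = np.minimum(min_d, d_new)
    chosen.sort()
    return [solutions[i] for i in chosen]


def solve_pool(prob: IlpProblem, cfg: SolverConfig) -> SolutionPool:
    """Enumerate near-optimal solutions by incumbent-exclusion cuts.

    Solves to optimality, then repeatedly excludes the incumbent's binary
    pattern and re-solves while the objective stays within ``cfg.relgap`` of
    the best, up to ``cfg.pool_populate`` solutions; thins to
    ``cfg.pool_capacity`` by greedy max-min Hamming diversity.  Hitting the
    time limit returns the best-found pool flagged non-optimal.
    """
    t0 = time.monotonic()
    cuts: list[tuple[np.ndarray, float]] = []
    solutions: list[SolutionNetwork] = []
    best = np.nan
    optimal = True
    while len(solutions) < cfg.pool_populate:
        remaining = cfg.time_limit_s - (time.monotonic() - t0)
        if remaining <= 0:
            optimal = False
            logger.warning("time limit reached after %d solution(s)", len(solutions))
            break
        status, x, _ = _solve_once(prob, cuts, remaining)
        if status == 2 and not solutions:
            raise InputError(
                "ILP infeasible: the fixed perturbation effects conflict with "
                "the causation/acyclicity constraints"
            )
        if status == 1:
            optimal = False
            logger.warning("solver hit a limit; pool may be incomplete")
            if x is None:
                break
        elif status != 0 or x is None:
            break
        sol = _extract_solution(prob, x)
        if not solutions:
            best = sol.objective_value
        else:
            threshold = best * (1.0 + cfg.relgap) + _EPS
            if sol.objective_value > threshold:
                break
        solutions.append(sol)
        cuts.append(_no_good_cut(prob, x))
        if status == 1:
            break
    if not solutions:
        raise InputError("solver returned no solution")
    node_order = [v for v in prob.nodes if v != prob.artificial_root]
    solutions = _diverse_subset(solutions, cfg.pool_capacity, node_order)
    if prob.artificial_root is None:
        inputs = frozenset(prob.roots)
    else:
        inputs = frozenset().union(*[frozenset(s.inferred_perturbations) for s in solutions])
    pool = SolutionPool(
        solutions=solutions,
        best_objective=best,
        config=cfg,
        measured_nodes=frozenset(prob.measured),
        input_nodes=inputs,
        optimal=optimal,
    )
    logger.info(
        "pool: %d solution(s), best objective %.6g, optimal=%s",
        len(pool), best, optimal,
    )
    return pool


def aggregate_pool(pools: SolutionPool | Iterable[SolutionPool]) -> PoolSummary:
    """Flat average of node states and edge usage over all solutions.

    Accepts one pool or several (e.g. runs over a grid of node penalties);
    every solution of every pool counts once.
    """
    if isinstance(pools, SolutionPool):
        pools = [pools]
    pools = list(pools)
    sols = [s for p in pools for s in p.solutions]
    if not sols:
        raise InputError("cannot aggregate an empty pool")
    act: dict[str, float] = {}
    for s in sols:
        for v, st in s.states.items():
            act[v] = act.get(v, 0.0) + st
    n = len(sols)
    node_activity = {v: total / n for v, total in act.items()}
    freq: dict[tuple[str, str, int], float] = {}
    for s in sols:
        for e in s.used_edges:
            freq[e] = freq.get(e, 0.0) + 1.0
    edge_frequency = {e: c / n for e, c in freq.items()}
    return PoolSummary(
        node_activity=node_activity, edge_frequency=edge_frequency, n_solutions=n
    )


# ---------------------------------------------------------------------------
# auditing
# ---------------------------------------------------------------------------

def audit_solution(
    pkn: SignedNetwork,
    sol: SolutionNetwork,
    atol: float = 1e-6,
    measured: Mapping[str, tuple[float, int]] | None = None,
    gamma: NodePenaltyWeights | Mapping[str, float] | None = None,
    beta: float | None = None,
) -> None:
    """Verify causal consistency of a solution; raises AssertionError if not.

    Checks that (1) used edges are PKN edges, (2) every nonzero-state
    non-root node is reachable through a chain of used, sign-consistent
    edges starting at the roots (which certifies an acyclic justification),
    and optionally (3) the objective recomputed from the states matches the
    reported one within ``atol``.
    """
    pkn_edges = set(pkn.edges)
    for e in sol.used_edges:
        assert e in pkn_edges, f"used edge {e} not in the network"
    for v, eff in sol.roots.items():
        if eff in (1, -1) and v in sol.states:
            assert sol.states[v] == eff, f"root {v} state {sol.states[v]} != effect {eff}"
    placed = set(sol.roots)
    nonzero = {v for v, s in sol.states.items() if s != 0}
    changed = True
    while changed:
        changed = False
        for src, tgt, sign in sol.used_edges:
            if tgt in placed or tgt not in nonzero:
                continue
            if src in placed and sol.states.get(src, 0) * sign == sol.states[tgt]:
                placed.add(tgt)
                changed = True
    unexplained = nonzero - placed
    assert not unexplained, f"states without acyclic causal support: {sorted(unexplained)}"
    if measured is not None and beta is not None:
        g = gamma if gamma is not None else {}
        recomputed = eq2_objective(sol.states, measured, g, beta)
        assert abs(recomputed - sol.objective_value) <= atol, (
            f"objective audit failed: {recomputed} vs {sol.objective_value}"
        )
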