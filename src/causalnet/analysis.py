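"""Topology statistics, degree/sign-preserving randomization, robustness.

Inferred networks are profiled with the classical directed-graph centrality
measures (degree, betweenness, HITS hub/authority scores) and compared
against degree- and sign-preserving edge-switch randomizations.  Robustness
of a full inference run is quantified by the Jaccard similarity of nonzero
node states between a reference solution and re-runs on down-sampled or
label-reshuffled measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import networkx as nx
import numpy as np
from scipy import stats as sps

from causalnet.core import InputError, MeasurementSet, SignedNetwork

logger = logging.getLogger("causalnet")


@dataclass
class TopologyReport:
    """Per-node centrality measures of a directed network."""

    in_degree: dict[str, int]
    out_degree: dict[str, int]
    all_degree: dict[str, int]
    betweenness: dict[str, float]
    hub_score: dict[str, float]
    authority_score: dict[str, float]
    node_weights: dict[str, float] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for v in sorted(self.all_degree):
            rows.append({
                "symbol": v,
                "in_degree": self.in_degree[v],
                "out_degree": self.out_degree[v],
                "all_degree": self.all_degree[v],
                "betweenness": self.betweenness[v],
                "hub_score": self.hub_score[v],
                "authority_score": self.authority_score[v],
                "weight": self.node_weights.get(v, 1.0),
            })
        return rows


def _to_multidigraph(net: SignedNetwork) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    g.add_nodes_from(net.nodes)
    for src, tgt, sign in net.edges:
        g.add_edge(src, tgt, sign=sign)
    return g


def topology_metrics(
    net: SignedNetwork,
    node_weights: Mapping[str, float] | None = None,
) -> TopologyReport:
    """Degree, betweenness and HITS hub/authority scores.

    When ``node_weights`` are supplied (e.g. pool-average node activities),
    nodes with weight exactly 0 are excluded before computation and the
    weight magnitudes annotate the report; the measures themselves are
    unweighted.  Hub/authority scores are normalized to a maximum of 1.
    """
    if not net.nodes:
        raise InputError("empty network")
    if node_weights is not None:
        keep = {v for v in net.nodes if node_weights.get(v, 0.0) != 0.0}
        net = SignedNetwork.from_edges(
            [e for e in net.edges if e[0] in keep and e[1] in keep],
            extra_nodes=keep,
        )
    g = _to_multidigraph(net)
    in_deg = {v: d for v, d in g.in_degree()}
    out_deg = {v: d for v, d in g.out_degree()}
    all_deg = {v: in_deg[v] + out_deg[v] for v in g}
    if g.number_of_edges() == 0:
        zeros = {v: 0.0 for v in g}
        return TopologyReport(
            in_degree=in_deg, out_degree=out_deg, all_degree=all_deg,
            betweenness=dict(zeros), hub_score=dict(zeros),
            authority_score=dict(zeros),
            node_weights={v: abs(node_weights[v]) for v in g if v in (node_weights or {})}
            if node_weights else {},
        )
    simple = nx.DiGraph(g)  # betweenness over distinct directed arcs
    btw = nx.betweenness_centrality(simple, normalized=False)
    hubs, auths = nx.hits(simple, max_iter=1000, tol=1e-8)
    for scores in (hubs, auths):
        peak = max(scores.values())
        if peak > 0:
            for v in scores:
                scores[v] /= peak
    weights = (
        {v: abs(node_weights[v]) for v in g if v in node_weights}
        if node_weights is not None else {}
    )
    return TopologyReport(
        in_degree=in_deg, out_degree=out_deg, all_degree=all_deg,
        betweenness=btw, hub_score=hubs, authority_score=auths,
        node_weights=weights,
    )


def rewire_preserving(
    net: SignedNetwork,
    n_networks: int = 100,
    n_swaps_per_edge: int = 10,
    seed: int = 0,
) -> list[SignedNetwork]:
    """Degree- and sign-preserving edge-switch randomization.

    Edge switches operate independently within the activating and the
    inhibitory edge class: two same-sign edges (a->b) and (c->d) become
    (a->d) and (c->b) when neither new edge duplicates an existing triple
    nor forms a self-loop, which preserves every node's per-sign in- and
    out-degree exactly.  A sign class with fewer than 2 edges is left
    untouched with a warning.
    """
    rng = np.random.default_rng(seed)
    by_sign: dict[int, list[tuple[str, str]]] = {1: [], -1: []}
    for src, tgt, sign in net.edges:
        by_sign[sign].append((src, tgt))
    for sign, pairs in by_sign.items():
        if 0 < len(pairs) < 2:
            logger.warning("sign class %+d has < 2 edges; skipped in rewiring", sign)

    out: list[SignedNetwork] = []
    for _ in range(n_networks):
        classes = {s: list(p) for s, p in by_sign.items()}
        present = {(a, b, s) for s, pairs in classes.items() for a, b in pairs}
        for sign, pairs in classes.items():
            if len(pairs) < 2:
                continue
            n_swaps = n_swaps_per_edge * len(pairs)
            for _ in range(n_swaps):
                i, j = rng.integers(0, len(pairs), size=2)
                if i == j:
                    continue
                a, b = pairs[i]
                c, d = pairs[j]
                if a == d or c == b:
                    continue
                new1, new2 = (a, d, sign), (c, b, sign)
                if new1 in present or new2 in present:
                    continue
                present.discard((a, b, sign))
                present.discard((c, d, sign))
                present.add(new1)
                present.add(new2)
                pairs[i] = (a, d)
                pairs[j] = (c, b)
        edges = [(a, b, s) for s, pairs in classes.items() for a, b in pairs]
        out.append(SignedNetwork.from_edges(edges, extra_nodes=net.nodes))
    return out


def jaccard_states(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    """Jaccard index of the (symbol, nonzero state) pair sets; 1.0 if both empty."""
    sa = {(v, s) for v, s in a.items() if s != 0}
    sb = {(v, s) for v, s in b.items() if s != 0}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclass
class RobustnessReport:
    downsample_jaccards: list[float]
    reshuffle_jaccards: list[float]
    downsample_mean: float
    downsample_sd: float
    reshuffle_mean: float
    reshuffle_sd: float
    t_statistic: float
    p_value: float


def robustness_suite(
    run: Callable[[MeasurementSet], Mapping[str, int]],
    ms: MeasurementSet,
    fraction: float = 0.7,
    n_reps: int = 20,
    seed: int = 0,
) -> RobustnessReport:
    """Down-sampling vs. label-reshuffling robustness of an inference run.

    ``run`` maps a MeasurementSet to consensus node states (e.g. a closure
    over build_ilp -> solve_pool -> aggregate).  The reference is the run on
    the full measurements.  Scheme (a) keeps a random ``fraction`` of the
    measured TFs per repetition; scheme (b) permutes the score-to-label
    assignment.  Per-rep Jaccard similarities against the reference are
    summarized as mean +/- SD per scheme with an unpaired two-sided
    unequal-variance t-test between the two distributions.
    """
    if n_reps < 2:
        raise InputError("n_reps must be >= 2 to report an SD")
    if not 0.0 < fraction <= 1.0:
        raise InputError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    reference = dict(run(ms))
    symbols = sorted(ms.entries)
    k = max(1, int(round(fraction * len(symbols))))

    down: list[float] = []
    shuf: list[float] = []
    for _ in range(n_reps):
        keep = rng.choice(symbols, size=k, replace=False)
        sub = MeasurementSet(entries={s: ms.entries[s] for s in keep})
        down.append(jaccard_states(reference, run(sub)))
    for _ in range(n_reps):
        perm = rng.permutation(len(symbols))
        scores = [ms.entries[symbols[p]].score for p in perm]
        shuffled = MeasurementSet.from_scores(dict(zip(symbols, scores)))
        shuf.append(jaccard_states(reference, run(shuffled)))

    t, p = sps.ttest_ind(down, shuf, equal_var=False)
    return RobustnessReport(
        downsample_jaccards=down,
        reshuffle_jaccards=shuf,
        downsample_mean=float(np.mean(down)),
        downsample_sd=float(np.std(down, ddof=1)),
        reshuffle_mean=float(np.mean(shuf)),
        reshuffle_sd=float(np.std(shuf, ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
    )
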