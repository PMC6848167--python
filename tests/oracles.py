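"""Independent reference implementations shared by the test modules.

These deliberately re-derive results through a different route than the
package (explicit python loops, closed forms, exhaustive enumeration) so
that agreement is evidence, not tautology.
"""

import math

import numpy as np

from causalnet import (
    MeasurementSet,
    NodePenaltyWeights,
    PerturbationSet,
    SignedNetwork,
)
from causalnet.core import UNKNOWN


def brute_force_pathway_scores(signature, model, n_perm, seed):
    """Explicit permutation loop for the pathway significance score.

    Follows the documented seed protocol (sorted gene order, one shared
    permutation stream) but scores each pathway with plain python sums.
    """
    genes = sorted(signature.stats)
    values = np.array([signature.stats[g] for g in genes])
    pos = {g: i for i, g in enumerate(genes)}
    names = [n for n, fp in model.pathways.items() if any(g in pos for g in fp)]
    obs = {
        n: sum(w * values[pos[g]] for g, w in model.pathways[n].items() if g in pos)
        for n in names
    }
    rng = np.random.default_rng(seed)
    below = {n: 0.0 for n in names}
    ties = {n: 0.0 for n in names}
    for _ in range(n_perm):
        shuffled = values[rng.permutation(len(values))]
        for n in names:
            null = sum(
                w * shuffled[pos[g]]
                for g, w in model.pathways[n].items() if g in pos
            )
            if null < obs[n]:
                below[n] += 1
            elif null == obs[n]:
                ties[n] += 1
    return {n: 2.0 * ((below[n] + 0.5 * ties[n]) / n_perm - 0.5) for n in names}


def random_ilp_instance(rng, n=None, ne=None, max_nodes=10, max_edges=14):
    """Random signed network with random measurements, roots and gamma."""
    n = n or int(rng.integers(4, max_nodes + 1))
    ne = ne or int(rng.integers(3, max_edges + 1))
    nodes = [f"V{i}" for i in range(n)]
    edges = set()
    for _ in range(3 * ne):
        if len(edges) >= ne:
            break
        i, j = rng.integers(0, n, 2)
        if i != j:
            edges.add((nodes[i], nodes[j], int(rng.choice([-1, 1]))))
    pkn = SignedNetwork.from_edges(edges, extra_nodes=nodes)
    meas = rng.choice(nodes, int(rng.integers(1, 4)), replace=False)
    ms = MeasurementSet.from_scores({v: float(rng.normal()) or 0.5 for v in meas})
    roots = rng.choice(nodes, int(rng.integers(1, 3)), replace=False)
    perturb = PerturbationSet.build(
        {v: int(rng.choice([-1, 1, UNKNOWN])) for v in roots}, pkn
    )
    gamma = NodePenaltyWeights(
        gamma={v: float(rng.uniform(-1, 1))
               for v in rng.choice(nodes, 2, replace=False)}
    )
    return pkn, ms, perturb, gamma


def hypergeom_upper_tail(overlap, universe, set_size, draw):
    """Exact combinatorial upper-tail P[X >= overlap]."""
    total = 0.0
    for k in range(overlap, min(set_size, draw) + 1):
        total += (
            math.comb(set_size, k)
            * math.comb(universe - set_size, draw - k)
            / math.comb(universe, draw)
        )
    return total
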