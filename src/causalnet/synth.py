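"""Synthetic scenarios: signed networks, planted causal signals, noisy readouts.

The generator emulates the statistical structure the inference pipeline
assumes: a signed, directed prior knowledge network; a perturbation entering
at one or more root nodes and propagating sign-consistently to a set of
downstream transcription factors; and a gene-level differential-expression
signature in which each TF's regulon targets shift according to the TF's
planted activity, on top of Gaussian noise.  Synthetic gene universes are
kept disjoint from the network node symbols, mirroring the TF -> target
layering of real data.  All randomness flows from one scenario seed through
named per-operation sub-seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from causalnet.core import (
    InputError,
    MeasurementSet,
    PerturbationSet,
    SignedNetwork,
    write_sif,
)
from causalnet.scoring import ExpressionSignature, Regulon

logger = logging.getLogger("causalnet")

_MAX_RETRIES = 100


@dataclass
class SyntheticScenario:
    """A complete ground-truth instance for end-to-end testing."""

    pkn: SignedNetwork
    true_states: dict[str, int]
    true_edges: tuple[tuple[str, str, int], ...]
    perturbation: PerturbationSet
    regulons: list[Regulon]
    signature: ExpressionSignature
    exact_measurements: MeasurementSet
    measured_tfs: list[str]
    seed: int


def _subseed(seed: int, label: str) -> np.random.Generator:
    """Named, reproducible sub-stream of the scenario seed."""
    import zlib

    key = zlib.crc32(label.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def generate_pkn(
    n_nodes: int,
    avg_out_degree: float = 2.6,
    frac_inhibitory: float = 0.3,
    allow_cycles: bool = True,
    seed: int = 0,
) -> SignedNetwork:
    """Random signed, directed, weakly connected network.

    Each ordered node pair receives an edge with probability
    ``avg_out_degree / (n_nodes - 1)`` (restricted to i < j pairs when
    ``allow_cycles`` is false), signed inhibitory with probability
    ``frac_inhibitory``.  Sampling repeats until the graph is weakly
    connected, up to a bounded number of retries.  The default mean
    out-degree matches the edge density of curated human signaling networks
    (roughly 2.6 directed edges per node).
    """
    if n_nodes < 3:
        raise InputError("n_nodes must be >= 3")
    rng = np.random.default_rng(seed)
    names = [f"N{i:04d}" for i in range(n_nodes)]
    p = min(1.0, avg_out_degree / (n_nodes - 1))
    for _ in range(_MAX_RETRIES):
        mask = rng.random((n_nodes, n_nodes)) < p
        np.fill_diagonal(mask, False)
        if not allow_cycles:
            mask = np.triu(mask)
        signs = np.where(rng.random((n_nodes, n_nodes)) < frac_inhibitory, -1, 1)
        edges = [
            (names[i], names[j], int(signs[i, j]))
            for i, j in zip(*np.nonzero(mask))
        ]
        if not edges:
            continue
        net = SignedNetwork.from_edges(edges, extra_nodes=names)
        if _weakly_connected(net):
            return net
    raise InputError(
        "could not sample a weakly connected network; "
        "increase avg_out_degree or n_nodes"
    )


def _weakly_connected(net: SignedNetwork) -> bool:
    nodes = list(net.nodes)
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for s, t, _ in net.edges:
        adj[s].add(t)
        adj[t].add(s)
    seen = {nodes[0]}
    stack = [nodes[0]]
    while stack:
        v = stack.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == len(net.nodes)


def plant_signal(
    pkn: SignedNetwork,
    n_roots: int = 1,
    depth: int = 3,
    p_follow: float = 0.7,
    root_effect: int | None = None,
    seed: int = 0,
) -> tuple[dict[str, int], tuple[tuple[str, str, int], ...], PerturbationSet]:
    """Plant a sign-consistent causal cascade of the given depth.

    Roots are drawn preferentially from zero-in-degree nodes with outgoing
    edges (perturbations enter signaling networks at source nodes such as
    ligand receptors), assigned a random +/-1 state (or the fixed
    ``root_effect``, e.g. +1 to emulate an activatory-perturbation benchmark
    panel), and propagated along
    randomly chosen outgoing edges (child state = parent state * edge sign),
    each available edge followed with probability ``p_follow`` (at least one
    per frontier node while unvisited targets remain), never revisiting a
    node.  Returns the consistent state map, the used edges, and the root
    effects; the planted assignment always satisfies the engine's causal
    consistency invariants by construction.
    """
    if depth < 1:
        raise InputError("depth must be >= 1")
    rng = _subseed(seed, "plant")
    out_edges = pkn.out_edges()
    with_in = {t for _, t, _ in pkn.edges}
    sources = sorted(v for v in pkn.nodes if v not in with_in and out_edges[v])
    fallback = sorted(v for v in pkn.nodes if out_edges[v])
    candidates = sources if len(sources) >= n_roots else fallback
    if len(candidates) < n_roots:
        raise InputError("not enough nodes with outgoing edges for the requested roots")
    roots = [candidates[i] for i in rng.choice(len(candidates), size=n_roots, replace=False)]

    if root_effect not in (None, 1, -1):
        raise InputError("root_effect must be +1, -1 or None (random)")
    states: dict[str, int] = {}
    used: list[tuple[str, str, int]] = []
    for r in roots:
        states[r] = int(rng.choice([-1, 1])) if root_effect is None else root_effect
    frontier = list(roots)
    for _ in range(depth):
        next_frontier: list[str] = []
        for v in frontier:
            available = [e for e in out_edges[v] if e[1] not in states]
            if not available:
                continue
            order = rng.permutation(len(available))
            took_any = False
            for k in order:
                src, tgt, sign = available[k]
                if tgt in states:  # may have been claimed this round
                    continue
                if took_any and rng.random() > p_follow:
                    continue
                states[tgt] = states[v] * sign
                used.append((src, tgt, sign))
                next_frontier.append(tgt)
                took_any = True
        frontier = next_frontier
        if not frontier:
            break
    perturb = PerturbationSet.build({r: states[r] for r in roots}, pkn)
    full_states = {v: states.get(v, 0) for v in pkn.nodes}
    return full_states, tuple(used), perturb


def emit_measurements(
    true_states: dict[str, int],
    true_edges: tuple[tuple[str, str, int], ...],
    n_tfs: int = 8,
    regulon_size: int = 15,
    noise_sd: float = 0.5,
    effect_size: float = 3.0,
    n_background_genes: int = 200,
    n_decoy_tfs: int = 0,
    seed: int = 0,
) -> tuple[list[Regulon], ExpressionSignature, MeasurementSet, list[str]]:
    """Noisy downstream readout of the planted signal.

    Measured TFs are drawn from the leaves of the planted cascade (nonzero
    nodes with no outgoing planted edge), falling back to any nonzero node;
    optional decoy TFs with true state 0 are added.  Each TF receives a
    regulon of fresh synthetic gene symbols with random +/-1 modes, and each
    target gene's differential-expression statistic is
    ``tf_state * mode * effect_size + N(0, noise_sd)``; background genes are
    pure noise.  Also returns the exact measurement set
    (score = state * effect_size) for tests that bypass the scoring layer.
    """
    rng = _subseed(seed, "emit")
    nonzero = sorted(v for v, s in true_states.items() if s != 0)
    has_out = {e[0] for e in true_edges}
    leaves = [v for v in nonzero if v not in has_out]
    pool = leaves if len(leaves) >= n_tfs else nonzero
    if len(pool) < n_tfs:
        raise InputError(
            f"requested {n_tfs} measured TFs but only {len(pool)} nonzero nodes"
        )
    tfs = sorted(pool[i] for i in rng.choice(len(pool), size=n_tfs, replace=False))
    zeros = sorted(v for v, s in true_states.items() if s == 0)
    if n_decoy_tfs:
        if len(zeros) < n_decoy_tfs:
            raise InputError("not enough zero-state nodes for the requested decoys")
        decoys = sorted(zeros[i] for i in rng.choice(len(zeros), size=n_decoy_tfs, replace=False))
    else:
        decoys = []

    gene_counter = 0
    regulons: list[Regulon] = []
    stats: dict[str, float] = {}
    for tf in tfs + decoys:
        targets: dict[str, int] = {}
        state = true_states[tf]
        for _ in range(regulon_size):
            gene = f"G{gene_counter:05d}"
            gene_counter += 1
            mode = int(rng.choice([-1, 1]))
            targets[gene] = mode
            stats[gene] = state * mode * effect_size + rng.normal(0.0, noise_sd)
        regulons.append(Regulon(tf=tf, targets=targets))
    for _ in range(n_background_genes):
        gene = f"G{gene_counter:05d}"
        gene_counter += 1
        stats[gene] = rng.normal(0.0, max(noise_sd, 1e-12))
    signature = ExpressionSignature(stats=stats)
    exact = MeasurementSet.from_scores(
        {tf: true_states[tf] * effect_size for tf in tfs}
    )
    return regulons, signature, exact, tfs


def make_scenario(
    n_nodes: int = 60,
    avg_out_degree: float = 2.6,
    frac_inhibitory: float = 0.3,
    n_roots: int = 1,
    depth: int = 3,
    n_tfs: int = 8,
    n_decoy_tfs: int = 8,
    regulon_size: int = 15,
    noise_sd: float = 0.5,
    effect_size: float = 3.0,
    root_effect: int | None = None,
    seed: int = 0,
) -> SyntheticScenario:
    """Wire the three generators into one reproducible scenario.

    Retries the network/plant draw (with derived sub-seeds) until the cascade
    yields enough nonzero nodes for the requested number of measured TFs.
    The default panel pairs the signal TFs with an equal number of decoy TFs
    (true state 0, regulon targets pure noise): real TF-activity panels score
    many transcription factors the perturbation never touches, and the decoys
    are what gives a label-reshuffling null its bite.
    """
    last_err: Exception | None = None
    for attempt in range(_MAX_RETRIES):
        inner = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(attempt,)
        ).generate_state(1)[0] % (2**31))
        try:
            pkn = generate_pkn(
                n_nodes, avg_out_degree, frac_inhibitory, seed=inner
            )
            states, used, perturb = plant_signal(
                pkn, n_roots=n_roots, depth=depth, root_effect=root_effect,
                seed=inner,
            )
            regs, sig, exact, tfs = emit_measurements(
                states, used, n_tfs=n_tfs, regulon_size=regulon_size,
                noise_sd=noise_sd, effect_size=effect_size,
                n_decoy_tfs=n_decoy_tfs, seed=inner,
            )
        except InputError as err:
            last_err = err
            continue
        return SyntheticScenario(
            pkn=pkn, true_states=states, true_edges=used, perturbation=perturb,
            regulons=regs, signature=sig, exact_measurements=exact,
            measured_tfs=tfs, seed=seed,
        )
    raise InputError(f"could not build a scenario: {last_err}")


def write_scenario(scn: SyntheticScenario, out_dir) -> None:
    """Write a scenario directory consumable by the `run` / `validate` CLI."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    write_sif(scn.pkn, os.path.join(out_dir, "pkn.sif"))
    with open(os.path.join(out_dir, "signature.tsv"), "w") as fh:
        for g in sorted(scn.signature.stats):
            fh.write(f"{g}\t{scn.signature.stats[g]:.6g}\n")
    with open(os.path.join(out_dir, "regulons.tsv"), "w") as fh:
        for reg in scn.regulons:
            for g, mode in sorted(reg.targets.items()):
                fh.write(f"{reg.tf}\t{g}\t{mode}\n")
    with open(os.path.join(out_dir, "measurements.tsv"), "w") as fh:
        for tf, m in sorted(scn.exact_measurements.entries.items()):
            fh.write(f"{tf}\t{m.score:.6g}\n")
    with open(os.path.join(out_dir, "targets.tsv"), "w") as fh:
        for v, eff in sorted(scn.perturbation.targets.items()):
            fh.write(f"{v}\t{eff}\n")
    with open(os.path.join(out_dir, "true_states.tsv"), "w") as fh:
        for v in sorted(scn.true_states):
            fh.write(f"{v}\t{scn.true_states[v]}\n")
    with open(os.path.join(out_dir, "true_edges.sif"), "w") as fh:
        for src, tgt, sign in sorted(scn.true_edges):
            fh.write(f"{src}\t{sign}\t{tgt}\n")
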