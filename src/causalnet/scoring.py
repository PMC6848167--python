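"""Footprint scoring: pathway significance scores and TF activity NES.

Pathway activity is scored from the expression footprint the pathway leaves
on its downstream genes: the observed weighted sum of differential-expression
statistics over the footprint genes is located within an empirical null built
by gene-wise permutation of the signature, and the percentile is mapped to a
signed significance score in [-1, 1],

    score(x) = 2 * (percentile(x) - 0.5).

TF activity is summarized as a normalized enrichment score (NES) over the
ranks of the TF's regulon targets in the signature: genes are rank-transformed
to fractional ranks, mapped through the standard-normal quantile function, and
combined Stouffer-style with the regulon's interaction modes.  Only the
magnitude and sign of the NES feed the downstream ILP (as the mismatch weight
alpha and the discretized measurement m), so a rank-based NES is sufficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from causalnet.core import InputError, MeasurementSet, NodePenaltyWeights

logger = logging.getLogger("causalnet")

MIN_REGULON_SIZE = 10  # minimum TF-target interactions for a usable regulon


@dataclass
class ExpressionSignature:
    """Per-gene differential-expression statistics (t-values or logFC)."""

    stats: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.stats) < 2:
            raise InputError("a signature needs at least 2 genes")
        arr = np.asarray(list(self.stats.values()), dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InputError("signature contains non-finite values")

    def __len__(self) -> int:
        return len(self.stats)


@dataclass
class PathwayModel:
    """Pathway footprint gene weights plus representative network nodes.

    ``pathways`` maps pathway name -> {footprint gene -> coefficient};
    ``representative_nodes`` maps pathway name -> the (pairwise disjoint)
    set of network nodes through which the pathway's activity score enters
    the node-penalty adjustment.
    """

    pathways: dict[str, dict[str, float]]
    representative_nodes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise InputError(f"pathway {name!r} has no footprint genes")
        seen: dict[str, str] = {}
        for name, nodes in self.representative_nodes.items():
            if not nodes:
                raise InputError(f"pathway {name!r} has no representative nodes")
            for v in nodes:
                if v in seen:
                    raise InputError(
                        f"representative node {v!r} shared by {seen[v]!r} and {name!r}"
                    )
                seen[v] = name

    @classmethod
    def from_gene_sets(
        cls,
        sets: Mapping[str, Sequence[str] | frozenset[str]],
        representative_nodes: Mapping[str, frozenset[str]] | None = None,
    ) -> "PathwayModel":
        """Build an unweighted model (all footprint weights 1) from gene lists."""
        pathways = {name: {g: 1.0 for g in genes} for name, genes in sets.items()}
        reps = {k: frozenset(v) for k, v in (representative_nodes or {}).items()}
        return cls(pathways=pathways, representative_nodes=reps)


@dataclass(frozen=True)
class Regulon:
    """A TF with its signed transcriptional targets (mode +1 / -1)."""

    tf: str
    targets: Mapping[str, int]

    def __post_init__(self) -> None:
        for g, mode in self.targets.items():
            if mode not in (1, -1):
                raise InputError(f"regulon {self.tf}: mode of {g!r} must be +1/-1")


@dataclass
class PathwayScore:
    """Signed pathway significance scores in [-1, 1]."""

    scores: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.scores.items():
            if not -1.0 <= s <= 1.0:
                raise InputError(f"pathway score {name!r} = {s} outside [-1, 1]")


def pathway_score(
    signature: ExpressionSignature,
    model: PathwayModel,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PathwayScore:
    """Score each pathway against a gene-wise permutation null.

    The observed statistic is ``sum_g weight_g * stat_g`` over the pathway's
    footprint genes present in the signature.  The null re-computes the same
    statistic after permuting which gene carries which signature value; one
    permutation stream is shared by all pathways per iteration.  The score is
    ``2 * (percentile - 0.5)`` where the percentile counts null values
    strictly below the observed one plus half of the ties, so an observed
    value at the null median scores 0 and the score is bounded by +/-1.

    Pathways with no footprint gene in the signature are absent from the
    output (logged).  Seed protocol: genes are taken in sorted symbol order
    and ``numpy.random.default_rng(seed).permutation`` drives every iteration.
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    genes = sorted(signature.stats)
    values = np.asarray([signature.stats[g] for g in genes], dtype=float)
    gene_index = {g: i for i, g in enumerate(genes)}

    usable: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, fp in model.pathways.items():
        idx = [gene_index[g] for g in fp if g in gene_index]
        if not idx:
            logger.warning("pathway %s has no footprint gene in the signature", name)
            continue
        w = np.asarray([fp[g] for g in fp if g in gene_index], dtype=float)
        usable[name] = (np.asarray(idx, dtype=int), w)

    rng = np.random.default_rng(seed)
    names = list(usable)
    observed = np.asarray(
        [float(values[idx] @ w) for idx, w in usable.values()], dtype=float
    )
    below = np.zeros(len(names))
    ties = np.zeros(len(names))
    for _ in range(n_perm):
        perm = rng.permutation(len(values))
        permuted = values[perm]
        for k, (idx, w) in enumerate(usable.values()):
            null = float(permuted[idx] @ w)
            if null < observed[k]:
                below[k] += 1.0
            elif null == observed[k]:
                ties[k] += 1.0
    percentile = (below + 0.5 * ties) / n_perm
    scores = {name: float(2.0 * (percentile[k] - 0.5)) for k, name in enumerate(names)}
    return PathwayScore(scores=scores)


def tf_nes(
    signature: ExpressionSignature, regulons: Sequence[Regulon]
) -> MeasurementSet:
    """Rank-based TF activity NES from regulon target positions.

    Signature statistics are converted to fractional ranks r in (0, 1)
    (mid-rank for ties), mapped to standard-normal quantiles q = Phi^{-1}(r),
    and combined as ``NES(tf) = sum_t mode_t * q_t / sqrt(n_targets)`` over
    the regulon targets present in the signature.  TFs with fewer than
    MIN_REGULON_SIZE overlapping targets are skipped with a warning.  The
    result is rank-based, hence invariant under any strictly monotone
    transform of the signature.
    """
    genes = sorted(signature.stats)
    values = np.asarray([signature.stats[g] for g in genes], dtype=float)
    n = len(values)
    frac_ranks = sps.rankdata(values, method="average") / (n + 1)
    quantiles = sps.norm.ppf(frac_ranks)
    q_of = dict(zip(genes, quantiles))

    scores: dict[str, float] = {}
    for reg in regulons:
        present = [(g, mode) for g, mode in reg.targets.items() if g in q_of]
        if len(present) < MIN_REGULON_SIZE:
            logger.warning(
                "regulon %s has %d overlapping target(s) (< %d), skipped",
                reg.tf, len(present), MIN_REGULON_SIZE,
            )
            continue
        total = sum(mode * q_of[g] for g, mode in present)
        scores[reg.tf] = float(total / np.sqrt(len(present)))
    return MeasurementSet.from_scores(scores)


def select_top_tfs(ms: MeasurementSet, k: int = 50) -> MeasurementSet:
    """Keep the k measurements with largest |score|, lexicographic tie-break."""
    if k < 1:
        raise InputError("k must be >= 1")
    ranked = sorted(ms.entries.items(), key=lambda kv: (-kv[1].alpha, kv[0]))
    return MeasurementSet(entries=dict(ranked[:k]))


def gamma_from_pathway_scores(
    ps: PathwayScore, model: PathwayModel, pkn_nodes: frozenset[str] | None = None
) -> NodePenaltyWeights:
    """Spread each pathway's score onto its representative network nodes.

    Every representative node of a scored pathway receives that pathway's
    score as its gamma weight; all other nodes default to 0.  A representative
    node absent from the network is recorded anyway (harmless) with a warning.
    """
    gamma: dict[str, float] = {}
    for name, score in ps.scores.items():
        for v in model.representative_nodes.get(name, ()):  # unmapped pathway: no-op
            if pkn_nodes is not None and v not in pkn_nodes:
                logger.warning("representative node %s (pathway %s) not in network", v, name)
            gamma[v] = float(score)
    return NodePenaltyWeights(gamma=gamma)


# ---------------------------------------------------------------------------
# file formats for the scoring layer
# ---------------------------------------------------------------------------

def read_signature(path) -> ExpressionSignature:
    """Read a 2-column TSV of gene, statistic."""
    stats: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(f"{path}: line {lineno}: expected 2 fields")
            sym, raw = parts[0].strip(), parts[1].strip()
            if sym in stats:
                raise InputError(f"{path}: line {lineno}: duplicate gene {sym!r}")
            try:
                stats[sym] = float(raw)
            except ValueError:
                raise InputError(f"{path}: line {lineno}: non-numeric value {raw!r}") from None
    return ExpressionSignature(stats=stats)


def read_regulons(path) -> list[Regulon]:
    """Read regulons from a 3-column TSV: tf, target, mode (+1/-1)."""
    raw: dict[str, dict[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(f"{path}: line {lineno}: expected 3 fields")
            tf, target, mode = (p.strip() for p in parts)
            if mode not in ("1", "+1", "-1"):
                raise InputError(f"{path}: line {lineno}: mode must be +1/-1")
            raw.setdefault(tf, {})[target] = 1 if mode in ("1", "+1") else -1
    return [Regulon(tf=tf, targets=targets) for tf, targets in raw.items()]


def read_pathway_model(genes_path, reps_path=None) -> PathwayModel:
    """Read footprint weights (pathway, gene, weight) and optional
    representative nodes (pathway, node)."""
    pathways: dict[str, dict[str, float]] = {}
    with open(genes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise InputError(f"{genes_path}: line {lineno}: expected 2-3 fields")
            name, gene = parts[0].strip(), parts[1].strip()
            weight = float(parts[2]) if len(parts) == 3 else 1.0
            pathways.setdefault(name, {})[gene] = weight
    reps: dict[str, frozenset[str]] = {}
    if reps_path is not None:
        tmp: dict[str, set[str]] = {}
        with open(reps_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise InputError(f"{reps_path}: line {lineno}: expected 2 fields")
                tmp.setdefault(parts[0].strip(), set()).add(parts[1].strip())
        reps = {k: frozenset(v) for k, v in tmp.items()}
    return PathwayModel(pathways=pathways, representative_nodes=reps)
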