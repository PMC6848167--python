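"""Domain types and file formats.

Everything the tool reads or writes passes through here: the signed, directed
prior knowledge network (SIF), TF activity measurements (TSV), gene-set
collections (GMT), solver configuration (YAML), and the solution tables
written after a run.  Symbols are case-sensitive opaque strings; no identifier
mapping is attempted.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger("causalnet")

#: tokens accepted in the relation column of a SIF file
_SIGN_TOKENS = {
    "1": 1, "+1": 1, "activate": 1, "activation": 1,
    "-1": -1, "−1": -1, "inhibit": -1, "inhibition": -1,
}


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass(frozen=True)
class SignedNetwork:
    """A signed, directed interaction network.

    ``edges`` are (source, target, sign) triples with sign in {+1, -1}.
    Self-loops are removed and exact duplicate triples collapsed on
    construction; a pair of nodes connected by BOTH signs is legal and kept
    as two distinct edges.
    """

    nodes: frozenset[str]
    edges: tuple[tuple[str, str, int], ...]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, int]],
        extra_nodes: Iterable[str] = (),
    ) -> "SignedNetwork":
        seen: dict[tuple[str, str, int], None] = {}
        nodes: set[str] = set(extra_nodes)
        n_self = n_dup = 0
        for src, tgt, sign in edges:
            if sign not in (1, -1):
                raise InputError(f"edge sign must be +1 or -1, got {sign!r}")
            nodes.add(src)
            nodes.add(tgt)
            if src == tgt:
                n_self += 1
                continue
            key = (src, tgt, int(sign))
            if key in seen:
                n_dup += 1
                continue
            seen[key] = None
        if n_self:
            logger.warning("removed %d self-loop edge(s)", n_self)
        if n_dup:
            logger.warning("collapsed %d duplicate edge(s)", n_dup)
        return cls(nodes=frozenset(nodes), edges=tuple(seen))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def in_edges(self) -> dict[str, list[tuple[str, str, int]]]:
        """Map target -> incoming edges."""
        out: dict[str, list[tuple[str, str, int]]] = {v: [] for v in self.nodes}
        for e in self.edges:
            out[e[1]].append(e)
        return out

    def out_edges(self) -> dict[str, list[tuple[str, str, int]]]:
        """Map source -> outgoing edges."""
        out: dict[str, list[tuple[str, str, int]]] = {v: [] for v in self.nodes}
        for e in self.edges:
            out[e[0]].append(e)
        return out


@dataclass(frozen=True)
class Measurement:
    score: float   # continuous activity score (e.g. TF NES)
    alpha: float   # mismatch weight, |score|
    m: int         # discretized sign, +1 or -1


@dataclass
class MeasurementSet:
    """Per-TF continuous scores with their discretized ILP inputs.

    For every retained entry ``alpha = |score|`` and ``m = sign(score)``;
    zero scores are never retained (they carry no directional information).
    """

    entries: dict[str, Measurement] = field(default_factory=dict)

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "MeasurementSet":
        entries = {}
        for sym, s in scores.items():
            s = float(s)
            if s == 0.0:
                logger.warning("dropping zero-score measurement for %s", sym)
                continue
            entries[sym] = Measurement(score=s, alpha=abs(s), m=1 if s > 0 else -1)
        return cls(entries=entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sym: str) -> bool:
        return sym in self.entries

    def restrict_to(self, nodes: Iterable[str]) -> "MeasurementSet":
        """Drop measured symbols absent from ``nodes`` (warning, not error)."""
        nodes = set(nodes)
        kept = {s: m for s, m in self.entries.items() if s in nodes}
        dropped = len(self.entries) - len(kept)
        if dropped:
            logger.warning("dropped %d measured TF(s) absent from the network", dropped)
        return MeasurementSet(entries=kept)


@dataclass
class NodePenaltyWeights:
    """Per-node penalty adjustment gamma in [-1, 1]; 0 for unmapped nodes.

    A positive gamma cheapens activation and taxes inhibition of the node,
    and vice versa; it is derived from pathway footprint scores.
    """

    gamma: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sym, g in self.gamma.items():
            if not -1.0 <= g <= 1.0:
                raise InputError(f"gamma[{sym}] = {g} outside [-1, 1]")

    def __getitem__(self, sym: str) -> float:
        return self.gamma.get(sym, 0.0)


#: sentinel for a perturbation target whose effect direction is unknown
UNKNOWN = 0


@dataclass
class PerturbationSet:
    """Known perturbation targets with effect +1, -1 or UNKNOWN (0)."""

    targets: dict[str, int] = field(default_factory=dict)

    @classmethod
    def build(cls, targets: Mapping[str, int], pkn: SignedNetwork) -> "PerturbationSet":
        for sym, eff in targets.items():
            if sym not in pkn.nodes:
                raise InputError(f"perturbation target {sym!r} not in the network")
            if eff not in (1, -1, UNKNOWN):
                raise InputError(f"perturbation effect must be +1, -1 or unknown, got {eff!r}")
        return cls(targets=dict(targets))

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathway membership); no empty sets allowed."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class SolverConfig:
    """ILP solver and solution-pool settings.

    Defaults accept solutions within 0.01% of the best objective, enumerate
    up to 500 and keep the 100 most diverse, with a one-hour time limit.
    """

    beta: float = 0.1
    relgap: float = 1e-4
    pool_populate: int = 500
    pool_capacity: int = 100
    time_limit_s: int = 3600
    seed: int = 0
    mode: str = "standard"  # "standard" | "inverse"

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise InputError("beta must be >= 0")
        if self.relgap < 0:
            raise InputError("relgap must be >= 0")
        if self.pool_capacity > self.pool_populate:
            raise InputError("pool_capacity must be <= pool_populate")
        if self.mode not in ("standard", "inverse"):
            raise InputError(f"mode must be 'standard' or 'inverse', got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SolverConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f: getattr(self, f) for f in self.__dataclass_fields__}, fh
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sif(path: str | os.PathLike) -> SignedNetwork:
    """Read a 3-column SIF file: source <TAB> relation <TAB> target.

    The relation column accepts 1/+1/activate/activation for activating and
    -1/inhibit/inhibition for inhibitory edges.  Self-loops are removed and
    duplicate triples collapsed (logged); an unparseable relation or an empty
    file is a hard error.
    """
    edges: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise InputError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            src, rel, tgt = (p.strip() for p in parts)
            sign = _SIGN_TOKENS.get(rel.lower())
            if sign is None:
                raise InputError(f"{path}: line {lineno}: unparseable relation {rel!r}")
            edges.append((src, tgt, sign))
    if not edges:
        raise InputError(f"{path}: empty SIF file")
    return SignedNetwork.from_edges(edges)


def write_sif(net: SignedNetwork, path: str | os.PathLike) -> None:
    """Write a network as canonical 3-column SIF (signs as 1 / -1)."""
    with open(path, "w") as fh:
        for src, tgt, sign in sorted(net.edges):
            fh.write(f"{src}\t{sign}\t{tgt}\n")


def read_measurements(path: str | os.PathLike) -> MeasurementSet:
    """Read a 2-column TSV of symbol, score into a MeasurementSet.

    Duplicate symbols and non-numeric scores are hard errors; zero scores
    are dropped with a warning.
    """
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, got {len(parts)}"
                )
            sym, raw = parts[0].strip(), parts[1].strip()
            if sym in scores:
                raise InputError(f"{path}: line {lineno}: duplicate symbol {sym!r}")
            try:
                scores[sym] = float(raw)
            except ValueError:
                raise InputError(
                    f"{path}: line {lineno}: non-numeric score {raw!r} for {sym!r}"
                ) from None
    return MeasurementSet.from_scores(scores)


def read_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file (set name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(
                    f"{path}: line {lineno}: GMT line needs >= 3 fields, got {len(parts)}"
                )
            name = parts[0].strip()
            if name in sets:
                raise InputError(f"{path}: line {lineno}: duplicate set name {name!r}")
            members = frozenset(p.strip() for p in parts[2:] if p.strip())
            sets[name] = members
    return GeneSetCollection(sets=sets)


def read_targets(path: str | os.PathLike, pkn: SignedNetwork) -> PerturbationSet:
    """Read perturbation targets: symbol <TAB> effect (1, -1, or NA/unknown)."""
    targets: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            sym, raw = parts[0].strip(), parts[1].strip().lower()
            if raw in ("na", "nan", "unknown", "?"):
                targets[sym] = UNKNOWN
            elif raw in ("1", "+1"):
                targets[sym] = 1
            elif raw == "-1":
                targets[sym] = -1
            else:
                raise InputError(f"{path}: line {lineno}: unparseable effect {raw!r}")
    return PerturbationSet.build(targets, pkn)


def write_solution_tables(pool, out_dir: str | os.PathLike) -> None:
    """Write the solution pool as plain tables consumable by any graph viewer.

    Per solution ``edges_<k>.sif``; ``nodes.tsv`` with the pool-average node
    activity in [-1, 1] and a node class (tf / input / inferred); and
    ``summary_network.sif`` listing every edge used in >= 1 solution with its
    usage frequency.
    """
    from causalnet.ilp import aggregate_pool  # local import, avoids a cycle

    if not pool.solutions:
        raise InputError("cannot write tables for an empty solution pool")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for k, sol in enumerate(pool.solutions):
        with open(os.path.join(out_dir, f"edges_{k:03d}.sif"), "w") as fh:
            for src, tgt, sign in sorted(sol.used_edges):
                fh.write(f"{src}\t{sign}\t{tgt}\n")
    summary = aggregate_pool(pool)
    with open(os.path.join(out_dir, "nodes.tsv"), "w") as fh:
        fh.write("symbol\tavg_activity\tnode_class\n")
        for sym in sorted(summary.node_activity):
            if sym in pool.measured_nodes:
                cls = "tf"
            elif sym in pool.input_nodes:
                cls = "input"
            else:
                cls = "inferred"
            fh.write(f"{sym}\t{summary.node_activity[sym]:.6g}\t{cls}\n")
    with open(os.path.join(out_dir, "summary_network.sif"), "w") as fh:
        fh.write("source\tsign\ttarget\tfrequency\n")
        for (src, tgt, sign), freq in sorted(summary.edge_frequency.items()):
            fh.write(f"{src}\t{sign}\t{tgt}\t{freq:.6g}\n")
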