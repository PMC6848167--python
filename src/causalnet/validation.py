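"""Two-step enrichment validation of inferred networks.

Step 1 tests, separately for the up- and down-regulated node sets of a
solution, whether each pathway gene set is over-represented among the
inferred nodes (hypergeometric upper tail over the PKN node universe,
Benjamini-Hochberg FDR within each direction).  Step 2 asks whether a
prior set of perturbation-attributed pathways is enriched among the
dysregulated pathways, combining the per-pathway FDR-adjusted p-values with
four set statistics (Stouffer, Wilcoxon rank-sum, reporter, tail strength),
each calibrated against a random-subset permutation null.  A result shows
"clear directionality" when it is significant in one direction and
insignificant in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from causalnet.core import GeneSetCollection, InputError

logger = logging.getLogger("causalnet")

_P_CLIP = 1e-12  # keep normal quantiles of p-values finite
METHODS = ("stouffer", "wilcoxon", "reporter", "tailStrength")


@dataclass
class OraResult:
    """Directional over-representation: one row per (gene set, direction)."""

    rows: dict[tuple[str, str], dict] = field(default_factory=dict)
    universe_size: int = 0

    def pvalues(self, direction: str) -> dict[str, float]:
        return {
            name: row["fdr_adjusted_p"]
            for (name, d), row in self.rows.items()
            if d == direction
        }


@dataclass
class AttributionResult:
    """Step-2 combination statistics for one direction."""

    p_values: dict[str, float]
    mean_p: float
    sd_p: float
    degenerate: bool = False


@dataclass
class TwoStepResult:
    ora: OraResult
    up: AttributionResult
    down: AttributionResult
    clear_directionality: bool
    significant_direction: str | None


def directional_ora(
    states: Mapping[str, int],
    sets: GeneSetCollection,
    universe: Iterable[str],
) -> OraResult:
    """Hypergeometric over-representation of up- and down-regulated nodes.

    The draw for the "up" direction is the set of nodes with state +1, for
    "down" the nodes with state -1; the universe is the full node space of
    the network.  A gene set is only tested when at least one member appears
    among the nonzero-state nodes (either direction); FDR correction is
    applied within each direction.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    nonzero = {v for v, s in states.items() if s != 0}
    if not nonzero <= universe:
        raise InputError("nonzero-state symbols outside the universe")
    draws = {
        "up": {v for v, s in states.items() if s == 1},
        "down": {v for v, s in states.items() if s == -1},
    }
    m_univ = len(universe)
    result = OraResult(universe_size=m_univ)
    tested: dict[str, dict[str, dict]] = {"up": {}, "down": {}}
    for name, members in sets.sets.items():
        members_in_universe = members & universe
        if not members_in_universe or not (members_in_universe & nonzero):
            continue  # untested: no member among the dysregulated nodes
        k_set = len(members_in_universe)
        for direction, draw in draws.items():
            n_draw = len(draw)
            overlap = len(members_in_universe & draw)
            # upper tail: P[X >= overlap], X ~ Hypergeom(M=universe, K=set, n=draw)
            p = float(sps.hypergeom.sf(overlap - 1, m_univ, k_set, n_draw))
            tested[direction][name] = {
                "overlap": overlap,
                "set_size": k_set,
                "universe_size": m_univ,
                "draw_size": n_draw,
                "p_value": p,
            }
    for direction, rows in tested.items():
        if rows:
            names = sorted(rows)
            padj = multipletests(
                [rows[n]["p_value"] for n in names], method="fdr_bh"
            )[1]
            for n, q in zip(names, padj):
                rows[n]["fdr_adjusted_p"] = float(q)
        for n, row in rows.items():
            result.rows[(n, direction)] = row
    return result


def _subset_indices(rng: np.random.Generator, n_perm: int, m_total: int, m: int) -> np.ndarray:
    """(n_perm, m) matrix of random size-m index subsets of range(m_total)."""
    keys = rng.random((n_perm, m_total))
    return np.argpartition(keys, m - 1, axis=1)[:, :m]


def attributed_enrichment(
    pvalues: Mapping[str, float],
    attributed: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> AttributionResult:
    """Enrichment of an attributed pathway set among small p-values.

    Input is the per-pathway (FDR-adjusted) p-values of one direction from
    step 1.  With attributed subset A of size m among M tested pathways:

    - ``wilcoxon``: one-sided rank-sum test that the attributed p-values are
      smaller than the rest.
    - ``stouffer``: S = sum_{i in A} Phi^{-1}(1 - p_i) / sqrt(m); significance
      as the fraction of random size-m subsets with S at least as large.
    - ``reporter``: mean of Phi^{-1}(1 - p_i) over A, standardized by the
      subset-permutation null's mean and SD; one-sided normal p-value.
    - ``tailStrength``: TS = mean_i (1 - p_(i) * (m + 1) / i) over the
      ascending-sorted attributed p-values; same permutation null.

    Permutation p-values use the add-one estimator (b + 1) / (n_perm + 1).
    With m = M there is no contrast: all methods return 1 with a warning.
    """
    names = sorted(pvalues)
    attributed = set(attributed)
    hit = [n for n in names if n in attributed]
    if not hit:
        raise InputError("no attributed pathway among the tested sets")
    m_total, m = len(names), len(hit)
    if m == m_total:
        logger.warning("all tested pathways are attributed; no contrast, p = 1")
        ones = {meth: 1.0 for meth in METHODS}
        return AttributionResult(p_values=ones, mean_p=1.0, sd_p=0.0, degenerate=True)

    p = np.clip(np.asarray([pvalues[n] for n in names]), _P_CLIP, 1.0 - _P_CLIP)
    in_a = np.asarray([n in attributed for n in names])
    z = sps.norm.isf(p)  # Phi^{-1}(1 - p)

    rng = np.random.default_rng(seed)
    idx = _subset_indices(rng, n_perm, m_total, m)
    z_perm = z[idx]                      # (n_perm, m)
    p_perm = np.sort(p[idx], axis=1)     # ascending per subset

    out: dict[str, float] = {}

    # wilcoxon: attributed p-values smaller than the rest
    out["wilcoxon"] = float(
        sps.mannwhitneyu(p[in_a], p[~in_a], alternative="less").pvalue
    )

    # stouffer
    s_obs = z[in_a].sum() / np.sqrt(m)
    s_null = z_perm.sum(axis=1) / np.sqrt(m)
    out["stouffer"] = float((1 + (s_null >= s_obs - 1e-12).sum()) / (n_perm + 1))

    # reporter: standardized mean z, normal tail
    r_obs = z[in_a].mean()
    r_null = z_perm.mean(axis=1)
    sd = r_null.std(ddof=1)
    if sd == 0:
        out["reporter"] = 1.0 if r_obs <= r_null.mean() else 0.0
    else:
        out["reporter"] = float(sps.norm.sf((r_obs - r_null.mean()) / sd))

    # tailStrength
    ranks = np.arange(1, m + 1)
    ts_obs = float(np.mean(1.0 - np.sort(p[in_a]) * (m + 1) / ranks))
    ts_null = np.mean(1.0 - p_perm * (m + 1) / ranks, axis=1)
    out["tailStrength"] = float((1 + (ts_null >= ts_obs - 1e-12).sum()) / (n_perm + 1))

    vals = np.asarray([out[meth] for meth in METHODS])
    return AttributionResult(
        p_values=out, mean_p=float(vals.mean()), sd_p=float(vals.std(ddof=1))
    )


def two_step(
    states: Mapping[str, int],
    sets: GeneSetCollection,
    universe: Iterable[str],
    attributed: Iterable[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TwoStepResult:
    """Directional ORA followed by attributed-set enrichment per direction.

    A direction counts as significant when the mean of the four method
    p-values falls below ``alpha``; "clear directionality" means significance
    in exactly one direction.  When a direction has no tested pathway (no
    nonzero nodes, or no overlap) its result is p = 1 by convention.
    """
    ora = directional_ora(states, sets, universe)
    attributed = set(attributed)
    results: dict[str, AttributionResult] = {}
    for direction in ("up", "down"):
        pvals = ora.pvalues(direction)
        if not pvals or not (attributed & set(pvals)):
            results[direction] = AttributionResult(
                p_values={meth: 1.0 for meth in METHODS},
                mean_p=1.0, sd_p=0.0, degenerate=True,
            )
            continue
        results[direction] = attributed_enrichment(
            pvals, attributed, n_perm=n_perm, seed=seed
        )
    up_sig = results["up"].mean_p < alpha
    down_sig = results["down"].mean_p < alpha
    clear = up_sig != down_sig
    sig_dir = "up" if (clear and up_sig) else ("down" if clear else None)
    return TwoStepResult(
        ora=ora, up=results["up"], down=results["down"],
        clear_directionality=clear, significant_direction=sig_dir,
    )
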