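"""Two-step enrichment validation: hypergeometric ORA and set statistics."""

import math

import numpy as np
import pytest

from causalnet import GeneSetCollection, attributed_enrichment, directional_ora, two_step
from causalnet.core import InputError
from causalnet.validation import METHODS
from oracles import hypergeom_upper_tail


class TestDirectionalOra:
    def _universe(self, n):
        return {f"g{i:02d}" for i in range(n)}

    def test_perfect_overlap_closed_form(self):
        universe = self._universe(20)
        members = {f"g{i:02d}" for i in range(5)}
        sets = GeneSetCollection(sets={"S": frozenset(members)})
        states = {g: 1 for g in members}
        res = directional_ora(states, sets, universe)
        p = res.rows[("S", "up")]["p_value"]
        assert p == pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_other_direction_p_one(self):
        universe = self._universe(10)
        sets = GeneSetCollection(sets={"S": frozenset({"g00", "g01"})})
        states = {"g00": 1, "g05": -1}
        res = directional_ora(states, sets, universe)
        assert res.rows[("S", "down")]["overlap"] == 0
        assert res.rows[("S", "down")]["p_value"] == pytest.approx(1.0)

    def test_untouched_set_absent(self):
        universe = self._universe(10)
        sets = GeneSetCollection(sets={
            "HIT": frozenset({"g00"}), "MISS": frozenset({"g09"}),
        })
        res = directional_ora({"g00": 1}, sets, universe)
        tested = {name for name, _ in res.rows}
        assert tested == {"HIT"}

    def test_empty_universe_rejected(self):
        sets = GeneSetCollection(sets={"S": frozenset({"a"})})
        with pytest.raises(InputError):
            directional_ora({}, sets, set())

    def test_matches_exact_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n_univ = int(rng.integers(8, 31))
            universe = self._universe(n_univ)
            members = set(rng.choice(sorted(universe), int(rng.integers(2, 6)), replace=False))
            states = {}
            for g in rng.choice(sorted(universe), int(rng.integers(1, n_univ)), replace=False):
                states[g] = int(rng.choice([-1, 1]))
            if not members & set(states):
                continue
            sets = GeneSetCollection(sets={"S": frozenset(members)})
            res = directional_ora(states, sets, universe)
            for direction, s in (("up", 1), ("down", -1)):
                draw = {g for g, st in states.items() if st == s}
                row = res.rows[("S", direction)]
                expected = hypergeom_upper_tail(
                    len(members & draw), n_univ, len(members), len(draw)
                )
                assert row["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_within_direction(self):
        universe = self._universe(30)
        sets = GeneSetCollection(sets={
            "A": frozenset({"g00", "g01", "g02"}),
            "B": frozenset({"g10", "g11", "g12"}),
            "C": frozenset({"g00", "g20"}),
        })
        states = {"g00": 1, "g01": 1, "g02": 1, "g10": 1}
        res = directional_ora(states, sets, universe)
        raw = sorted(
            res.rows[(n, "up")]["p_value"] for n in ("A", "B", "C")
        )
        adj = sorted(
            res.rows[(n, "up")]["fdr_adjusted_p"] for n in ("A", "B", "C")
        )
        assert all(a >= r for a, r in zip(adj, raw))
        assert all(0 <= a <= 1 for a in adj)


class TestAttributedEnrichment:
    def _pvals(self, rng, m_total=24):
        return {f"P{i:02d}": float(rng.uniform()) for i in range(m_total)}

    def test_smallest_pvalues_attributed_is_extreme(self):
        rng = np.random.default_rng(0)
        pvals = self._pvals(rng)
        attributed = sorted(pvals, key=pvals.get)[:6]
        res = attributed_enrichment(pvals, attributed, n_perm=2000, seed=1)
        # the attributed set holds exactly the m smallest p-values: the
        # rank-sum p equals the minimal achievable value for (m, M)
        from scipy.stats import mannwhitneyu

        a = sorted(pvals.values())[:6]
        b = sorted(pvals.values())[6:]
        assert res.p_values["wilcoxon"] == pytest.approx(
            mannwhitneyu(a, b, alternative="less").pvalue
        )
        for meth in ("stouffer", "reporter", "tailStrength"):
            assert res.p_values[meth] < 0.05

    def test_all_pathways_attributed_degenerate(self):
        rng = np.random.default_rng(2)
        pvals = self._pvals(rng, 8)
        res = attributed_enrichment(pvals, set(pvals), n_perm=200, seed=0)
        assert res.degenerate
        assert all(p == 1.0 for p in res.p_values.values())

    def test_no_overlap_rejected(self):
        with pytest.raises(InputError):
            attributed_enrichment({"A": 0.5}, {"ZZZ"}, n_perm=200)

    def test_mean_sd_over_four_methods(self):
        rng = np.random.default_rng(3)
        pvals = self._pvals(rng)
        res = attributed_enrichment(pvals, list(pvals)[:5], n_perm=500, seed=0)
        vals = [res.p_values[m] for m in METHODS]
        assert res.mean_p == pytest.approx(np.mean(vals))
        assert res.sd_p == pytest.approx(np.std(vals, ddof=1))

    @pytest.mark.parametrize("method", METHODS)
    def test_monotone_in_attributed_pvalues(self, method):
        """Shrinking one attributed p-value never increases any method's p."""
        rng = np.random.default_rng(4)
        pvals = self._pvals(rng, 20)
        attributed = sorted(pvals)[:5]
        base = attributed_enrichment(pvals, attributed, n_perm=1000, seed=7)
        better = dict(pvals)
        better[attributed[0]] = pvals[attributed[0]] * 0.01
        res = attributed_enrichment(better, attributed, n_perm=1000, seed=7)
        assert res.p_values[method] <= base.p_values[method] + 1e-12

    def test_uniform_null_roughly_calibrated(self):
        """Quick 300-dataset check; the full calibration lives in the
        acceptance suite."""
        rng = np.random.default_rng(5)
        hits = {m: 0 for m in METHODS}
        n_data = 300
        for i in range(n_data):
            pvals = {f"P{k:02d}": float(rng.uniform()) for k in range(24)}
            res = attributed_enrichment(pvals, [f"P{k:02d}" for k in range(6)],
                                        n_perm=400, seed=i)
            for m in METHODS:
                hits[m] += res.p_values[m] < 0.05
        for m in METHODS:
            assert 0.01 <= hits[m] / n_data <= 0.10, (m, hits[m] / n_data)


class TestTwoStep:
    def test_planted_up_signal_has_clear_directionality(self):
        rng = np.random.default_rng(6)
        universe = {f"g{i:03d}" for i in range(120)}
        up_nodes = sorted(universe)[:25]
        states = {g: 1 for g in up_nodes}
        for g in sorted(universe)[60:70]:
            states[g] = -1
        sets = {}
        for k in range(3):  # attributed sets drawn from the up nodes
            members = set(rng.choice(up_nodes, 8, replace=False)) | set(
                rng.choice(sorted(universe), 4, replace=False)
            )
            sets[f"ATTR{k}"] = frozenset(members)
        for k in range(12):  # decoy sets
            sets[f"RAND{k}"] = frozenset(rng.choice(sorted(universe), 10, replace=False))
        res = two_step(
            states, GeneSetCollection(sets=sets), universe,
            {"ATTR0", "ATTR1", "ATTR2"}, n_perm=2000, seed=0,
        )
        assert res.up.mean_p < 0.05
        assert res.down.mean_p > 0.05
        assert res.clear_directionality
        assert res.significant_direction == "up"

    def test_no_nonzero_states_p_one_flag_unset(self):
        universe = {"a", "b", "c"}
        sets = GeneSetCollection(sets={"S": frozenset({"a"})})
        res = two_step({}, sets, universe, {"S"}, n_perm=200)
        assert res.up.mean_p == 1.0 and res.down.mean_p == 1.0
        assert not res.clear_directionality
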