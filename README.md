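# causalnet

Contextualize a signed, directed signaling network against transcription-factor
activity footprints by integer linear programming.

## The problem

Gene expression profiling shows *which* genes change, but not *which upstream
signaling events drove the change* — protein activities correlate only
partially with their own transcript levels. A more reliable readout is the
**footprint** a signaling protein leaves downstream: a transcription factor's
(TF) activity is visible in the expression of its regulon targets, a
pathway's activity in its perturbation-response signature genes. `causalnet`
takes (1) a prior knowledge network (**PKN**) of signed, directed
protein–protein interactions, (2) TF activity scores inferred from a
differential-expression signature, and optionally (3) pathway activity scores,
and searches for the sub-network of causally consistent mechanisms that best
explains the observed TF pattern. It is written for computational biologists
who want mechanistic hypotheses — which receptors, kinases and mediators were
up- or down-regulated, and through which edges — out of a transcriptomics
contrast.

## The model

Every network node *j* takes a state x_j ∈ {−1, 0, +1}. Measured TFs carry a
discretized sign m_j and weight α_j = |NES_j|; the inference solves the
integer linear program

minimize  Σ_j α_j·|x_j − m_j| + Σ_j β·(1 − γ_j)·x_j⁺ + Σ_j β·(1 + γ_j)·x_j⁻

subject to causal consistency: a node may only be active if an incoming edge
delivers its state from an already-explained node with the matching sign, and
the justification chain must be acyclic (certified by integer depth
variables). β controls sparsity; γ ∈ [−1, 1] is a per-node adjustment derived
from pathway footprint scores, score(x) = 2·(percentile(x) − 0.5) against a
gene-permutation null, that cheapens changes in the direction the pathway
evidence expects. Two modes are available: **standard** (perturbation targets
and effects known — they become the causal roots) and **inverse** (targets
unknown — an artificial root proposes entry points and the chosen edge signs
are reported as inferred perturbation effects). Near-optimal alternatives
within a relative tolerance are enumerated into a solution pool and
summarized as node activity averages and edge usage frequencies.

See `docs/methods.md` for the full formulation, the scoring layer, the
two-step enrichment validation and the synthetic benchmark design.

## Worked example

Generate a synthetic scenario (a 40-node PKN with a planted causal cascade
and noisy TF measurements), then contextualize it:

```bash
causalnet simulate --n-nodes 40 --n-tfs 5 --seed 11 --out scn
causalnet run --mode std --pkn scn/pkn.sif --measurements scn/measurements.tsv \
    --targets scn/targets.tsv --beta 0.1 --relgap 0 --pool 10 --populate 10 \
    --out run
```

prints

```
9 solution(s) over 1 beta value(s); best objective 1.1
```

meaning nine co-optimal mechanism networks explain the five measured TFs at
objective 1.1 (here: zero mismatch — every measured sign is reproduced — plus
eleven active nodes at β = 0.1 each). `run/nodes.tsv` holds the pool-average
node activities in [−1, 1] and each node's role:

```
symbol  avg_activity  node_class
N0000   0             inferred
N0001   1             inferred
N0002   -1            tf
N0005   1             tf
N0006   1             inferred
...
```

`tf` rows are measured TFs, `input` rows perturbation targets, `inferred`
rows pure causal-reasoning predictions; `edges_000.sif` … hold each
solution's mechanism edges and `summary_network.sif` the edge usage
frequencies across the pool. The same scenario without telling the tool the
perturbation target:

```bash
causalnet run --mode inv --pkn scn/pkn.sif --measurements scn/measurements.tsv \
    --beta 0.1 --pool 5 --populate 5 --out runinv
cat runinv/inferred_targets.tsv
```

```
N0014   1
```

recovers the planted perturbation site N0014 with its true activatory effect
(compare `scn/targets.tsv`), at the same objective as the informed run.

Downstream, `causalnet topology` profiles an inferred network (degree,
betweenness, HITS hub/authority), and `causalnet validate` runs the two-step
enrichment check — directional over-representation of solution nodes in
pathway gene sets, then enrichment of an attributed pathway list among the
dysregulated pathways with four set statistics (Stouffer, Wilcoxon, reporter,
tail strength) against subset-permutation nulls, reporting whether the result
has clear directionality.

## Library use

Every CLI step is a plain function:

```python
from causalnet import (make_scenario, tf_nes, select_top_tfs, SolverConfig,
                       NodePenaltyWeights, build_ilp, solve_pool, aggregate_pool)

scn = make_scenario(seed=0)                       # synthetic ground truth
ms = select_top_tfs(tf_nes(scn.signature, scn.regulons), k=8)
cfg = SolverConfig(beta=0.1, relgap=0.0)
pool = solve_pool(build_ilp(scn.pkn, ms, NodePenaltyWeights(),
                            scn.perturbation, cfg), cfg)
states = aggregate_pool(pool).state_signs()       # consensus node states
```

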