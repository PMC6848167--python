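# Methods

## Problem and model

`causalnet` contextualizes a **prior knowledge network** (PKN) — a curated,
signed, directed protein–protein interaction graph — against downstream
**expression footprints**. The observable is not the activity of signaling
proteins themselves but the transcriptional trace they leave: transcription
factor (TF) activities estimated from the expression of their regulon
targets, and pathway activities estimated from footprint gene signatures.
The tool selects the sub-network and node activity pattern that best explains
those observations causally.

Each network node *j* takes a state x_j ∈ {−1, 0, +1} (inhibited, absent,
activated). Measured TFs carry a discretized sign m_j ∈ {−1, +1} and a
continuous weight α_j = |NES_j|. The inference minimizes

    Σ_j α_j·|x_j − m_j|  +  Σ_j β·(1 − γ_j)·x_j⁺  +  Σ_j β·(1 + γ_j)·x_j⁻

where x_j⁺/x_j⁻ indicate activation/inhibition, β ≥ 0 is the node (sparsity)
penalty, and γ_j ∈ [−1, 1] is a pathway-score-derived adjustment that makes
activation of nodes downstream of an up-scored pathway cheaper and their
inhibition dearer (and symmetrically for down-scored pathways).

States must be **causally consistent**: a nonzero state is only admissible if
it is delivered from a perturbation root through a chain of sign-consistent
edges, and the justification must be acyclic — no state may ultimately
justify itself around a feedback loop. The integer program encodes this with
per-edge carry indicators (an edge may transmit an up- or down-signal only if
its source has the matching state and its target adopts the implied state)
and per-node integer depth variables that must strictly increase along
carrying edges (big-M = node count, the tightest generally valid constant).
Perturbation targets are roots: depth 0, state fixed by the stated effect, or
free-but-exempt from the causation constraint when the effect is unknown.

Two operating modes:

* **Standard**: the perturbation targets and effects are inputs.
* **Inverse**: no targets are known. An artificial root with fixed state +1
  is connected by candidate edges of *both* signs to every zero-in-degree
  node (to all nodes if the network has none). The artificial node carries no
  node penalty and is stripped from reported solutions; the sign of each
  chosen candidate edge is reported as the inferred perturbation effect on
  its target.

Because |x_j − m_j| with m_j ∈ {−1, +1} equals 1 − m_j·x_j exactly, the
mismatch term is affine in the state indicators and enters the objective
directly, without auxiliary variables.

## Solver and solution pool

The MILP is solved with HiGHS through `scipy.optimize.milp`. Near-optimal
alternatives are enumerated solver-agnostically: after each incumbent, a
no-good cut excluding that exact binary pattern (states and carries) is
added and the model re-solved, while the objective stays within `relgap`
(default 10⁻⁴, i.e. 0.01%) of the optimum, up to `pool_populate` (default
500) solutions; if more are found than `pool_capacity` (default 100), the
pool is thinned by greedy max–min Hamming distance on node-state vectors,
always retaining the optimum first. The default time limit is 3600 s;
hitting it returns the best-found pool flagged non-optimal rather than
failing. Pools can be aggregated — also across runs with different β —
into per-node mean activities and per-edge usage frequencies.

Every reported solution is auditable: `audit_solution` re-derives causal
support by fixed-point closure over the used edges and recomputes the
objective from the states (tolerance 10⁻⁶). An independent brute-force
reference (`causalnet.exhaustive`) enumerates all 3^n state assignments with
a vectorized consistency closure; the test suite requires exact agreement of
optima on hundreds of random instances with ≤ 10 nodes.

## Footprint scoring

**Pathway scores** (γ weights): the observed statistic of a pathway is the
weighted sum of signature values over its footprint genes. An empirical null
is built by gene-wise permutation of the signature (default 10,000 rounds;
one shared permutation stream across pathways per iteration, genes taken in
sorted order — this makes the computation exactly reproducible and exactly
testable against an independent loop). The percentile of the observed value
(mid-rank tie handling, so a constant null yields 0.5) maps to
score = 2·(percentile − 0.5) ∈ [−1, 1]. Each pathway then deposits its score
as γ on a small set of representative network nodes (pairwise disjoint
across pathways).

**TF activities**: a Stouffer-style rank NES. Signature values are converted
to fractional ranks r ∈ (0,1), mapped through Φ⁻¹, and combined as
NES = Σ mode·q / √n over the regulon targets present (≥ 10 required — smaller
regulons give unstable activity estimates and are skipped). Downstream, only |NES|
(as α) and sign(NES) (as m) are consumed, which is why a rank NES suffices;
exact reproduction of the VIPER/aREA two-tail statistic is out of scope. The
NES is invariant under monotone transforms of the signature by construction.
By default the top 50 TFs by |NES| enter the ILP (`select_top_tfs`), with
deterministic lexicographic tie-breaking.

## Two-step enrichment validation

Step 1: hypergeometric over-representation of the up-regulated (x = +1) and,
separately, down-regulated (x = −1) solution nodes in pathway gene sets, with
the full PKN node set as universe; a set is only tested if at least one
member appears among the nonzero nodes; Benjamini–Hochberg FDR within each
direction. Step 2: enrichment of a perturbation-attributed pathway list among
the per-pathway FDR-adjusted p-values, with four statistics — one-sided
Wilcoxon rank-sum, Stouffer (Σ Φ⁻¹(1−p)/√m), reporter (standardized mean
Φ⁻¹(1−p)), and tail strength (mean of 1 − p₍ᵢ₎(m+1)/i over the ascending
attributed p-values). The latter three are calibrated against a random
size-m subset permutation null with the add-one estimator (b+1)/(n+1);
p-values are clipped to [10⁻¹², 1−10⁻¹²] before normal quantiles. With all
pathways attributed there is no contrast and every method returns 1 with a
warning. A result has **clear directionality** when the mean of the four
p-values is below α = 0.05 in exactly one direction.

Under an i.i.d.-uniform null all four statistics are calibrated (type-I
error 0.05 ± 0.02 at α = 0.05 over 2000 simulated datasets — checked in the
acceptance suite), and all four are monotone: shrinking an attributed
p-value never increases any method's p-value (with a common permutation
seed).

## Topology and robustness analyses

Topology metrics (in/out/all degree on the multigraph, unnormalized
betweenness, HITS hub/authority scores iterated to 10⁻⁸ and normalized to
max 1) use `networkx`; node weights (e.g. pool-average activities) gate
inclusion — weight-0 nodes are dropped before computation — but the metrics
themselves are unweighted, since a numeric weighting scheme is not uniquely
defined. Degree- and sign-preserving randomization performs edge switches
independently within the activating and inhibitory edge class (default 10
switch attempts per edge, 100 networks), exactly conserving every node's
per-sign in/out degree. Robustness of an inference run is quantified by
Jaccard similarity of the (node, nonzero state) pair sets between a
reference run and re-runs on (a) 70%-down-sampled and (b) label-reshuffled
measurements, compared with an unpaired two-sided unequal-variance t-test.

## Synthetic scenarios

The generator emulates the layered structure of real inputs at desk scale:

* **Network**: random directed G(n, p) with expected out-degree 2.6 per node
  (the edge density of large curated human signaling networks, roughly 9300
  signed directed edges over 3600 proteins) and 30% inhibitory edges;
  resampled until weakly connected. Default 60 nodes.
* **Planted cascade**: one root drawn from the zero-in-degree nodes
  (perturbations enter at sources, e.g. receptors), random ±1 effect (fixable
  to +1 to emulate activatory-perturbation benchmarks), propagated
  sign-consistently to depth 3, following each available edge with
  probability 0.7 and never revisiting a node. The planted assignment is
  feasible by construction and verified against the consistency audit.
* **Readout**: 8 measured TFs drawn from the cascade leaves plus 8 decoy TFs
  with true state 0 — real TF-activity panels score many factors the
  perturbation never touches, and the decoys are what gives label-reshuffling
  nulls their bite. Each TF gets a 15-gene regulon of fresh synthetic symbols
  (disjoint from network nodes) with random ±1 modes; each target gene's
  t-value is state·mode·3.0 + N(0, 0.5²); 200 background genes are pure
  noise. The standard pipeline is tf_nes → top-8 selection → ILP, mirroring
  the top-50 rule at panel scale.

What the generator does **not** emulate: probe-level noise structure, batch
effects, correlated regulons, overlapping TF target sets, feedback-dominated
topologies, or database bias in the PKN. Passing recovery tests therefore
demonstrates correctness of the inference machinery under the model's own
assumptions, not performance on real transcriptomics.

## Problem sizes and observed behavior

Validation experiments are sized for quick, repeatable runs: oracle
equivalence on 200 random networks of ≤ 10 nodes; recovery, directionality
and robustness contrasts on twenty 60-node scenarios; calibration on 2000
simulated p-value datasets with 500-subset permutation nulls. At these sizes
the standard-mode recovery Jaccard vs planted truth averages ≈ 0.7, the
inverse mode recovers the true root among its inferred perturbation sites in
≈ 85% of scenarios, and the down-sampling/reshuffling contrast shows the expected robustness
signature (down-sampled re-runs several-fold closer to the reference than
reshuffled ones). The
absolute Jaccard of reshuffled controls sits higher here than in a
3610-node network because two ~25-node solutions in a 60-node graph overlap
substantially by chance alone; the contrast, not the absolute level, is the
meaningful quantity at toy scale.

## Numerical choices and edge cases

* Zero-score measurements carry no direction and are dropped with a warning.
* Measured TFs absent from the PKN are dropped (warning), not an error.
* Duplicate (source, target) edges with both signs are legal and kept; exact
  duplicate triples are collapsed; self-loops are removed on load.
* Measured TFs are ordinary nodes: they pay the node penalty and must be
  causally reachable to take a state; the alternative is paying the mismatch.
* Pool enumeration treats solutions as distinct when states *or* used edges
  differ (the no-good cut covers both), so alternative edge supports for the
  same states are enumerated as distinct solutions.
* With a best objective of 0, only exact co-optima (within 10⁻⁹) enter the
  pool regardless of relgap.
* `jaccard_states` returns 1.0 when both supports are empty.
* All generator randomness flows from one scenario seed through named
  sub-streams (CRC-keyed `SeedSequence` spawns), so every fixture is
  reproducible bit-for-bit.

## Known limitations

* The acyclicity big-M formulation has a weak LP relaxation; on adversarial
  instances (e.g. heavily conflicting measurements) pool enumeration can be
  slow, which the per-run time limit converts into a flagged, best-effort
  pool rather than a failure.
* Enumerating alternative edge supports can spend pool slots on solutions
  that differ only in unused-capacity edges between already-active nodes.
* The rank NES is one-tailed in spirit (mode-weighted location shift); TFs
  whose regulons respond with variance changes rather than location shifts
  are not captured.
* Inverse mode restricts candidate perturbation sites to zero-in-degree
  nodes when any exist; a true perturbation at an internal node is then
  only reachable indirectly.
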