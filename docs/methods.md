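# Methods

This note documents the models, defaults and numerical choices behind
`walkhub`, and what the synthetic benchmark does and does not establish.

## Differential screening

Expression values are assumed to be preprocessed log2 intensities (as a
series-matrix export would be); no normalization or background
correction is applied. For a timepoint, the log2 fold change is the
case-minus-control difference of group means, and a gene passes the
screen when |logFC| > 0.585 **and** BH-adjusted p < 0.05, both strict
inequalities. 0.585 = log2(1.5) is the conventional 1.5-fold cutoff.

Two test statistics are provided:

- `two_sample_test` — the ordinary pooled-variance two-sample *t*
  (df = n₁+n₂−2). It is exact, assumption-light, and the module-level
  default, but with 3 replicates per group its 4-df variance estimate
  is noisy: at effect 2.0 and noise SD 0.25 its power against the BH
  threshold for 2,000 genes is only ≈ 0.75.
- `moderated_t_test` — an empirical-Bayes moderated *t*. Gene-wise
  variances are modelled as scaled inverse-χ² around a prior variance
  s₀² with d₀ prior df; (d₀, s₀²) are estimated by moment-matching the
  observed log-variance distribution (with a closed-over Newton solve
  of the trigamma inverse), each posterior variance is
  (d₀s₀² + d·s²)/(d₀+d), and the statistic is referred to a *t* with
  d₀+d df (normal when the moment estimate of gene-to-gene variance
  heterogeneity is non-positive, i.e. complete shrinkage). This is the
  standard hierarchical-model treatment of few-replicate designs; our
  implementation is cross-checked against Bioconductor limma's eBayes
  in the test suite (rank correlation > 0.999; |Δlog p| < 0.1 away from
  the extreme tail). It is the *pipeline* default (`test_method:
  moderated_t`) because borrowing variance information across genes is
  what makes the planted signal recoverable at 3-vs-3 — the ordinary t
  remains available and the `stat_fn` hook accepts any statistic with
  the same signature.

BH adjustment is delegated to `statsmodels` (`fdr_bh`). Degenerate
genes with zero (posterior) variance get p = 1 when the means agree and
the smallest positive float otherwise, with a logged warning.

## Random walk with restart

The walker lives on the confidence-filtered PPI graph: edges are kept
only when score/1000 strictly exceeds 0.400, and the graph is restricted
to its largest connected component (logged), which guarantees a
column-stochastic transition matrix with no dangling nodes. Propagation
uses the binary adjacency — confidences are a retention filter, not a
walk bias — with a weighted-normalization variant behind
`column_normalize(weighted=True)`.

Update rule: `P_{t+1} = (1−r)A′P_t + rP_0`, `A′[i,j] = A[i,j]/deg(j)`,
`P_0` uniform over the seeds present in the network (absent seeds are
dropped with a warning and the mass renormalized). Defaults: restart
r = 0.7 (a widely used propagation default; the analysis is not very
sensitive to r because only the ranking matters), stopping when the L1
difference of successive iterates falls below 1e-5 (L2 and max norms
selectable), max 10,000 iterations with a non-silent warning on
non-convergence. Because the update is a contraction with ratio ≤ 1−r
in L1, convergence takes ≈ log(tol)/log(1−r) iterations (about 30 at
r = 0.7). `closed_form_oracle` solves (I − (1−r)A′)P = rP₀ densely and
exists purely for verification.

Candidate selection after propagation is deliberately explicit: the
seeds that are in the network plus the `top_k` highest-probability
non-seed genes, ties broken lexicographically. `top_k` defaults to 35
so that a ~60-gene seed set yields ≈ 95 candidates, the scale on which
such analyses typically operate; the choice is recorded in the
manifest.

## Intersection

Exact set intersection over ≥ 2 labelled candidate sets; exclusive Venn
region cardinalities are emitted (they sum to the union). An empty
intersection is a legal, warned outcome — downstream stages skip
gracefully rather than crash.

## Module extraction and hub calling

Node weight = k_max × density of the highest k-core of the node's
*closed* neighbourhood (so a node inside a 4-clique weighs 3.0; a leaf
whose neighbourhood is a single edge gets the minimal positive weight
1.0; an isolated node 0). Modules grow by seeded greedy expansion from
the highest-weight unused node, admitting neighbours with weight ≥
(1 − cutoff) × seed weight (cutoff 0.2), followed by a haircut that
*iteratively* removes degree-1 members (iterating makes the operation
idempotent) and a filter requiring each emitted module to contain a
2-core (which also discards trivial pairs and paths). Emitted modules
are node-disjoint; rejected candidates stay available to later seeds.
Score = density × size; ranking breaks ties by larger size, then by
smallest member id. Fluff expansion is not implemented (off is also the
Cytoscape default).

Hub genes are module members with degree **strictly greater than 10**
in the chosen context graph — the top module's induced subgraph by
default, the full candidate subnetwork via `hub_context:
candidate_network`; the context is recorded in every output row.

## Over-representation analysis

For query q, term K, universe N and overlap k: p = P(X ≥ k) with X
hypergeometric (upper tail, so k = 0 gives p = 1); q-values are BH
across all tested terms (note: not the clusterProfiler q-value
estimator); pass ⇔ p < 0.05 ∧ q < 0.05, strict. The default universe is
the network's node set (configurable); out-of-universe members and
query genes are dropped with counts. Enrichment term-level results
depend entirely on the supplied GMT and universe and are therefore
reported, not benchmarked.

## The synthetic benchmark

`walkhub.synth` emulates a two-group (SNI/Sham), three-replicate,
three-timepoint (d3/d7/d21) expression study of 2,000 genes plus a
matching PPI network on the same gene universe:

- **Expression** — baseline log2 intensity 8.0 (arbitrary; only
  differences propagate), i.i.d. Gaussian noise with SD 0.25, planted
  genes shifted by +2.0 log2 units in the case group at their planted
  timepoints. Defaults of 60 planted DE genes per timepoint sharing a
  40-gene common core keep the per-timepoint DEG counts and
  intersection size on the scale typical of nerve-injury screens.
- **Network** — scale-free background by preferential attachment
  (2 edges per node), STRING-style integer scores uniform in
  [500, 999] so the confidence filter keeps the structure intact, plus
  one planted 12-gene dense module inside the common core. When hub
  genes are designated (8 by default), each hub is wired to every other
  module member and the remaining member pairs are filled i.i.d. only
  if needed to reach the target density; at the default size the forced
  edges alone realize density 60/66 ≈ 0.91, giving hubs within-module
  degree 11 (> 10) and non-hubs degree 8 (≤ 10) by construction.
  Without designated hubs the module is purely i.i.d. at
  `module_density`. Background edges that would fall between two module
  members are dropped before planting so the within-module topology is
  exactly the planted one — otherwise stray edges could push a
  periphery member over the hub threshold and make the benchmark's
  expected answer ill-defined.
- **Determinism** — every generator takes an explicit seed; one
  top-level seed spawns the signal/expression/network streams, and
  identical inputs give byte-identical serialized outputs.

What passing the benchmark shows: the pipeline recovers planted
differential signal, module membership and hub identity through the
complete code path, and its statistical components are calibrated under
the null. What it does not show: robustness to the features of real
microarray data the generator deliberately omits — probe effects,
normalization artefacts, batch effects, heteroscedastic and correlated
noise, heavy-tailed intensities, incomplete probe-to-gene mapping, and
PPI networks whose "truth" is itself uncertain. The Gaussian
log-intensity model is this module's assumption, not an empirical claim
about any particular dataset.

## Numerical choices and degenerate inputs

- Strict inequalities at every published threshold (0.585, 0.05, 0.400,
  10, p/q 0.05); boundary values are excluded by unit test.
- Deterministic orderings everywhere randomness is absent: sorted node
  lists in the transition matrix, lexicographic tie-breaks in candidate
  selection and module ranking, sorted edge emission in writers.
- Convergence norms: tolerances are compared strictly (`delta < tol`);
  conservation of probability mass is tracked per iteration and exposed
  on the result object.
- Duplicate edges in input keep the higher score; self-loops and
  malformed rows are hard errors with line numbers.
- An empty candidate intersection, an edgeless candidate subnetwork, or
  a module-free graph end the run with warnings and zero counts, not
  exceptions; missing input files and disjoint id spaces fail before
  any output is written.

## Problem sizes

The test suite and `scripts/acceptance.py` run at the study's native
scale: 2,000-gene experiments, ~2,000-node networks (≈ 4,000 edges),
200 null simulations for calibration, 100 random graphs (n ∈ [10, 200])
for the propagation-vs-linear-solve comparison, 20 pipeline seeds for
the recovery sweep, and exhaustive enumeration oracles up to N = 12
(hypergeometric) and 16 nodes (densest connected subgraph). The whole
suite completes in well under a minute on one CPU.

## Known limitations

- The moderated t moment estimator needs enough genes (hundreds) for a
  stable prior; on very small panels prefer `test_method: t`.
- The rule mapping propagation ranks to a candidate count is an
  explicit `top_k`, because no principled universal cutoff exists;
  analyses that need a fixed candidate-set size should set it
  deliberately.
- MCODE-style extraction is greedy and order-dependent by design; it is
  validated against exhaustive search only on small graphs, where
  greedy and exact answers coincide.
- Enrichment q-values are BH, which is more conservative than the
  Storey-type estimator some tools report.
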