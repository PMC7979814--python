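# Methods

## Model

The multiscale interactome is an undirected heterogeneous graph over four
node kinds — drugs, diseases, proteins, biological functions — with edges
restricted to drug–protein (targets), disease–protein (perturbations),
protein–protein (physical interactions), protein–function (annotations), and
function–function (hierarchy). Hierarchy edges are stored with a single
child→parent orientation; the multiple ontology relation types (is-a,
part-of, regulates, …) are collapsed to that one higher/lower distinction
because the walk model only distinguishes two hierarchy directions. The kind
set and the permitted kind pairs are configurable, so additional node
categories (e.g. anatomical entities) can be represented without code
changes, though no loader for such ontologies ships.

A diffusion profile is the stationary visitation-frequency vector of a
type-biased random walk with restart, computed per focal drug or disease on
a directed view in which the focal node is a source and all other
drugs/diseases are sinks. The walk therefore never uses a drug or disease as
an intermediate: reaching one forces a restart. Mass arriving at sinks is
added back to the restart vector each iteration, which keeps every iterate a
probability vector. Nodes that end up with an empty out-row purely because
of the view construction (e.g. a protein whose only neighbor is the focal
drug) are treated as sinks too, since the sink set is defined as all
zero-out-degree nodes of the view.

At a node, continuation mass is split first across the adjacent node
*types* in proportion to the type weights, then uniformly within each type.
With all weights equal this is **not** the uniform per-edge walk unless each
node's out-neighbors are of a single type; the classical reduction to
personalized PageRank therefore holds (and is tested) on protein-only graphs
with one focal drug.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w_drug, w_disease, w_protein` | 3.21, 3.54, 4.40 | type weights (dimensionless, only ratios matter) |
| `w_biological_function` | 6.58 | weight of function neighbors seen from a protein |
| `w_higher/lower_level_function` | 2.10, 4.49 | hierarchy-direction weights at a function node |
| `alpha` | 0.860 | probability of continuing the walk at each step |
| `tolerance` | 1e-6 | L1 convergence threshold of power iteration |
| `max_iter` | 10 000 | iteration cap guarding non-convergence |

The default weights are the published optima of the cross-validated sweep on
the full network; the molecular-scale (function-ablated) defaults are
`w_drug = 4.88, w_disease = 6.83, w_protein = 3.21, alpha = 0.854`. The sweep
convention ties `w_biological_function = w_higher + w_lower`; the constraint
is checked to printed precision (±0.011) because the published optima are
rounded to two decimals and their sum is off by one ulp of the print.

The sweep helper builds evenly spaced per-axis grids over the documented
ranges (`w_drug, w_disease, w_protein ∈ [3, 9]`, hierarchy weights
∈ [1.5, 4.5], `alpha ∈ [0.85, 0.9]`), crosses them, and sub-samples the
cross-product to the requested budget with a seeded uniform draw; the exact
per-axis resolution behind the historical 486-point budget is not
recoverable, so only the ranges and the budget are reproduced. Selection
maximizes the median training AUROC averaged across folds.

## Numerical choices

* Power iteration starts from the uniform vector `1/|V|`, converges in L1,
  and asserts mass conservation (|Σr − 1| < 1e-9) at every iterate.
* The fixed point is exactly zero on nodes unreachable from the focal node,
  but iteration from the uniform start leaves decaying numerical dust there;
  profiles are therefore masked to the reachable set after convergence. The
  dense test oracle (sink rows replaced by the restart vector, then a direct
  linear solve; guarded to ≤ 2000 nodes) applies the same mask.
* An isolated focal node returns the restart vector with a warning rather
  than failing; the iteration cap raises a convergence error that reports
  the residual.
* Ranking ties break lexicographically by drug id, making rankings
  deterministic. AUROC uses mid-rank tie handling (scikit-learn); Recall@50
  keeps the fixed cutoff of 50 regardless of candidate-list size (with
  fewer than 50 candidates it degenerates to recall over the whole list).
* Distances (L1, L2, Canberra, correlation) are negated so larger is always
  "more treatment-like". Canberra defines 0/0 terms as 0. A zero-variance
  profile under the correlation metric is assigned the maximal distance 2
  (score −2) with a logged warning.
* During cross-validation the candidate set for each disease is the
  evaluated fold's drugs only (held-out) or the remaining drugs (training);
  diseases without both a positive and a negative candidate are skipped per
  fold, and folds with no evaluable disease are excluded from the summary
  with a warning.
* Information content uses the natural logarithm; the base only rescales
  Resnik values and cancels inside the simIC and simGIC ratios. `p(u)` is
  the fraction of *annotated* proteins associated with `u` or its
  descendants, so any term that subsumes all annotations has `p = 1` and
  `IC = 0`. Terms with no common informative ancestor get similarity 0.
* Degree-matched permutation nulls use log2-spaced degree bins merged
  upward until each holds at least `min_bin_size` nodes (default 100, the
  standard construction for this proximity-metric family); sets are resampled
  node-by-node within bins, without replacement inside a set. A graph with
  fewer proteins than the bin floor raises an error suggesting a smaller
  floor. Degenerate nulls (zero standard deviation) are flagged and z is
  undefined.
* Unreachable target–disease-protein pairs are dropped from the closest-
  distance average with a warning; an infinite sentinel would poison means.
* Enrichment-derived term sets use a one-sided hypergeometric
  over-representation test against the annotated-protein background with
  Benjamini–Hochberg control at FDR < 0.05.
* The treatment-importance percentile of a gene is computed against the
  *other* protein nodes of the same (drug, disease) context with mid-rank
  tie handling, so the unique maximum has percentile 1.0 and the unique
  minimum 0.0. The alteration fraction uses a strict inequality: ties are
  not successes.
* Function pruning keeps exactly the functions annotated — directly or
  through any hierarchy descendant — to at least one drug target or disease
  protein; it requires an acyclic hierarchy and is idempotent. Because
  released hierarchy files may already reflect this rule, pruning is an
  explicit optional step, not part of loading.

## Functional-overlap baseline enumeration

Seventeen named baselines are exposed: Jaccard and intersection over term
sets with descendant closure, term multisets, and enrichment-derived sets
(6), z-scored variants of the set and multiset forms (4; enrichment is not
z-scored, as re-running the FDR-controlled test inside every permutation
draw composes two testing procedures), Resnik and simIC each under average,
max, and best-match-average aggregation (6), and simGIC (1). Semantic
similarities operate on directly annotated terms; set/multiset overlaps use
descendant closure.

## Synthetic generator

The generator emulates the statistical structure the method assumes rather
than any real dataset: a modular PPI layer (Chung–Lu wiring inside blocks
with heavy-tailed stub weights, so degree-matched nulls are exercised
nontrivially, plus a spanning ring per block and sparse inter-block edges
for connectivity), one function tree per module under a shared root with
occasional cross-links (making the hierarchy a DAG, not a forest), diseases
attached to random proteins of one module, and drugs treating their
module's diseases by one of two planted routes. Molecular-route drugs
target proteins inside the module's disease-protein set. Functional-route
drugs target proteins of a separate reservoir block that no disease
touches, and those targets are annotated into the treated module's function
subtree — so the treatment signal flows only through function nodes and
vanishes when the function layer is removed. Placing functional targets
inside the disease's own PPI module would leave the signal molecularly
recoverable and defeat the ablation contrast the fixture exists to test.

Defaults: 4 modules × 25 proteins plus a reservoir block, 24 drugs (half
functional-route), 8 diseases (8 proteins each), 7 functions per module at
hierarchy depth 3, `p_in = 0.12`, `p_out = 0.004`, 3 targets per drug.
These sizes let the full pipeline (all profiles, two cross-validations,
PGx classification, concordance) complete in seconds on one CPU while
leaving enough candidates per fold for stable ranking metrics.

Treatment-altering genes are planted on proteins that are both a drug
target and a disease protein (high visitation in both profiles); negatives
are sampled uniformly. Expression signatures are standardized ranks of the
drug's protein-restricted diffusion profile plus Gaussian noise
(sd 0.75), with identical cell-line/dose/time metadata so all drug pairs
are comparable.

What the fixture does **not** emulate: the real network's degree sequence
and size (two orders of magnitude larger), realistic Gene Ontology
topology, annotation sparsity, correlated disease modules, or noisy
treatment labels. Passing the planted-signal tests shows the pipeline
recovers structure it is designed for; it does not certify performance
levels on real data, where the full released network and profiles are
required.

## Limitations

* Exact solvers are deliberately capped at small graphs; full-network
  profiles go through sparse power iteration only.
* Genes are identified with their protein nodes; no isoform handling.
* Raw-source curation (DrugBank/DisGeNet parsing, infectious-disease
  filtering, expression-signature quality control) is upstream of this
  package: loaders consume already-harmonized TSV tables.
* The loader-count and case-study checks against the released full-network
  tables require those published files to be placed under `data/released/`;
  they are not redistributable with the package.
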