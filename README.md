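# msinet

Network medicine tooling for modeling **how drugs treat diseases through both
proteins and biological functions**, aimed at computational biologists working
on drug repurposing, treatment explanation, and pharmacogenomics.

Classical interactome approaches assume a drug treats a disease only when its
target proteins are close to the disease-perturbed proteins in the
protein–protein interaction (PPI) network. That misses treatments that work at
a higher level of organization: a drug can bind proteins *distant* from the
disease proteins yet restore the same biological functions. `msinet`
implements the multiscale approach: a heterogeneous network of drugs,
diseases, proteins, and a Gene Ontology-style hierarchy of biological
functions, analyzed through **diffusion profiles**.

## The model

For a focal drug or disease, the graph `G = (V, E)` is turned into a directed
view `G'` where the focal node is a source and every other drug/disease is a
sink (drugs and diseases never act as walk intermediates). A walker at node
`i` continues its walk with probability `α` and restarts at the focal node
with probability `1 − α`. When continuing, it first picks a neighbor *type*
`t ∈ T` (the node kinds adjacent to `i`) and then a uniform neighbor of that
type:

    p_t  = w_t / Σ_{t'∈T} w_{t'}          M_ij = p_t / n_t

with separate weights for drugs, diseases, proteins, biological functions,
and higher-/lower-level functions along the hierarchy. The diffusion profile
`r` is the fixed point of

    r^(k+1) = (1−α)·s + α·( r^(k) M  +  s · Σ_{j∈J} r_j^(k) )

iterated from `r⁰ = 1/|V|` until the L1 change is below `ε` (default `1e-6`),
where `s` is the one-hot restart vector and `J` the sink set. `r` sums to 1
and measures how often each node is visited.

On top of the profiles the package provides:

* **treatment prediction** — rank drugs for a disease by profile similarity
  (L1/L2/Canberra/correlation distances, cosine, and two proximity readouts),
  scored per disease by AUROC / average precision / Recall@50 under drug-level
  five-fold cross-validation, plus the hyperparameter sweep;
* **baselines** — target/disease-protein Jaccard overlap, PPI proximity
  z-scored against degree-matched permutation nulls, and seventeen
  functional-overlap variants (set/multiset/enrichment overlaps, Resnik,
  simIC, simGIC with average/max/best-match-average aggregation);
* **explanation** — the induced subgraph on the top-k most-visited nodes of a
  drug and disease profile, exportable to GraphML;
* **pharmacogenomics** — the treatment importance of a gene,
  `TI(i|c,d) = r_i^(c) · r_i^(d)`, its percentile, classification of
  treatment-altering gene triplets, and drug-pair alteration fractions;
* **validation** — Spearman concordance between profile similarity and
  gene-expression-signature similarity;
* **synthetic data** — a generator of miniature multiscale interactomes with
  planted molecular-route and functional-route treatments, so every stage is
  testable without downloads.

## Worked example

```python
import msinet as ms

data = ms.default_fixture(seed=0)            # planted synthetic interactome
print(data.graph)

_, summary = ms.five_fold_cv(
    data.treatments, data.graph, ms.OPTIMAL_MULTISCALE, "correlation", seed=42)
print({k: round(v, 3) for k, v in summary.items()})

drug, disease = sorted(data.treatments.pairs)[0]
cache = ms.ProfileCache()
rc = cache.get(data.graph, ms.OPTIMAL_MULTISCALE, drug)
rd = cache.get(data.graph, ms.OPTIMAL_MULTISCALE, disease)
sub = ms.top_k_subgraph(rc, rd, data.graph, k=10)
print(f"explanation subgraph for ({drug}, {disease}): "
      f"{sub.graph.number_of_nodes()} nodes, {sub.graph.number_of_edges()} edges; "
      f"mass covered (drug, disease) = ({sub.mass_share[0]:.2f}, {sub.mass_share[1]:.2f})")
```

prints

```
MultiscaleGraph({'biological_function': 29, 'disease': 8, 'drug': 24, 'protein': 144}, n_edges=838)
{'median_auroc': 1.0, 'mean_average_precision': 1.0, 'mean_recall_at_50': 1.0}
explanation subgraph for (DB0000, C0000): 13 nodes, 23 edges; mass covered (drug, disease) = (0.64, 0.52)
```

The held-out median AUROC of 1.0 says every approved drug of the planted
fixture out-ranks the non-treating candidates for its disease; the subgraph
line says the ten most-visited nodes of each profile capture 64% and 52% of
the drug's and disease's total visitation mass — the compact mechanistic
explanation of the treatment. On the same fixture the function-ablated
(molecular-scale) configuration reaches a held-out median AUROC of only
~0.58–0.86 depending on the seed, because the drugs planted on the functional
route are invisible on the protein layer alone.

A command-line interface mirrors the library (`msinet build / diffuse /
predict / evaluate / sweep / baseline / explain / pgx / concordance / synth`);
run `msinet --help`.

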