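"""Comparison baselines: protein overlap, network proximity, functional overlap.

Three families of baselines rank drugs for a disease from the drug-target
set T and disease-protein set S alone:

* protein overlap — the Jaccard similarity |T ∩ S| / |T ∪ S|;
* network proximity — the mean over targets of the shortest-path distance
  to the nearest disease protein on the protein–protein layer, z-scored
  against 1000 degree- and size-matched random sets (lower z = closer than
  expected = more treatment-like);
* functional overlap — overlaps and semantic similarities between the Gene
  Ontology term collections of T and S: raw and z-scored Jaccard /
  intersection over sets, multisets, and enrichment-derived sets, plus
  Resnik, simIC (each aggregated by average / max / best-match-average) and
  simGIC, built on information content IC(u) = -ln p(u) where p(u) is the
  fraction of annotated proteins associated with term u or its descendants.

A separate analysis z-scores the PPI distance of protein pairs that share a
directly annotated function against degree-matched random pairs, asking
whether functionally related proteins can be topologically distant.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .graph import FUNCTION, PROTEIN, MultiscaleGraph, ancestors_of, topological_order

logger = logging.getLogger("msinet")


# -- PPI layer ----------------------------------------------------------------


class PPILayer:
    """Protein–protein layer with cached unweighted shortest-path distances.

    Distances are defined on the molecular-scale interactome only; the full
    matrix is precomputed by BFS (guarded to graphs small enough for a dense
    |P| x |P| array) and shared across permutation draws.
    """

    def __init__(self, graph: MultiscaleGraph, max_dense: int = 5000):
        self.proteins = graph.nodes_of_kind(PROTEIN)
        self.pos = {p: i for i, p in enumerate(self.proteins)}
        n = len(self.proteins)
        if n > max_dense:
            raise ValueError(f"PPI layer too large for dense distances ({n} > {max_dense})")
        rows, cols = [], []
        for u, v in graph.edges:
            if graph.kinds[u] == PROTEIN and graph.kinds[v] == PROTEIN:
                rows += [self.pos[u], self.pos[v]]
                cols += [self.pos[v], self.pos[u]]
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        self.dist = shortest_path(adj, method="D", unweighted=True, directed=False)
        self.degree = np.asarray(adj.sum(axis=1)).ravel().astype(int)

    def distance(self, u: str, v: str) -> float:
        return float(self.dist[self.pos[u], self.pos[v]])


def protein_overlap(targets: set[str], disease_proteins: set[str]) -> float:
    """Jaccard similarity between the drug-target and disease-protein sets."""
    if not targets or not disease_proteins:
        raise ValueError("protein_overlap requires nonempty sets")
    return len(targets & disease_proteins) / len(targets | disease_proteins)


def closest_distance(
    disease_proteins: set[str], targets: set[str], ppi: PPILayer
) -> float:
    """Mean over targets of the minimum PPI distance to any disease protein.

    Target/disease pairs with no connecting path are dropped from the
    average with a warning (an infinite sentinel would poison the mean).
    """
    if not targets:
        raise ValueError("closest_distance requires a nonempty target set")
    s_idx = np.array([ppi.pos[s] for s in disease_proteins])
    contributions = []
    for t in targets:
        d = ppi.dist[ppi.pos[t], s_idx].min()
        if math.isinf(d):
            logger.warning("target %r unreachable from disease proteins; excluded", t)
            continue
        contributions.append(d)
    if not contributions:
        raise ValueError("no target reaches any disease protein")
    return float(np.mean(contributions))


# -- degree-matched permutation nulls ----------------------------------------


def _degree_bins(ppi: PPILayer, min_bin_size: int = 100) -> dict[int, np.ndarray]:
    """log2-spaced degree bins, merged upward until each holds >= min_bin_size.

    Returns a map node-position -> array of candidate node positions sharing
    the node's (merged) bin.
    """
    n = len(ppi.proteins)
    if n < min_bin_size:
        raise ValueError(
            f"graph has only {n} proteins; degree-bin floor {min_bin_size} is "
            f"unattainable — pass a smaller min_bin_size"
        )
    raw_bin = np.floor(np.log2(np.maximum(ppi.degree, 1))).astype(int)
    order = sorted(set(raw_bin))
    # merge small bins upward (into the next-higher-degree bin)
    merged: dict[int, int] = {}
    pending: list[int] = []
    for b in order:
        pending.append(b)
        if sum((raw_bin == x).sum() for x in pending) >= min_bin_size:
            for x in pending:
                merged[x] = b
            pending = []
    if pending:  # leftover small top bins fold into the last complete one
        target = max(merged.values()) if merged else pending[-1]
        for x in pending:
            merged[x] = target
    eff_bin = np.array([merged[b] for b in raw_bin])
    members = {b: np.where(eff_bin == b)[0] for b in set(eff_bin)}
    return {i: members[eff_bin[i]] for i in range(n)}


def degree_matched_sample(
    nodes: set[str],
    ppi: PPILayer,
    n_perm: int,
    seed: int,
    min_bin_size: int = 100,
) -> list[set[str]]:
    """n_perm random node sets matching the size and binned degrees of ``nodes``.

    Each original node is replaced by a uniform draw from its degree bin;
    draws within one set are without replacement so cardinality is preserved.
    """
    bins = _degree_bins(ppi, min_bin_size)
    rng = np.random.default_rng(seed)
    positions = [ppi.pos[v] for v in sorted(nodes)]
    samples = []
    for _ in range(n_perm):
        chosen: set[int] = set()
        for p in positions:
            pool = bins[p]
            pick = int(pool[rng.integers(len(pool))])
            while pick in chosen:
                pick = int(pool[rng.integers(len(pool))])
            chosen.add(pick)
        samples.append({ppi.proteins[i] for i in chosen})
    return samples


@dataclass
class PermutationNull:
    """Observed statistic vs a permutation reference distribution."""

    observed: float
    null: np.ndarray
    seed: int
    degenerate: bool = False

    @property
    def z(self) -> float:
        sd = float(self.null.std(ddof=0))
        if sd == 0:
            raise ValueError("degenerate null (sd = 0); z undefined")
        return (self.observed - float(self.null.mean())) / sd


def proximity_zscore(
    disease_proteins: set[str],
    targets: set[str],
    ppi: PPILayer,
    n_perm: int = 1000,
    seed: int = 0,
    min_bin_size: int = 100,
) -> PermutationNull:
    """z-score of the closest distance d(S, T) against degree-matched nulls.

    Both the disease-protein and target sets are permuted.  For ranking,
    negate the z (more negative = closer than chance = more treatment-like).
    """
    if n_perm < 2:
        raise ValueError("proximity_zscore needs n_perm >= 2 (sd undefined otherwise)")
    observed = closest_distance(disease_proteins, targets, ppi)
    s_perms = degree_matched_sample(disease_proteins, ppi, n_perm, seed, min_bin_size)
    t_perms = degree_matched_sample(targets, ppi, n_perm, seed + 1, min_bin_size)
    null = np.array([closest_distance(s, t, ppi) for s, t in zip(s_perms, t_perms)])
    result = PermutationNull(observed=observed, null=null, seed=seed)
    if null.std() == 0:
        result.degenerate = True
        logger.warning("proximity null is degenerate (sd = 0)")
    return result


def shared_function_distance_zscore(
    pair: tuple[str, str],
    ppi: PPILayer,
    n_perm: int = 1000,
    seed: int = 0,
    min_bin_size: int = 100,
) -> PermutationNull:
    """z-score of a protein pair's PPI distance vs degree-matched random pairs.

    Intended for pairs sharing a *directly* annotated function (annotations
    are not propagated up the hierarchy, so shared functions stay specific).
    Disconnected observed pairs are rejected; disconnected null draws are
    excluded.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    u, v = pair
    observed = ppi.distance(u, v)
    if math.isinf(observed):
        raise ValueError(f"pair ({u!r}, {v!r}) is disconnected in the PPI layer")
    bins = _degree_bins(ppi, min_bin_size)
    rng = np.random.default_rng(seed)
    null = []
    pu, pv = ppi.pos[u], ppi.pos[v]
    while len(null) < n_perm:
        a = int(bins[pu][rng.integers(len(bins[pu]))])
        b = int(bins[pv][rng.integers(len(bins[pv]))])
        if a == b:
            continue
        d = ppi.dist[a, b]
        if math.isinf(d):
            continue
        null.append(d)
    return PermutationNull(observed=observed, null=np.array(null), seed=seed)


# -- annotation corpus & functional overlap ----------------------------------


class AnnotationCorpus:
    """Protein -> GO-term annotations over the function hierarchy.

    ``p(u)`` is the fraction of annotated proteins associated with term u or
    any of its descendants; the information content is IC(u) = -ln p(u)
    (base only rescales Resnik and cancels in the simIC/simGIC ratios).
    """

    def __init__(self, graph: MultiscaleGraph):
        self.graph = graph
        topological_order(graph)  # rejects cyclic hierarchies up front
        adj = graph.adjacency
        self.annotations: dict[str, set[str]] = {}
        for f in graph.nodes_of_kind(FUNCTION):
            for v in adj[f]:
                if graph.kinds[v] == PROTEIN:
                    self.annotations.setdefault(v, set()).add(f)
        self.background = sorted(self.annotations)
        # proteins associated with each term directly or via descendants:
        # propagate each protein's annotations to all ancestors
        self._term_proteins: dict[str, set[str]] = {}
        for protein, terms in self.annotations.items():
            for t in ancestors_of(graph, terms):
                self._term_proteins.setdefault(t, set()).add(protein)

    def term_protein_count(self, term: str) -> int:
        return len(self._term_proteins.get(term, ()))

    def p(self, term: str) -> float:
        return self.term_protein_count(term) / len(self.background)

    def ic(self, term: str) -> float:
        p = self.p(term)
        if p == 0:
            raise ValueError(f"term {term!r} has no annotated proteins; IC undefined")
        return -math.log(p)

    def ancestors(self, term: str) -> set[str]:
        """Term plus all its ancestors."""
        return ancestors_of(self.graph, [term])

    def direct_terms(self, proteins: set[str]) -> set[str]:
        out: set[str] = set()
        for p in proteins:
            out |= self.annotations.get(p, set())
        return out


def term_sets(
    proteins: set[str],
    corpus: AnnotationCorpus,
    mode: str = "set_with_descendant_closure",
    fdr: float = 0.05,
):
    """GO-term collection for a protein set, in one of four modes.

    * ``set_with_descendant_closure`` — terms a protein is associated with
      directly or through descendant terms (i.e. direct terms plus ancestors);
    * ``direct_set`` — directly annotated terms only (semantic similarity);
    * ``multiset`` — per-term counts of associated proteins (with closure);
    * ``enriched`` — terms over-represented in the set vs the annotated
      background (one-sided hypergeometric, Benjamini–Hochberg FDR < 0.05).
    """
    annotated = [p for p in proteins if p in corpus.annotations]
    if not annotated:
        logger.warning("no annotated proteins in query set")
        return {} if mode == "multiset" else set()
    if mode == "direct_set":
        return corpus.direct_terms(set(annotated))
    if mode in ("set_with_descendant_closure", "multiset"):
        counts: dict[str, int] = {}
        for p in annotated:
            for t in ancestors_of(corpus.graph, corpus.annotations[p]):
                counts[t] = counts.get(t, 0) + 1
        return counts if mode == "multiset" else set(counts)
    if mode == "enriched":
        n_bg = len(corpus.background)
        n_query = len(annotated)
        query_terms = sorted(
            {t for p in annotated for t in ancestors_of(corpus.graph, corpus.annotations[p])}
        )
        pvals = []
        for t in query_terms:
            term_prots = corpus._term_proteins[t]
            k = len(term_prots.intersection(annotated))
            pvals.append(hypergeom.sf(k - 1, n_bg, len(term_prots), n_query))
        reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        return {t for t, r in zip(query_terms, reject) if r}
    raise ValueError(f"unknown term_sets mode {mode!r}")


def term_overlap(u_like, v_like, statistic: str = "jaccard") -> float:
    """Jaccard or intersection between term sets or multisets.

    Multisets are dicts term -> count; the multiset Jaccard is
    sum_i min(U'_i, V'_i) / sum_i max(U'_i, V'_i).
    """
    if not u_like and not v_like:
        raise ValueError("both term collections are empty; overlap undefined")
    if isinstance(u_like, dict) or isinstance(v_like, dict):
        u = dict(u_like) if not isinstance(u_like, dict) else u_like
        v = dict(v_like) if not isinstance(v_like, dict) else v_like
        keys = set(u) | set(v)
        mins = sum(min(u.get(k, 0), v.get(k, 0)) for k in keys)
        maxs = sum(max(u.get(k, 0), v.get(k, 0)) for k in keys)
        if statistic == "intersection":
            return float(mins)
        if maxs == 0:
            raise ValueError("both multisets are empty; overlap undefined")
        return mins / maxs
    u, v = set(u_like), set(v_like)
    if statistic == "jaccard":
        return len(u & v) / len(u | v)
    if statistic == "intersection":
        return float(len(u & v))
    raise ValueError(f"unknown overlap statistic {statistic!r}")


def zscored_term_overlap(
    targets: set[str],
    disease_proteins: set[str],
    corpus: AnnotationCorpus,
    ppi: PPILayer,
    mode: str = "set_with_descendant_closure",
    statistic: str = "jaccard",
    n_perm: int = 1000,
    seed: int = 0,
    min_bin_size: int = 100,
) -> PermutationNull:
    """Term overlap z-scored against degree-matched permutations of both sets."""
    observed = term_overlap(
        term_sets(targets, corpus, mode), term_sets(disease_proteins, corpus, mode), statistic
    )
    t_perms = degree_matched_sample(targets, ppi, n_perm, seed, min_bin_size)
    s_perms = degree_matched_sample(disease_proteins, ppi, n_perm, seed + 1, min_bin_size)
    null = []
    for t_set, s_set in zip(t_perms, s_perms):
        ut, vs = term_sets(t_set, corpus, mode), term_sets(s_set, corpus, mode)
        null.append(term_overlap(ut, vs, statistic) if (ut or vs) else 0.0)
    result = PermutationNull(observed=observed, null=np.array(null), seed=seed)
    if result.null.std() == 0:
        result.degenerate = True
    return result


# -- semantic similarity ------------------------------------------------------


def mica(u: str, v: str, corpus: AnnotationCorpus) -> str | None:
    """Most informative common ancestor (terms count as their own ancestors)."""
    common = corpus.ancestors(u) & corpus.ancestors(v)
    common = {x for x in common if corpus.term_protein_count(x) > 0}
    if not common:
        return None
    return max(common, key=lambda x: (corpus.ic(x), x))


def semantic_similarity(u: str, v: str, corpus: AnnotationCorpus, kind: str = "resnik") -> float:
    """Resnik or simIC similarity between two terms.

    Terms with no common ancestor have similarity 0 by convention.
    """
    anc = mica(u, v, corpus)
    if anc is None:
        return 0.0
    ic_mica = corpus.ic(anc)
    if kind == "resnik":
        return ic_mica
    if kind == "sim_ic":
        log_pu, log_pv = math.log(corpus.p(u)), math.log(corpus.p(v))
        if log_pu + log_pv == 0:  # both terms cover the whole background
            return 0.0
        lin = 2.0 * math.log(corpus.p(anc)) / (log_pu + log_pv)
        return lin * (1.0 - 1.0 / (1.0 + ic_mica))
    raise ValueError(f"unknown semantic similarity kind {kind!r}")


def sim_gic(u_terms: set[str], v_terms: set[str], corpus: AnnotationCorpus) -> float:
    """Graph IC similarity over the ancestor closures A(U), A(V)."""
    if not u_terms or not v_terms:
        raise ValueError("sim_gic requires nonempty term sets")
    au = {t for t in ancestors_of(corpus.graph, u_terms) if corpus.term_protein_count(t) > 0}
    av = {t for t in ancestors_of(corpus.graph, v_terms) if corpus.term_protein_count(t) > 0}
    denom = sum(corpus.ic(t) for t in au | av)
    if denom == 0:
        return 1.0  # closures consist solely of universal terms
    return sum(corpus.ic(t) for t in au & av) / denom


def aggregate_similarity(
    u_terms: set[str],
    v_terms: set[str],
    corpus: AnnotationCorpus,
    kind: str = "resnik",
    mode: str = "best_match_average",
) -> float:
    """Aggregate pairwise term similarity over U x V.

    Modes: ``average`` (grand mean), ``max``, and ``best_match_average``
    (mean of per-term best matches in both directions).
    """
    if not u_terms or not v_terms:
        raise ValueError("aggregate_similarity requires nonempty term sets")
    sim = {
        (u, v): semantic_similarity(u, v, corpus, kind)
        for u, v in itertools.product(sorted(u_terms), sorted(v_terms))
    }
    vals = list(sim.values())
    if mode == "average":
        return float(np.mean(vals))
    if mode == "max":
        return float(max(vals))
    if mode == "best_match_average":
        u_best = [max(sim[(u, v)] for v in v_terms) for u in u_terms]
        v_best = [max(sim[(u, v)] for u in u_terms) for v in v_terms]
        return float((sum(u_best) + sum(v_best)) / (len(u_terms) + len(v_terms)))
    raise ValueError(f"unknown aggregation mode {mode!r}")


# -- baseline enumeration -----------------------------------------------------

#: every functional-overlap baseline reachable by name: overlap statistics
#: over sets / multisets / enriched sets, raw and z-scored, plus the
#: semantic-similarity family.
FUNCTIONAL_BASELINES: tuple[str, ...] = tuple(
    [
        f"{stat}_{mode}{suffix}"
        for stat in ("jaccard", "intersection")
        for mode in ("set", "multiset", "enriched")
        for suffix in ("", "_zscored")
        if not (mode == "enriched" and suffix == "_zscored")
    ]
    + [f"resnik_{agg}" for agg in ("average", "max", "best_match_average")]
    + [f"sim_ic_{agg}" for agg in ("average", "max", "best_match_average")]
    + ["sim_gic"]
)


def functional_baseline(
    name: str,
    targets: set[str],
    disease_proteins: set[str],
    corpus: AnnotationCorpus,
    ppi: PPILayer | None = None,
    n_perm: int = 100,
    seed: int = 0,
    min_bin_size: int = 100,
) -> float:
    """Evaluate one named functional-overlap baseline (higher = more similar).

    For z-scored overlaps the z itself is returned: higher observed overlap
    gives a higher z, so the common larger-is-better convention holds.
    """
    if name == "sim_gic":
        return sim_gic(
            term_sets(targets, corpus, "direct_set"),
            term_sets(disease_proteins, corpus, "direct_set"),
            corpus,
        )
    for kind in ("resnik", "sim_ic"):
        if name.startswith(kind + "_"):
            return aggregate_similarity(
                term_sets(targets, corpus, "direct_set"),
                term_sets(disease_proteins, corpus, "direct_set"),
                corpus,
                kind=kind,
                mode=name[len(kind) + 1 :],
            )
    stat, rest = name.split("_", 1)
    zscored = rest.endswith("_zscored")
    mode = rest.removesuffix("_zscored")
    mode_full = {"set": "set_with_descendant_closure", "multiset": "multiset",
                 "enriched": "enriched"}[mode]
    if zscored:
        if ppi is None:
            raise ValueError("z-scored baselines need the PPI layer")
        return zscored_term_overlap(
            targets, disease_proteins, corpus, ppi, mode_full, stat, n_perm, seed, min_bin_size
        ).z
    return term_overlap(
        term_sets(targets, corpus, mode_full),
        term_sets(disease_proteins, corpus, mode_full),
        stat,
    )
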