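"""Treatment explanation subgraphs, gene treatment importance, pharmacogenomics.

The diffusion profiles of an approved drug–disease pair do more than score
the pair: the most-visited nodes name the proteins and biological functions
the treatment acts through.  Inducing a subgraph on the top-k nodes of both
profiles gives a compact mechanistic explanation; the product of a gene's
visitation frequencies in the two profiles — its treatment importance
TI(i|c,d) = r_i^(c) * r_i^(d) — prioritizes genes whose variants may alter
drug efficacy or cause adverse reactions for that particular treatment.

Drug diffusion profiles are validated externally against gene-expression
signatures: drugs whose profiles are similar (negative Canberra distance on
rank-transformed profiles) should also have overlapping sets of most up-
and down-regulated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

from .diffusion import DiffusionProfile
from .graph import PROTEIN, MultiscaleGraph, PGxTriplet, TreatmentDataset

logger = logging.getLogger("msinet")


# -- explanation subgraphs ----------------------------------------------------


@dataclass
class ExplanationSubgraph:
    """Induced subgraph on the top-k nodes of a drug and a disease profile."""

    graph: nx.Graph
    drug: str
    disease: str
    k: int
    #: share of total visitation mass (drug, disease) covered by the top-k
    #: node selection, before isolated-component removal
    mass_share: tuple[float, float] = (0.0, 0.0)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def top_k_subgraph(
    rc: DiffusionProfile, rd: DiffusionProfile, graph: MultiscaleGraph, k: int
) -> ExplanationSubgraph:
    """Union of each profile's k most-visited nodes, induced and cleaned.

    The two focal nodes are always included; ties are broken by
    (frequency, node id); isolated nodes (degree 0 in the induced subgraph)
    are removed, except the focal nodes themselves.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(rc.index)
    if k > n:
        logger.warning("k=%d exceeds node count %d; clipped", k, n)
        k = n
    selected: set[str] = {rc.focal, rd.focal}
    mass = []
    for prof in (rc, rd):
        top = [node for node, _ in prof.top(k)]
        mass.append(float(sum(prof[t] for t in top)))
        selected.update(top)

    g = nx.Graph()
    for node in selected:
        g.add_node(
            node,
            kind=graph.kinds[node],
            rc=rc[node],
            rd=rd[node],
            name=graph.names.get(node, node),
        )
    for u, v in graph.edges:
        if u in selected and v in selected:
            g.add_edge(u, v)
    isolated = [x for x in g.nodes if g.degree(x) == 0 and x not in (rc.focal, rd.focal)]
    g.remove_nodes_from(isolated)
    return ExplanationSubgraph(
        graph=g, drug=rc.focal, disease=rd.focal, k=k, mass_share=(mass[0], mass[1])
    )


# -- treatment importance -----------------------------------------------------


@dataclass(frozen=True)
class TreatmentImportance:
    gene: str
    drug: str
    disease: str
    ti: float
    percentile: float


def treatment_importance(
    rc: DiffusionProfile, rd: DiffusionProfile, gene: str, graph: MultiscaleGraph
) -> TreatmentImportance:
    """TI(i|c,d) = r_i^(c) * r_i^(d), with its percentile among all genes.

    The percentile of gene i is computed against the other protein nodes of
    the same (drug, disease) context with the mid-rank convention: the
    fraction of other genes with strictly smaller TI plus half of those
    tied, so the unique maximum has percentile 1.0 and the unique minimum 0.
    """
    if graph.kinds.get(gene) != PROTEIN:
        raise KeyError(f"gene {gene!r} does not resolve to a protein node in the graph")
    proteins = graph.nodes_of_kind(PROTEIN)
    ti_all = np.array([rc[p] * rd[p] for p in proteins])
    idx = proteins.index(gene)
    others = np.delete(ti_all, idx)
    ti = float(ti_all[idx])
    if len(others) == 0:
        pct = 1.0
    else:
        pct = float(((others < ti).sum() + 0.5 * (others == ti).sum()) / len(others))
    return TreatmentImportance(gene=gene, drug=rc.focal, disease=rd.focal, ti=ti, percentile=pct)


def sample_negative_triplets(
    dataset: TreatmentDataset,
    positives: list[PGxTriplet],
    genes: list[str],
    n: int,
    seed: int,
    max_tries: int = 100_000,
) -> list[PGxTriplet]:
    """n random (drug, disease, gene) triplets not known to alter treatment.

    Drugs and diseases are drawn uniformly from the approved pairs and genes
    uniformly from the protein universe, rejecting collisions with the
    positive set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pos = {(t.drug, t.disease, t.gene) for t in positives}
    pairs = sorted(dataset.pairs)
    out: list[PGxTriplet] = []
    seen: set[tuple[str, str, str]] = set()
    for _ in range(max_tries):
        if len(out) == n:
            return out
        c, d = pairs[rng.integers(len(pairs))]
        g = genes[rng.integers(len(genes))]
        key = (c, d, g)
        if key in pos or key in seen:
            continue
        seen.add(key)
        out.append(PGxTriplet(c, d, g))
    raise ValueError(f"could not sample {n} negative triplets (got {len(out)})")


def classify_treatment_altering(
    positives: list[PGxTriplet],
    negatives: list[PGxTriplet],
    profiles: dict[str, DiffusionProfile],
    graph: MultiscaleGraph,
) -> dict[str, float]:
    """Score treatment-altering vs other triplets by TI; AUROC and AP."""
    if not positives or not negatives:
        raise ValueError("both triplet classes must be nonempty")
    scores, labels = [], []
    for label, triplets in ((1, positives), (0, negatives)):
        for t in triplets:
            ti = treatment_importance(profiles[t.drug], profiles[t.disease], t.gene, graph)
            scores.append(ti.ti)
            labels.append(label)
    scores, labels = np.array(scores), np.array(labels)
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "average_precision": float(average_precision_score(labels, scores)),
        "n_positive": int(labels.sum()),
        "n_negative": int(len(labels) - labels.sum()),
    }


def altered_fraction(
    gene: str,
    triplets: list[tuple[str, str, str]],
    profiles: dict[str, DiffusionProfile],
    graph: MultiscaleGraph,
    min_triplets: int = 100,
) -> float | None:
    """Fraction of (disease, altered drug, unaltered drug) triplets in which
    the gene's TI is strictly greater under the altered drug.

    Ties are not successes.  Genes with fewer than ``min_triplets`` triplets
    are excluded (returns None).
    """
    if not triplets:
        raise ValueError(f"no triplets for gene {gene!r}")
    if len(triplets) < min_triplets:
        return None
    wins = 0
    for disease, c_alt, c_unalt in triplets:
        ti_alt = treatment_importance(profiles[c_alt], profiles[disease], gene, graph).ti
        ti_un = treatment_importance(profiles[c_unalt], profiles[disease], gene, graph).ti
        wins += ti_alt > ti_un
    return wins / len(triplets)


# -- expression-signature concordance ----------------------------------------


@dataclass(frozen=True)
class ExpressionSignature:
    """Per-gene z-scored expression changes for one drug.

    ``metadata`` (cell line, dose, exposure time) must match between two
    signatures for them to be comparable.
    """

    drug: str
    genes: tuple[str, ...]
    values: tuple[float, ...]
    metadata: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene ids must be unique")
        if len(self.genes) < 50:
            raise ValueError("signature needs >= 50 genes for top/bottom-25 extraction")

    def extremes(self, n: int = 25) -> tuple[set[str], set[str]]:
        order = np.argsort(np.array(self.values), kind="stable")
        genes = np.array(self.genes)
        return set(genes[order[-n:]]), set(genes[order[:n]])  # (up, down)


def signature_similarity(sig1: ExpressionSignature, sig2: ExpressionSignature) -> float:
    """Mean Jaccard overlap of the 25 most up- and down-regulated gene sets."""
    if sig1.metadata != sig2.metadata:
        raise ValueError("signatures are not comparable (metadata differs)")
    u1, d1 = sig1.extremes()
    u2, d2 = sig2.extremes()
    return 0.5 * (len(u1 & u2) / len(u1 | u2) + len(d1 & d2) / len(d1 | d2))


def profile_expression_concordance(
    profiles: dict[str, DiffusionProfile],
    signatures: dict[str, ExpressionSignature],
) -> dict[str, float]:
    """Spearman correlation between profile and signature drug–drug similarity.

    Profile similarity is the rank-transformed Canberra distance times -1;
    signature similarity is the top/bottom-25 overlap.  Pairs with
    incomparable signature metadata are excluded.
    """
    drugs = sorted(set(profiles) & set(signatures))
    ranked = {c: rankdata(profiles[c].r) for c in drugs}
    prof_sims, sig_sims = [], []
    for i, c1 in enumerate(drugs):
        for c2 in drugs[i + 1 :]:
            if signatures[c1].metadata != signatures[c2].metadata:
                continue
            diff = np.abs(ranked[c1] - ranked[c2])
            denom = np.abs(ranked[c1]) + np.abs(ranked[c2])
            with np.errstate(invalid="ignore"):
                terms = np.where(denom > 0, diff / np.where(denom > 0, denom, 1), 0.0)
            prof_sims.append(-float(terms.sum()))
            sig_sims.append(signature_similarity(signatures[c1], signatures[c2]))
    if len(prof_sims) < 3:
        raise ValueError("too few comparable drug pairs for a rank correlation")
    rho, p = spearmanr(prof_sims, sig_sims)
    return {"spearman_rho": float(rho), "p_value": float(p), "n_pairs": len(prof_sims)}
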