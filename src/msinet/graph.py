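"""Heterogeneous multiscale-interactome graph: data model, loaders, validation.

The multiscale interactome is an undirected graph over four default node
kinds — drugs, diseases, proteins, and biological functions — where the
function layer is a hierarchy (each function–function edge records which
endpoint is the parent, i.e. the more general term).  Edges are permitted
only between drug–protein, disease–protein, protein–protein,
protein–function, and function–function pairs; the kind set is extensible so
additional node categories (e.g. anatomical entities) can be represented
with their own permitted pairs.

Edge lists are plain TSV with header columns
``node_1  node_1_type  node_2  node_2_type``; for hierarchy files the first
column is the child (more specific) term and the second the parent.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("msinet")

# -- node kinds --------------------------------------------------------------

DRUG = "drug"
DISEASE = "disease"
PROTEIN = "protein"
FUNCTION = "biological_function"

DEFAULT_KINDS = (DRUG, DISEASE, PROTEIN, FUNCTION)

#: unordered kind pairs an edge may connect (hierarchy edges are the
#: function–function pair, with orientation recorded separately)
DEFAULT_PERMITTED_PAIRS = frozenset(
    {
        frozenset({DRUG, PROTEIN}),
        frozenset({DISEASE, PROTEIN}),
        frozenset({PROTEIN}),
        frozenset({PROTEIN, FUNCTION}),
        frozenset({FUNCTION}),
    }
)

#: kinds whose nodes act as walk endpoints (sources/sinks) during diffusion
DEFAULT_RESTART_KINDS = frozenset({DRUG, DISEASE})

GRAPH_FORMAT_VERSION = 1

EDGE_TABLE_COLUMNS = ["node_1", "node_1_type", "node_2", "node_2_type"]


class GraphFormatError(ValueError):
    """Malformed edge table or treatment/PGx file."""


class GraphValidationError(ValueError):
    """Graph violates a structural invariant (kind collision, bad pair...)."""


# -- data model --------------------------------------------------------------


class MultiscaleGraph:
    """Typed heterogeneous undirected graph with oriented hierarchy edges.

    Parameters
    ----------
    kinds
        Mapping node id -> kind label.  Identifiers must be unique across
        kinds (namespaced upstream; verbatim ids from the input files).
    edges
        Iterable of unordered node-id pairs.  Self-loops and duplicates are
        rejected.
    hierarchy
        Iterable of ``(child, parent)`` function-id pairs, one per
        function–function edge.
    """

    def __init__(
        self,
        kinds: Mapping[str, str],
        edges: Iterable[tuple[str, str]],
        hierarchy: Iterable[tuple[str, str]] = (),
        permitted_pairs: frozenset[frozenset[str]] = DEFAULT_PERMITTED_PAIRS,
        restart_kinds: frozenset[str] = DEFAULT_RESTART_KINDS,
        names: Mapping[str, str] | None = None,
    ):
        self.kinds: dict[str, str] = dict(kinds)
        self.permitted_pairs = frozenset(permitted_pairs)
        self.restart_kinds = frozenset(restart_kinds)
        self.names: dict[str, str] = dict(names or {})

        self.edges: set[tuple[str, str]] = set()
        for u, v in edges:
            if u == v:
                raise GraphValidationError(f"self-loop on node {u!r}")
            self.edges.add(_canon(u, v))

        # child -> set of parents; one parent endpoint per hierarchy edge
        self.parents: dict[str, set[str]] = {}
        for child, parent in hierarchy:
            key = _canon(child, parent)
            if key not in self.edges:
                raise GraphValidationError(
                    f"hierarchy orientation given for absent edge {child!r}-{parent!r}"
                )
            self.parents.setdefault(child, set()).add(parent)

        self._adj: dict[str, list[str]] | None = None
        self._fingerprint: int | None = None
        self.validate()

    # -- structure -----------------------------------------------------------

    def validate(self) -> None:
        for u, v in self.edges:
            for n in (u, v):
                if n not in self.kinds:
                    raise GraphValidationError(f"edge endpoint {n!r} has no kind")
            pair = frozenset({self.kinds[u], self.kinds[v]})
            if pair not in self.permitted_pairs:
                raise GraphValidationError(
                    f"edge {u!r}({self.kinds[u]}) - {v!r}({self.kinds[v]}) "
                    f"connects a non-permitted kind pair"
                )
            if self.kinds[u] == FUNCTION and self.kinds[v] == FUNCTION:
                n_orient = (v in self.parents.get(u, ())) + (u in self.parents.get(v, ()))
                if n_orient != 1:
                    raise GraphValidationError(
                        f"function-function edge {u!r}-{v!r} must have exactly one "
                        f"parent endpoint (found {n_orient})"
                    )

    @property
    def adjacency(self) -> dict[str, list[str]]:
        """Sorted neighbor lists (deterministic iteration order)."""
        if self._adj is None:
            adj: dict[str, list[str]] = {n: [] for n in self.kinds}
            for u, v in self.edges:
                adj[u].append(v)
                adj[v].append(u)
            self._adj = {n: sorted(vs) for n, vs in adj.items()}
        return self._adj

    def neighbors(self, node: str) -> list[str]:
        return self.adjacency[node]

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, k in self.kinds.items() if k == kind)

    @property
    def node_index(self) -> list[str]:
        """Canonical (sorted) node ordering used by diffusion profiles."""
        return sorted(self.kinds)

    def fingerprint(self) -> int:
        """Stable content hash used as a profile-cache key."""
        if self._fingerprint is None:
            payload = (
                tuple(sorted(self.kinds.items())),
                tuple(sorted(self.edges)),
                tuple(sorted((c, p) for c, ps in self.parents.items() for p in ps)),
            )
            self._fingerprint = hash(payload)
        return self._fingerprint

    def is_parent(self, parent: str, child: str) -> bool:
        return parent in self.parents.get(child, ())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MultiscaleGraph)
            and self.kinds == other.kinds
            and self.edges == other.edges
            and self.parents == other.parents
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        per_kind = {k: len(self.nodes_of_kind(k)) for k in sorted(set(self.kinds.values()))}
        return f"MultiscaleGraph({per_kind}, n_edges={len(self.edges)})"

    # -- summaries & serialization -------------------------------------------

    def summary(self) -> dict:
        nodes = {k: len(self.nodes_of_kind(k)) for k in sorted(set(self.kinds.values()))}
        edges: dict[str, int] = {}
        for u, v in self.edges:
            key = "-".join(sorted((self.kinds[u], self.kinds[v])))
            edges[key] = edges.get(key, 0) + 1
        return {"nodes": nodes, "edges": edges, "n_edges": len(self.edges)}

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": GRAPH_FORMAT_VERSION,
            "kinds": self.kinds,
            "edges": sorted(self.edges),
            "hierarchy": sorted((c, p) for c, ps in self.parents.items() for p in ps),
            "permitted_pairs": [sorted(p) for p in self.permitted_pairs],
            "restart_kinds": sorted(self.restart_kinds),
            "names": self.names,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "MultiscaleGraph":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format_version") != GRAPH_FORMAT_VERSION:
            raise GraphFormatError(
                f"unsupported graph container version {payload.get('format_version')!r}"
            )
        return cls(
            kinds=payload["kinds"],
            edges=[tuple(e) for e in payload["edges"]],
            hierarchy=[tuple(e) for e in payload["hierarchy"]],
            permitted_pairs=frozenset(frozenset(p) for p in payload["permitted_pairs"]),
            restart_kinds=frozenset(payload["restart_kinds"]),
            names=payload.get("names"),
        )


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class TreatmentDataset:
    """Approved (drug, disease) pairs used as ranking ground truth."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        if len({p for p in self.pairs}) != len(self.pairs):  # frozenset dedups anyway
            raise GraphValidationError("duplicate treatment pairs")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TreatmentDataset":
        pairs = list(pairs)
        if len(set(pairs)) != len(pairs):
            logger.info("treatment pairs: %d duplicates collapsed", len(pairs) - len(set(pairs)))
        return cls(frozenset(pairs))

    @property
    def drugs(self) -> list[str]:
        return sorted({c for c, _ in self.pairs})

    @property
    def diseases(self) -> list[str]:
        return sorted({d for _, d in self.pairs})

    def drugs_for(self, disease: str) -> set[str]:
        return {c for c, d in self.pairs if d == disease}

    def validate_against(self, graph: MultiscaleGraph) -> None:
        """Every id in the graph; every drug has >=1 target, disease >=1 protein."""
        adj = graph.adjacency
        for c, d in self.pairs:
            for n, want in ((c, DRUG), (d, DISEASE)):
                if graph.kinds.get(n) != want:
                    raise GraphValidationError(f"treatment pair node {n!r} is not a {want}")
            if not adj[c]:
                raise GraphValidationError(f"drug {c!r} has no target edge")
            if not adj[d]:
                raise GraphValidationError(f"disease {d!r} has no protein edge")


@dataclass(frozen=True)
class PGxTriplet:
    """A (drug, disease, gene) record of a known treatment alteration.

    Genes are identified by their protein node in the graph.
    """

    drug: str
    disease: str
    gene: str


def validate_triplets(
    triplets: Sequence[PGxTriplet], dataset: TreatmentDataset, graph: MultiscaleGraph
) -> None:
    for t in triplets:
        if (t.drug, t.disease) not in dataset.pairs:
            raise GraphValidationError(
                f"triplet ({t.drug}, {t.disease}, {t.gene}): pair is not an approved treatment"
            )
        if graph.kinds.get(t.gene) != PROTEIN:
            raise GraphValidationError(f"triplet gene {t.gene!r} does not resolve to a protein")


# -- loaders -----------------------------------------------------------------


def load_edge_table(
    path: str | Path, expected_kinds: tuple[str, str] | None = None
) -> pd.DataFrame:
    """Read one TSV edge layer; collapse duplicate rows with a logged count.

    Returns a DataFrame with columns ``node_1, node_1_type, node_2,
    node_2_type``.  Column order carries hierarchy orientation: for
    function–function tables ``node_1`` is the child and ``node_2`` the
    parent.
    """
    path = Path(path)
    if not path.exists():
        raise GraphFormatError(f"edge table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise GraphFormatError(f"edge table is empty: {path}")
    missing = [c for c in EDGE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GraphFormatError(f"{path}: missing required column(s) {missing}")
    df = df[EDGE_TABLE_COLUMNS]
    n_raw = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n_raw:
        logger.info("%s: collapsed %d duplicate rows", path.name, n_raw - len(df))
    if expected_kinds is not None:
        k1, k2 = expected_kinds
        bad = df[(df.node_1_type != k1) | (df.node_2_type != k2)]
        if not bad.empty:
            raise GraphFormatError(
                f"{path}: {len(bad)} rows do not match expected kinds ({k1}, {k2})"
            )
    return df


def load_treatment_table(path: str | Path) -> TreatmentDataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drug", "disease"):
        if col not in df.columns:
            raise GraphFormatError(f"{path}: missing required column '{col}'")
    return TreatmentDataset.from_pairs(zip(df.drug, df.disease))


def load_pgx_table(path: str | Path) -> list[PGxTriplet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drug", "disease", "gene"):
        if col not in df.columns:
            raise GraphFormatError(f"{path}: missing required column '{col}'")
    return [PGxTriplet(r.drug, r.disease, r.gene) for r in df.itertuples()]


def assemble_graph(
    tables: Sequence[pd.DataFrame],
    hierarchy_tables: Sequence[pd.DataFrame] = (),
    permitted_pairs: frozenset[frozenset[str]] = DEFAULT_PERMITTED_PAIRS,
    restart_kinds: frozenset[str] = DEFAULT_RESTART_KINDS,
) -> MultiscaleGraph:
    """Union edge tables into a validated :class:`MultiscaleGraph`.

    ``hierarchy_tables`` rows are (child, parent) oriented; their edges are
    also added to the undirected edge set.  An id appearing under two kinds
    is a hard error (identifiers are namespaced by the caller).
    """
    kinds: dict[str, str] = {}
    collisions: set[str] = set()

    def claim(node: str, kind: str) -> None:
        prev = kinds.setdefault(node, kind)
        if prev != kind:
            collisions.add(node)

    edges: list[tuple[str, str]] = []
    hierarchy: list[tuple[str, str]] = []
    for df in tables:
        for r in df.itertuples():
            claim(r.node_1, r.node_1_type)
            claim(r.node_2, r.node_2_type)
            edges.append((r.node_1, r.node_2))
    for df in hierarchy_tables:
        for r in df.itertuples():
            claim(r.node_1, r.node_1_type)
            claim(r.node_2, r.node_2_type)
            edges.append((r.node_1, r.node_2))
            hierarchy.append((r.node_1, r.node_2))

    if collisions:
        raise GraphValidationError(
            f"id(s) appear under multiple kinds: {sorted(collisions)}"
        )
    graph = MultiscaleGraph(
        kinds, edges, hierarchy, permitted_pairs=permitted_pairs, restart_kinds=restart_kinds
    )
    logger.info("assembled graph: %s", graph.summary())
    return graph


def write_edge_tables(graph: MultiscaleGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write the graph back to the five TSV layers (round-trip counterpart)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    layers: dict[str, list[tuple[str, str, str, str]]] = {
        "drug_protein": [],
        "disease_protein": [],
        "ppi": [],
        "protein_function": [],
        "hierarchy": [],
    }
    layer_of = {
        frozenset({DRUG, PROTEIN}): "drug_protein",
        frozenset({DISEASE, PROTEIN}): "disease_protein",
        frozenset({PROTEIN}): "ppi",
        frozenset({PROTEIN, FUNCTION}): "protein_function",
    }
    kind_rank = {DRUG: 0, DISEASE: 0, PROTEIN: 1, FUNCTION: 2}
    for u, v in sorted(graph.edges):
        ku, kv = graph.kinds[u], graph.kinds[v]
        if ku == FUNCTION and kv == FUNCTION:
            child, parent = (u, v) if graph.is_parent(v, child=u) else (v, u)
            layers["hierarchy"].append((child, FUNCTION, parent, FUNCTION))
            continue
        # put the drug/disease (or protein, vs function) endpoint first
        if kind_rank.get(ku, 9) > kind_rank.get(kv, 9):
            u, v, ku, kv = v, u, kv, ku
        layers[layer_of[frozenset({ku, kv})]].append((u, ku, v, kv))
    paths = {}
    for name, rows in layers.items():
        p = out_dir / f"{name}.tsv"
        pd.DataFrame(rows, columns=EDGE_TABLE_COLUMNS).to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths


# -- hierarchy utilities & pruning -------------------------------------------


def topological_order(graph: MultiscaleGraph) -> list[str]:
    """Functions ordered children before parents; raises on a cyclic hierarchy."""
    functions = graph.nodes_of_kind(FUNCTION)
    children: dict[str, list[str]] = {f: [] for f in functions}
    n_parents = {f: 0 for f in functions}
    for child, parents in graph.parents.items():
        for p in parents:
            children[child]  # child must be a function node
            children.setdefault(p, [])
            children[p].append(child)
    for f in functions:
        n_parents[f] = len(graph.parents.get(f, ()))
    # Kahn's algorithm starting from roots (no parents), emitting parents last
    order: list[str] = []
    stack = sorted(f for f in functions if n_parents[f] == 0)
    remaining = dict(n_parents)
    while stack:
        node = stack.pop()
        order.append(node)
        for ch in sorted(children.get(node, ())):
            remaining[ch] -= 1
            if remaining[ch] == 0:
                stack.append(ch)
    if len(order) != len(functions):
        raise GraphValidationError("function hierarchy contains a cycle")
    return order[::-1]  # children first


def ancestors_of(graph: MultiscaleGraph, terms: Iterable[str]) -> set[str]:
    """Terms plus all their ancestors via recorded child->parent edges."""
    out: set[str] = set()
    stack = list(terms)
    while stack:
        t = stack.pop()
        if t in out:
            continue
        out.add(t)
        stack.extend(graph.parents.get(t, ()))
    return out


def prune_functions(graph: MultiscaleGraph) -> MultiscaleGraph:
    """Drop functions not tied (directly or through any descendant) to a drug
    target or disease protein.

    A function is retained iff it, or some descendant in the hierarchy, is
    annotated to at least one protein that is a drug target or a disease
    protein.  Idempotent; requires an acyclic hierarchy.
    """
    topological_order(graph)  # cycle check
    adj = graph.adjacency
    relevant_proteins: set[str] = set()
    for n, k in graph.kinds.items():
        if k in (DRUG, DISEASE):
            relevant_proteins.update(v for v in adj[n] if graph.kinds[v] == PROTEIN)
    if not relevant_proteins:
        raise GraphValidationError("no drug targets or disease proteins to prune against")
    directly_relevant = {
        f
        for f in graph.nodes_of_kind(FUNCTION)
        if any(graph.kinds[v] == PROTEIN and v in relevant_proteins for v in adj[f])
    }
    keep = ancestors_of(graph, directly_relevant)
    dropped = set(graph.nodes_of_kind(FUNCTION)) - keep
    if dropped:
        logger.info("prune_functions: removed %d function nodes", len(dropped))
    return _without_nodes(graph, dropped)


def molecular_subgraph(graph: MultiscaleGraph) -> MultiscaleGraph:
    """The molecular-scale interactome: the graph with function nodes removed."""
    return _without_nodes(graph, set(graph.nodes_of_kind(FUNCTION)))


def _without_nodes(graph: MultiscaleGraph, drop: set[str]) -> MultiscaleGraph:
    kinds = {n: k for n, k in graph.kinds.items() if n not in drop}
    edges = [(u, v) for u, v in graph.edges if u not in drop and v not in drop]
    hierarchy = [
        (c, p)
        for c, ps in graph.parents.items()
        if c not in drop
        for p in ps
        if p not in drop
    ]
    return MultiscaleGraph(
        kinds,
        edges,
        hierarchy,
        permitted_pairs=graph.permitted_pairs,
        restart_kinds=graph.restart_kinds,
        names=graph.names,
    )
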