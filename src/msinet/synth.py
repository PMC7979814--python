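"""Miniature multiscale interactomes with planted treatment structure.

The generator emulates the statistical structure the diffusion-profile
method assumes: a modular protein–protein network (degree-heterogeneous
stochastic-block wiring), a per-module hierarchy of biological functions
under one shared root, diseases that perturb proteins of one module, and
drugs that treat diseases of their module through one of two planted
mechanisms:

* molecular route — the drug targets proteins inside its module's
  disease-protein set, so drug and disease are close on the protein layer;
* functional route — the drug targets proteins of a separate "reservoir"
  block that is unrelated to any disease module on the protein layer, but
  those targets are annotated to the treated module's function subtree.
  The treatment signal then flows only through function nodes and vanishes
  when the function layer is ablated.

Approved pairs are exactly the (drug, disease) pairs sharing a module.
Treatment-altering (PGx) genes are planted on drug targets that are also
disease proteins; expression signatures are noisy monotone transforms of
the drug diffusion profiles.  Generation is a pure function of the spec
(which includes the seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import OPTIMAL_MULTISCALE, EdgeWeightConfig, diffusion_profile
from .explain import ExpressionSignature
from .graph import (
    DISEASE,
    DRUG,
    FUNCTION,
    PROTEIN,
    MultiscaleGraph,
    PGxTriplet,
    TreatmentDataset,
    write_edge_tables,
)

SIGNATURE_METADATA = (("cell_line", "SYNCELL1"), ("dose", "10uM"), ("time", "24h"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Counts, wiring probabilities, and planted-treatment parameters."""

    n_modules: int = 4
    proteins_per_module: int = 25
    n_drugs: int = 24
    n_diseases: int = 8
    functions_per_module: int = 7
    hierarchy_depth: int = 3
    p_in: float = 0.12
    p_out: float = 0.004
    functional_route_fraction: float = 0.5
    targets_per_drug: int = 3
    proteins_per_disease: int = 8
    pgx_rate: float = 0.5
    signature_noise: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        for name in (
            "n_modules",
            "proteins_per_module",
            "n_drugs",
            "n_diseases",
            "functions_per_module",
            "hierarchy_depth",
            "targets_per_drug",
            "proteins_per_disease",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.proteins_per_disease > self.proteins_per_module:
            raise ValueError("proteins_per_disease cannot exceed proteins_per_module")


@dataclass
class SyntheticData:
    """Everything the generator emits for one spec."""

    spec: SyntheticSpec
    graph: MultiscaleGraph
    treatments: TreatmentDataset
    pgx_positives: list[PGxTriplet]
    signatures: dict[str, ExpressionSignature]
    drug_module: dict[str, int]
    disease_module: dict[str, int]
    drug_route: dict[str, str]  # "molecular" | "functional"


def _powerlaw_weights(n: int, rng: np.random.Generator, exponent: float = 0.8) -> np.ndarray:
    """Heavy-tailed stub weights so blocks get hub-like degree heterogeneity."""
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** -exponent
    return w / w.mean()


def _wire_block(
    members: list[str], p_in: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Chung–Lu wiring inside a block plus a spanning ring for connectivity."""
    n = len(members)
    edges = {(members[i], members[(i + 1) % n]) for i in range(n)} if n > 1 else set()
    w = _powerlaw_weights(n, rng)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < min(1.0, p_in * w[i] * w[j]):
                edges.add((members[i], members[j]))
    return [tuple(sorted(e)) for e in edges]


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Build the planted multiscale interactome and its companion tables."""
    rng = np.random.default_rng(spec.seed)
    n_functional = round(spec.functional_route_fraction * spec.n_drugs)
    # reservoir sized so functional drugs get mostly disjoint target sets
    reservoir_size = max(
        spec.proteins_per_module, math.ceil(1.2 * n_functional * spec.targets_per_drug)
    )

    kinds: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    hierarchy: list[tuple[str, str]] = []

    # protein blocks: modules 0..n_modules-1 plus the reservoir block
    modules: list[list[str]] = []
    counter = 0
    for m in range(spec.n_modules + 1):
        size = reservoir_size if m == spec.n_modules else spec.proteins_per_module
        block = [f"P{counter + i:04d}" for i in range(size)]
        counter += size
        for p in block:
            kinds[p] = PROTEIN
        modules.append(block)
        edges.extend(_wire_block(block, spec.p_in, rng))
    reservoir = modules[spec.n_modules]

    # sparse inter-block wiring plus one bridge per consecutive block pair
    all_blocks = modules
    for a in range(len(all_blocks)):
        for b in range(a + 1, len(all_blocks)):
            for u in all_blocks[a]:
                for v in all_blocks[b]:
                    if rng.random() < spec.p_out:
                        edges.append(tuple(sorted((u, v))))
    for a in range(len(all_blocks) - 1):
        u = all_blocks[a][int(rng.integers(len(all_blocks[a])))]
        v = all_blocks[a + 1][int(rng.integers(len(all_blocks[a + 1])))]
        edges.append(tuple(sorted((u, v))))

    # one function tree per module under a shared global root
    root = "GO:ROOT"
    kinds[root] = FUNCTION
    module_functions: list[list[str]] = []
    module_leaves: list[list[str]] = []
    for m in range(spec.n_modules):
        terms = [f"GO:M{m}N{i:02d}" for i in range(spec.functions_per_module)]
        for t in terms:
            kinds[t] = FUNCTION
        # binary-ish tree: node i's parent is node (i-1)//2, capped at depth
        for i, t in enumerate(terms):
            parent = root if i == 0 else terms[(i - 1) // 2]
            edges.append(tuple(sorted((t, parent))))
            hierarchy.append((t, parent))
        n_internal = (spec.functions_per_module - 1) // 2
        leaves = terms[n_internal + 1 :] or terms[-1:]
        module_functions.append(terms)
        module_leaves.append(leaves)
    # a few cross-links between neighboring module subtrees (DAG, not a forest)
    for m in range(spec.n_modules - 1):
        child = module_leaves[m][int(rng.integers(len(module_leaves[m])))]
        parent = module_functions[m + 1][0]
        edge = tuple(sorted((child, parent)))
        if edge not in set(edges):
            edges.append(edge)
            hierarchy.append((child, parent))

    # native annotations: module proteins to their module's deeper terms
    for m in range(spec.n_modules):
        deep = module_functions[m][1:] or module_functions[m]
        for p in modules[m]:
            for t in rng.choice(deep, size=min(2, len(deep)), replace=False):
                edges.append(tuple(sorted((p, str(t)))))

    # diseases perturb proteins of one module
    disease_module: dict[str, int] = {}
    disease_proteins: dict[str, list[str]] = {}
    for i in range(spec.n_diseases):
        d = f"C{i:04d}"
        kinds[d] = DISEASE
        m = i % spec.n_modules
        disease_module[d] = m
        chosen = rng.choice(modules[m], size=spec.proteins_per_disease, replace=False)
        disease_proteins[d] = [str(p) for p in chosen]
        edges.extend(tuple(sorted((d, p))) for p in disease_proteins[d])

    module_disease_proteins: dict[int, list[str]] = {}
    for d, prots in disease_proteins.items():
        module_disease_proteins.setdefault(disease_module[d], [])
        module_disease_proteins[disease_module[d]].extend(prots)
    for m in module_disease_proteins:
        module_disease_proteins[m] = sorted(set(module_disease_proteins[m]))

    # drugs: module-assigned, molecular or functional route
    drug_module: dict[str, int] = {}
    drug_route: dict[str, str] = {}
    drug_targets: dict[str, list[str]] = {}
    route_order = ["functional"] * n_functional + ["molecular"] * (spec.n_drugs - n_functional)
    route_order = [route_order[i] for i in rng.permutation(spec.n_drugs)]
    reservoir_pool = list(rng.permutation(reservoir))
    for i in range(spec.n_drugs):
        c = f"DB{i:04d}"
        kinds[c] = DRUG
        m = i % spec.n_modules
        drug_module[c] = m
        drug_route[c] = route_order[i]
        if route_order[i] == "molecular":
            pool = module_disease_proteins.get(m, modules[m])
            k = min(spec.targets_per_drug, len(pool))
            targets = [str(p) for p in rng.choice(pool, size=k, replace=False)]
        else:
            if len(reservoir_pool) < spec.targets_per_drug:
                reservoir_pool = list(rng.permutation(reservoir))
            targets = [reservoir_pool.pop() for _ in range(spec.targets_per_drug)]
            # planted cross-annotations: targets act on the treated module's functions
            for t in targets:
                leaves = module_leaves[m]
                for f in rng.choice(leaves, size=min(2, len(leaves)), replace=False):
                    edge = tuple(sorted((t, str(f))))
                    if edge not in set(edges):
                        edges.append(edge)
        drug_targets[c] = targets
        edges.extend(tuple(sorted((c, t))) for t in targets)

    graph = MultiscaleGraph(kinds, set(edges), hierarchy)

    # approved pairs: drug and disease share a module
    pairs = [
        (c, d)
        for c in sorted(drug_module)
        for d in sorted(disease_module)
        if drug_module[c] == disease_module[d]
    ]
    treatments = TreatmentDataset.from_pairs(pairs)

    # PGx positives: genes that are both drug targets and disease proteins
    pgx: list[PGxTriplet] = []
    for c, d in pairs:
        if drug_route[c] != "molecular":
            continue
        if rng.random() > spec.pgx_rate:
            continue
        shared = sorted(set(drug_targets[c]) & set(disease_proteins[d]))
        gene = shared[int(rng.integers(len(shared)))] if shared else drug_targets[c][0]
        pgx.append(PGxTriplet(c, d, gene))

    # expression signatures: standardized profile ranks plus Gaussian noise
    proteins = graph.nodes_of_kind(PROTEIN)
    signatures: dict[str, ExpressionSignature] = {}
    for c in sorted(drug_module):
        prof = diffusion_profile(graph, OPTIMAL_MULTISCALE, c)
        values = np.array([prof[p] for p in proteins])
        ranks = values.argsort(kind="stable").argsort().astype(float)
        z = (ranks - ranks.mean()) / ranks.std()
        z = z + spec.signature_noise * rng.standard_normal(len(z))
        signatures[c] = ExpressionSignature(
            drug=c,
            genes=tuple(proteins),
            values=tuple(float(x) for x in z),
            metadata=SIGNATURE_METADATA,
        )

    return SyntheticData(
        spec=spec,
        graph=graph,
        treatments=treatments,
        pgx_positives=pgx,
        signatures=signatures,
        drug_module=drug_module,
        disease_module=disease_module,
        drug_route=drug_route,
    )


def default_fixture(seed: int = 0) -> SyntheticData:
    """The default study fixture (all counts at their spec defaults)."""
    return generate(SyntheticSpec(seed=seed))


def write_fixture(data: SyntheticData, out_dir: str | Path) -> dict[str, Path]:
    """Emit the fixture as the exact TSV schemas the loaders expect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_edge_tables(data.graph, out_dir)

    pairs = pd.DataFrame(sorted(data.treatments.pairs), columns=["drug", "disease"])
    paths["treatments"] = out_dir / "approved_pairs.tsv"
    pairs.to_csv(paths["treatments"], sep="\t", index=False)

    pgx = pd.DataFrame(
        [(t.drug, t.disease, t.gene) for t in data.pgx_positives],
        columns=["drug", "disease", "gene"],
    )
    paths["pgx"] = out_dir / "pgx_triplets.tsv"
    pgx.to_csv(paths["pgx"], sep="\t", index=False)

    sig_dir = out_dir / "signatures"
    sig_dir.mkdir(exist_ok=True)
    meta_rows = []
    for drug, sig in sorted(data.signatures.items()):
        df = pd.DataFrame({"gene": sig.genes, "zscore": sig.values})
        df.to_csv(sig_dir / f"{drug}.tsv", sep="\t", index=False)
        meta_rows.append({"drug": drug, **dict(sig.metadata)})
    paths["signature_metadata"] = sig_dir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(paths["signature_metadata"], sep="\t", index=False)

    with open(out_dir / "spec.json", "w") as fh:
        json.dump(data.spec.__dict__, fh, indent=2)
    return paths


def load_signatures(sig_dir: str | Path) -> dict[str, ExpressionSignature]:
    """Read back the per-drug signature TSVs written by :func:`write_fixture`."""
    sig_dir = Path(sig_dir)
    meta = pd.read_csv(sig_dir / "metadata.tsv", sep="\t", dtype=str).set_index("drug")
    out = {}
    for path in sorted(sig_dir.glob("*.tsv")):
        if path.name == "metadata.tsv":
            continue
        drug = path.stem
        df = pd.read_csv(path, sep="\t")
        metadata = tuple(sorted(meta.loc[drug].items())) if drug in meta.index else ()
        out[drug] = ExpressionSignature(
            drug=drug,
            genes=tuple(df.gene.astype(str)),
            values=tuple(df.zscore.astype(float)),
            metadata=metadata,
        )
    return out
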