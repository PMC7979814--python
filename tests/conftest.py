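import numpy as np
import pytest

import msinet as ms


@pytest.fixture(scope="session")
def fixture_data():
    """Default planted synthetic interactome (seed 0), shared across tests."""
    return ms.default_fixture(seed=0)


@pytest.fixture(scope="session")
def fixture_profiles(fixture_data):
    """Multiscale diffusion profiles for every drug and disease of the fixture."""
    cache = ms.ProfileCache()
    entities = (
        fixture_data.graph.nodes_of_kind(ms.DRUG)
        + fixture_data.graph.nodes_of_kind(ms.DISEASE)
    )
    return cache.get_many(fixture_data.graph, ms.OPTIMAL_MULTISCALE, entities)


@pytest.fixture()
def tiny_graph():
    """Two drugs, one disease, four proteins, three functions (A parent of B, C)."""
    kinds = {
        "c1": ms.DRUG,
        "c2": ms.DRUG,
        "d1": ms.DISEASE,
        "p1": ms.PROTEIN,
        "p2": ms.PROTEIN,
        "p3": ms.PROTEIN,
        "p4": ms.PROTEIN,
        "fA": ms.FUNCTION,
        "fB": ms.FUNCTION,
        "fC": ms.FUNCTION,
    }
    edges = [
        ("c1", "p1"),
        ("c2", "p3"),
        ("d1", "p2"),
        ("p1", "p2"),
        ("p2", "p3"),
        ("p3", "p4"),
        ("p1", "fB"),
        ("p4", "fC"),
        ("fB", "fA"),
        ("fC", "fA"),
    ]
    hierarchy = [("fB", "fA"), ("fC", "fA")]
    return ms.MultiscaleGraph(kinds, edges, hierarchy)


def random_typed_graph(rng: np.random.Generator, n_proteins=12, n_drugs=2, n_diseases=2,
                       n_functions=5, p_edge=0.25):
    """Small random multiscale graph, connected enough for diffusion tests."""
    prot = [f"P{i}" for i in range(n_proteins)]
    drugs = [f"DB{i}" for i in range(n_drugs)]
    diseases = [f"C{i}" for i in range(n_diseases)]
    funcs = [f"F{i}" for i in range(n_functions)]
    kinds = {p: ms.PROTEIN for p in prot}
    kinds.update({c: ms.DRUG for c in drugs})
    kinds.update({d: ms.DISEASE for d in diseases})
    kinds.update({f: ms.FUNCTION for f in funcs})
    edges = {tuple(sorted((prot[i], prot[i + 1]))) for i in range(n_proteins - 1)}
    for i in range(n_proteins):
        for j in range(i + 1, n_proteins):
            if rng.random() < p_edge:
                edges.add((prot[i], prot[j]))
    for x in drugs + diseases:
        k = 1 + int(rng.integers(3))
        for p in rng.choice(prot, size=k, replace=False):
            edges.add(tuple(sorted((x, str(p)))))
    hierarchy = []
    for i, f in enumerate(funcs):
        if i > 0:
            parent = funcs[(i - 1) // 2]
            edges.add(tuple(sorted((f, parent))))
            hierarchy.append((f, parent))
        for p in rng.choice(prot, size=2, replace=False):
            edges.add(tuple(sorted((str(p), f))))
    return ms.MultiscaleGraph(kinds, edges, hierarchy)
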