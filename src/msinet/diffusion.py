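"""Diffusion profiles: biased random walks with restart on the multiscale graph.

A diffusion profile r is the stationary visitation-frequency vector of a
walker that starts at one focal drug or disease, steps across the network,
and restarts at the focal node with probability 1 - alpha at each step.
When continuing, the walker first picks a neighbor *type* t with probability
proportional to the type weight w_t, then a uniform neighbor of that type:

    p_t      = w_t / sum_{t' in T} w_{t'}          (T = types adjacent to i)
    M_ij     = p_t / n_t                           (n_t neighbors of type t)

The graph is first converted to a per-focal directed view: the focal node is
a source (no in-edges) and every other drug/disease is a sink (no
out-edges), so drugs and diseases never act as walk intermediates.  Mass
reaching a sink is returned to the restart vector:

    r(k+1) = (1-alpha) s + alpha (r(k) M + s * sum_{j in J} r_j(k))

iterated from r(0) = 1/|V| until the L1 change drops below a tolerance
(default 1e-6), with an explicit iteration cap guarding non-convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .graph import DISEASE, DRUG, FUNCTION, PROTEIN, MultiscaleGraph

logger = logging.getLogger("msinet")

HIGHER_FUNCTION = "higher_level_function"
LOWER_FUNCTION = "lower_level_function"


class ConvergenceError(RuntimeError):
    pass


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EdgeWeightConfig:
    """Type weights W, continuation probability alpha, and tolerance.

    ``weights`` maps every node kind the walker may step to onto a positive
    scalar; function–function steps use the ``higher_level_function`` /
    ``lower_level_function`` entries, resolved from the hierarchy
    orientation.  ``tie_function_weights`` asserts the sweep convention
    w_biological_function = w_higher + w_lower.
    """

    weights: tuple[tuple[str, float], ...]
    alpha: float = 0.860
    tolerance: float = 1e-6
    max_iter: int = 10_000
    tie_function_weights: bool = False

    def __post_init__(self):
        w = dict(self.weights)
        for kind, val in w.items():
            if not val > 0:
                raise ConfigurationError(f"weight for {kind!r} must be > 0 (got {val})")
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must be in (0, 1) (got {self.alpha})")
        if not self.tolerance > 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.tie_function_weights:
            # checked to printed precision: published optima round each weight
            # to two decimals, so the sum can be off by one ulp of the print
            want = w.get(HIGHER_FUNCTION, 0.0) + w.get(LOWER_FUNCTION, 0.0)
            if abs(w.get(FUNCTION, np.nan) - want) > 0.011:
                raise ConfigurationError(
                    "tie_function_weights requires w_biological_function = "
                    "w_higher_level_function + w_lower_level_function"
                )

    @classmethod
    def from_dict(cls, weights: dict[str, float], **kwargs) -> "EdgeWeightConfig":
        return cls(weights=tuple(sorted(weights.items())), **kwargs)

    def weight(self, kind: str) -> float:
        w = dict(self.weights)
        if kind not in w:
            raise ConfigurationError(f"no weight configured for node kind {kind!r}")
        return w[kind]

    def as_dict(self) -> dict[str, float]:
        return dict(self.weights)

    def with_alpha(self, alpha: float) -> "EdgeWeightConfig":
        return replace(self, alpha=alpha)


#: optimal multiscale weights from the model-selection sweep
OPTIMAL_MULTISCALE = EdgeWeightConfig.from_dict(
    {
        DRUG: 3.21,
        DISEASE: 3.54,
        PROTEIN: 4.40,
        FUNCTION: 6.58,
        HIGHER_FUNCTION: 2.10,
        LOWER_FUNCTION: 4.49,
    },
    alpha=0.860,
    tie_function_weights=True,
)

#: optimal molecular-scale (function-ablated) weights
OPTIMAL_MOLECULAR = EdgeWeightConfig.from_dict(
    {DRUG: 4.88, DISEASE: 6.83, PROTEIN: 3.21},
    alpha=0.854,
)

#: weights equal across kinds -> plain random walk with restart
UNIFORM = EdgeWeightConfig.from_dict(
    {k: 1.0 for k in (DRUG, DISEASE, PROTEIN, FUNCTION, HIGHER_FUNCTION, LOWER_FUNCTION)},
    alpha=0.5,
)


@dataclass
class DirectedView:
    """Per-focal directed view G' of the graph.

    ``out`` gives each node's out-neighbor list; ``sinks`` (J) is every node
    with an empty out-row — all non-focal drugs/diseases plus any node left
    without out-edges by the construction (e.g. a protein whose only
    neighbor is the focal node).
    """

    graph: MultiscaleGraph
    focal: str
    index: list[str]
    pos: dict[str, int]
    out: dict[str, list[str]]
    sinks: set[str]


def directed_view(graph: MultiscaleGraph, focal: str) -> DirectedView:
    kind = graph.kinds.get(focal)
    if kind not in graph.restart_kinds:
        raise ValueError(
            f"focal node {focal!r} must be one of kinds {sorted(graph.restart_kinds)} "
            f"(got {kind!r})"
        )
    adj = graph.adjacency
    out: dict[str, list[str]] = {}
    for n in graph.node_index:
        if n == focal:
            out[n] = list(adj[n])
        elif graph.kinds[n] in graph.restart_kinds:
            out[n] = []
        else:
            out[n] = [v for v in adj[n] if v != focal]
    sinks = {n for n, vs in out.items() if not vs}
    index = graph.node_index
    return DirectedView(
        graph=graph,
        focal=focal,
        index=index,
        pos={n: i for i, n in enumerate(index)},
        out=out,
        sinks=sinks,
    )


def _step_kind(graph: MultiscaleGraph, i: str, j: str) -> str:
    """Resolve the type label of out-neighbor j as seen from node i."""
    kj = graph.kinds[j]
    if graph.kinds[i] == FUNCTION and kj == FUNCTION:
        return HIGHER_FUNCTION if graph.is_parent(j, child=i) else LOWER_FUNCTION
    return kj


def transition_matrix(view: DirectedView, config: EdgeWeightConfig) -> sp.csr_matrix:
    """Biased transition matrix M over the view's node index.

    Row i splits probability mass across adjacent *types* proportionally to
    their weights, then uniformly within each type; sink rows are all zero.
    """
    graph = view.graph
    rows, cols, vals = [], [], []
    for i in view.index:
        neigh = view.out[i]
        if not neigh:
            continue
        by_type: dict[str, list[str]] = {}
        for j in neigh:
            by_type.setdefault(_step_kind(graph, i, j), []).append(j)
        total_w = sum(config.weight(t) for t in by_type)
        ri = view.pos[i]
        for t, members in by_type.items():
            p = config.weight(t) / total_w / len(members)
            for j in members:
                rows.append(ri)
                cols.append(view.pos[j])
                vals.append(p)
    n = len(view.index)
    M = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # row-stochastic where defined
    row_sums = np.asarray(M.sum(axis=1)).ravel()
    nonsink = np.setdiff1d(
        np.arange(n), np.fromiter((view.pos[s] for s in view.sinks), dtype=int, count=len(view.sinks))
    )
    assert np.all(np.abs(row_sums[nonsink] - 1.0) < 1e-12)
    return M


@dataclass
class DiffusionProfile:
    """Visitation-frequency vector r over all graph nodes (sums to 1)."""

    r: np.ndarray
    index: list[str]
    focal: str
    config: EdgeWeightConfig
    iterations: int = 0
    residual: float = 0.0
    _pos: dict[str, int] = field(default=None, repr=False)

    def __post_init__(self):
        if self._pos is None:
            self._pos = {n: i for i, n in enumerate(self.index)}

    def __getitem__(self, node: str) -> float:
        return float(self.r[self._pos[node]])

    def top(self, k: int, kinds: set[str] | None = None, graph: MultiscaleGraph | None = None):
        """Top-k (node, frequency) pairs, ties broken by node id."""
        items = self.index
        if kinds is not None:
            items = [n for n in items if graph.kinds[n] in kinds]
        ranked = sorted(items, key=lambda n: (-self[n], n))
        return [(n, self[n]) for n in ranked[:k]]


def restart_vector(view: DirectedView) -> np.ndarray:
    s = np.zeros(len(view.index))
    s[view.pos[view.focal]] = 1.0
    return s


def reachable_mask(view: DirectedView) -> np.ndarray:
    """Boolean mask of nodes reachable from the focal node in the view.

    The fixed point is exactly zero off this set; power iteration started
    from the uniform vector leaves only decaying numerical dust there, which
    callers zero out.
    """
    mask = np.zeros(len(view.index), dtype=bool)
    stack = [view.focal]
    while stack:
        n = stack.pop()
        i = view.pos[n]
        if mask[i]:
            continue
        mask[i] = True
        stack.extend(v for v in view.out[n] if not mask[view.pos[v]])
    return mask


def power_iteration(
    M: sp.csr_matrix,
    s: np.ndarray,
    sinks: np.ndarray,
    alpha: float,
    tolerance: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, int, float]:
    """Iterate the restart-walk fixed point; returns (r, iterations, residual).

    ``sinks`` is a boolean mask of zero-out-row nodes (J).  Every iterate
    sums to 1; a cap guards non-convergence.
    """
    if not (s >= 0).all() or abs(s.sum() - 1.0) > 1e-9:
        raise ValueError("restart vector must be a probability vector")
    n = M.shape[0]
    r = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        sink_mass = r[sinks].sum()
        r_new = (1.0 - alpha) * s + alpha * (r @ M + s * sink_mass)
        residual = float(np.abs(r_new - r).sum())
        r = r_new
        assert abs(r.sum() - 1.0) < 1e-9, "visitation mass not conserved"
        if residual <= tolerance:
            return r, it, residual
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations (residual {residual:.3e})"
    )


def diffusion_profile(
    graph: MultiscaleGraph, config: EdgeWeightConfig, focal: str
) -> DiffusionProfile:
    """Compute the diffusion profile of one focal drug or disease."""
    view = directed_view(graph, focal)
    s = restart_vector(view)
    if not view.out[focal]:
        logger.warning("focal node %r is isolated; returning the restart vector", focal)
        return DiffusionProfile(r=s, index=view.index, focal=focal, config=config)
    M = transition_matrix(view, config)
    sink_mask = np.zeros(len(view.index), dtype=bool)
    for j in view.sinks:
        sink_mask[view.pos[j]] = True
    r, iters, res = power_iteration(
        M, s, sink_mask, config.alpha, config.tolerance, config.max_iter
    )
    r[~reachable_mask(view)] = 0.0
    return DiffusionProfile(
        r=r, index=view.index, focal=focal, config=config, iterations=iters, residual=res
    )


def exact_profile_oracle(
    view: DirectedView, config: EdgeWeightConfig, s: np.ndarray | None = None
) -> DiffusionProfile:
    """Dense linear solve of the restart-walk fixed point (test oracle).

    Replacing each sink row of M by s folds the sink-redistribution term
    into the transition matrix; the fixed point then satisfies
    r = (1-alpha) s + alpha r M', solved directly.  Guarded to small graphs.
    """
    n = len(view.index)
    if n > 2000:
        raise ValueError(f"dense oracle guarded to <= 2000 nodes (got {n})")
    if s is None:
        s = restart_vector(view)
    M = transition_matrix(view, config).toarray()
    for j in view.sinks:
        M[view.pos[j], :] = s
    alpha = config.alpha
    A = np.eye(n) - alpha * M.T
    r = np.linalg.solve(A, (1.0 - alpha) * s)
    assert abs(r.sum() - 1.0) < 1e-8
    if (s > 0).sum() == 1 and s[view.pos[view.focal]] == 1.0:
        r[~reachable_mask(view)] = 0.0
    return DiffusionProfile(r=r, index=view.index, focal=view.focal, config=config)


class ProfileCache:
    """Memoizes profiles per (graph fingerprint, config, focal).

    Sweeps recompute profiles for many (weights, alpha) settings over the
    same graph; the cache makes repeated ranking passes cheap.
    """

    def __init__(self):
        self._store: dict[tuple, DiffusionProfile] = {}

    def get(
        self, graph: MultiscaleGraph, config: EdgeWeightConfig, focal: str
    ) -> DiffusionProfile:
        key = (graph.fingerprint(), config.weights, config.alpha, config.tolerance, focal)
        if key not in self._store:
            self._store[key] = diffusion_profile(graph, config, focal)
        return self._store[key]

    def get_many(
        self, graph: MultiscaleGraph, config: EdgeWeightConfig, focals: list[str]
    ) -> dict[str, DiffusionProfile]:
        return {f: self.get(graph, config, f) for f in focals}
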