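"""Ranking drugs by diffusion-profile similarity, CV evaluation, weight sweep.

A drug is predicted to treat a disease when their diffusion profiles are
similar: both affect the same proteins and biological functions.  Seven
comparison metrics are supported — L2, L1, Canberra and correlation
distances (negated so larger is always better), cosine similarity, and two
proximity readouts: the visitation frequency of the drug node in the
disease profile, and that frequency multiplied by the visitation frequency
of the disease node in the drug profile.

Rankings are scored per disease with AUROC, average precision, and
Recall@50, aggregated as the median AUROC / mean AP / mean Recall@50 across
diseases, under drug-level five-fold cross-validation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import distance as ssd
from sklearn.metrics import average_precision_score, roc_auc_score

from .diffusion import (
    HIGHER_FUNCTION,
    LOWER_FUNCTION,
    DiffusionProfile,
    EdgeWeightConfig,
    ProfileCache,
)
from .graph import DISEASE, DRUG, FUNCTION, PROTEIN, MultiscaleGraph, TreatmentDataset

logger = logging.getLogger("msinet")

DISTANCE_METRICS = ("l2", "l1", "canberra", "correlation")
SIMILARITY_METRICS = ("cosine", "proximity_drug_in_disease", "proximity_product")
ALL_METRICS = DISTANCE_METRICS + SIMILARITY_METRICS


def profile_similarity(
    rc: DiffusionProfile,
    rd: DiffusionProfile,
    metric: str,
    drug_node: str | None = None,
    disease_node: str | None = None,
) -> float:
    """Similarity score between a drug and a disease profile.

    Distances are negated so that a larger score always means "more likely
    to treat".  The proximity metrics require the drug and disease node ids
    (defaulting to each profile's focal node).
    """
    if rc.index != rd.index:
        raise ValueError("profiles are not over the same node index")
    x, y = rc.r, rd.r
    if metric == "l2":
        return -float(np.linalg.norm(x - y))
    if metric == "l1":
        return -float(np.abs(x - y).sum())
    if metric == "canberra":
        return -float(ssd.canberra(x, y))  # 0/0 terms contribute 0
    if metric == "correlation":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("zero-variance profile under correlation; maximal distance 2")
            return -2.0
        return -float(ssd.correlation(x, y))
    if metric == "cosine":
        return 1.0 - float(ssd.cosine(x, y))
    if metric == "proximity_drug_in_disease":
        return rd[drug_node or rc.focal]
    if metric == "proximity_product":
        return rd[drug_node or rc.focal] * rc[disease_node or rd.focal]
    raise ValueError(f"unknown metric {metric!r}")


def rank_drugs(
    disease: str,
    candidates: list[str],
    profiles: dict[str, DiffusionProfile],
    metric: str,
) -> list[tuple[str, float]]:
    """Candidates sorted by descending score; ties broken by drug id."""
    if disease not in profiles:
        raise KeyError(f"no diffusion profile for disease {disease!r}")
    rd = profiles[disease]
    scored = []
    for c in candidates:
        if c not in profiles:
            raise KeyError(f"no diffusion profile for drug {c!r}")
        scored.append((c, profile_similarity(profiles[c], rd, metric)))
    return sorted(scored, key=lambda t: (-t[1], t[0]))


# -- evaluation ---------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-disease ranking metrics plus their aggregates for one fold/split."""

    per_disease: dict[str, dict[str, float]]
    fold: int | None = None
    split: str = "held_out"

    def _agg(self, key: str, fn) -> float:
        vals = [m[key] for m in self.per_disease.values()]
        return float(fn(vals)) if vals else float("nan")

    @property
    def median_auroc(self) -> float:
        return self._agg("auroc", np.median)

    @property
    def mean_average_precision(self) -> float:
        return self._agg("average_precision", np.mean)

    @property
    def mean_recall_at_50(self) -> float:
        return self._agg("recall_at_50", np.mean)

    def aggregates(self) -> dict[str, float]:
        return {
            "median_auroc": self.median_auroc,
            "mean_average_precision": self.mean_average_precision,
            "mean_recall_at_50": self.mean_recall_at_50,
        }


def _ranking_metrics(scores: np.ndarray, labels: np.ndarray, k: int = 50) -> dict[str, float]:
    order = np.argsort(-scores, kind="stable")
    topk = labels[order[:k]]
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "average_precision": float(average_precision_score(labels, scores)),
        "recall_at_50": float(topk.sum() / labels.sum()),
    }


def evaluate_rankings(
    rankings: dict[str, list[tuple[str, float]]], positives: TreatmentDataset
) -> EvalReport:
    """Score per-disease ranked candidate lists against approved pairs.

    Diseases with no positive or no negative among their candidates are
    excluded with a warning (AUROC is undefined there).
    """
    per_disease = {}
    for disease, ranked in rankings.items():
        pos = positives.drugs_for(disease)
        labels = np.array([1 if c in pos else 0 for c, _ in ranked])
        if labels.sum() == 0 or labels.sum() == len(labels):
            logger.warning("disease %r skipped: needs >=1 positive and >=1 negative", disease)
            continue
        scores = np.array([s for _, s in ranked])
        per_disease[disease] = _ranking_metrics(scores, labels)
    return EvalReport(per_disease=per_disease)


def drug_folds(drugs: list[str], n_folds: int, seed: int) -> list[list[str]]:
    """Disjoint drug folds covering all drugs, shuffled by seed."""
    rng = np.random.default_rng(seed)
    order = list(np.array(sorted(drugs))[rng.permutation(len(drugs))])
    return [sorted(order[i::n_folds]) for i in range(n_folds)]


def five_fold_cv(
    dataset: TreatmentDataset,
    graph: MultiscaleGraph,
    config: EdgeWeightConfig,
    metric: str,
    seed: int,
    n_folds: int = 5,
    cache: ProfileCache | None = None,
) -> tuple[list[EvalReport], dict[str, float]]:
    """Drug-level cross-validation of treatment ranking.

    Drugs are split into folds; in each fold the held-out evaluation ranks
    only that fold's drugs for every disease (training metrics use the
    remaining drugs).  Returns (reports, summary), the summary averaging the
    held-out aggregates across folds.
    """
    drugs = [c for c in dataset.drugs if c in graph.kinds]
    if len(drugs) < n_folds:
        raise ValueError(f"need >= {n_folds} drugs for {n_folds}-fold CV")
    diseases = [d for d in dataset.diseases if d in graph.kinds]
    cache = cache or ProfileCache()
    profiles = cache.get_many(graph, config, drugs + diseases)

    reports: list[EvalReport] = []
    folds = drug_folds(drugs, n_folds, seed)
    for k, fold in enumerate(folds):
        train = sorted(set(drugs) - set(fold))
        for split, cands in (("held_out", fold), ("train", train)):
            rankings = {d: rank_drugs(d, cands, profiles, metric) for d in diseases}
            rep = evaluate_rankings(rankings, dataset)
            rep.fold, rep.split = k, split
            reports.append(rep)
    held = [r for r in reports if r.split == "held_out" and r.per_disease]
    if len(held) < len(folds):
        logger.warning(
            "%d fold(s) had no evaluable disease and are excluded from the summary",
            len(folds) - len(held),
        )
    if not held:
        raise ValueError("no fold produced an evaluable disease ranking")
    summary = {
        key: float(np.mean([r.aggregates()[key] for r in held]))
        for key in ("median_auroc", "mean_average_precision", "mean_recall_at_50")
    }
    return reports, summary


# -- hyperparameter sweep -----------------------------------------------------


DEFAULT_SWEEP_RANGES: dict[str, tuple[float, float]] = {
    DRUG: (3.0, 9.0),
    DISEASE: (3.0, 9.0),
    PROTEIN: (3.0, 9.0),
    HIGHER_FUNCTION: (1.5, 4.5),
    LOWER_FUNCTION: (1.5, 4.5),
    "alpha": (0.85, 0.90),
}


def sweep_grid(
    ranges: dict[str, tuple[float, float]] | None = None,
    budget: int = 486,
    points_per_axis: int = 3,
    seed: int = 0,
) -> list[EdgeWeightConfig]:
    """Evenly spaced weight grid, sub-sampled to the requested budget.

    Each axis gets ``points_per_axis`` linearly spaced values; the
    cross-product is truncated to ``budget`` configurations by a seeded
    uniform draw.  The function-node weight is tied:
    w_biological_function = w_higher + w_lower.
    """
    ranges = dict(DEFAULT_SWEEP_RANGES if ranges is None else ranges)
    axes = {k: np.linspace(lo, hi, points_per_axis) for k, (lo, hi) in ranges.items()}
    keys = sorted(axes)
    combos = list(itertools.product(*(axes[k] for k in keys)))
    if not combos:
        raise ValueError("empty sweep grid")
    if len(combos) > budget:
        rng = np.random.default_rng(seed)
        combos = [combos[i] for i in sorted(rng.choice(len(combos), budget, replace=False))]
    configs = []
    for combo in combos:
        vals = dict(zip(keys, combo))
        alpha = float(vals.pop("alpha", 0.860))
        weights = {k: float(v) for k, v in vals.items()}
        if HIGHER_FUNCTION in weights and LOWER_FUNCTION in weights:
            weights[FUNCTION] = weights[HIGHER_FUNCTION] + weights[LOWER_FUNCTION]
        configs.append(
            EdgeWeightConfig.from_dict(
                weights, alpha=alpha, tie_function_weights=FUNCTION in weights
            )
        )
    return configs


def weight_sweep(
    dataset: TreatmentDataset,
    graph: MultiscaleGraph,
    configs: list[EdgeWeightConfig],
    metrics: tuple[str, ...] = ALL_METRICS,
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[EdgeWeightConfig, str, pd.DataFrame]:
    """Select (config, metric) maximizing median training AUROC across folds.

    Returns the winning configuration and metric plus the full sweep table
    (one row per configuration x metric).
    """
    if not configs:
        raise ValueError("empty sweep grid")
    rows = []
    best = None
    for config in configs:
        cache = ProfileCache()  # shared across metrics for this config
        for metric in metrics:
            reports, _ = five_fold_cv(
                dataset, graph, config, metric, seed=seed, n_folds=n_folds, cache=cache
            )
            train = [r for r in reports if r.split == "train"]
            score = float(np.mean([r.median_auroc for r in train]))
            row = {**config.as_dict(), "alpha": config.alpha, "metric": metric,
                   "train_median_auroc": score}
            rows.append(row)
            if best is None or score > best[0]:
                best = (score, config, metric)
    table = pd.DataFrame(rows)
    _, best_config, best_metric = best
    return best_config, best_metric, table
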