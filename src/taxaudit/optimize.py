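"""Fallacy-minimizing taxonomy relabelling.

Scales are clustered in embedding space (hierarchical linkages, k-means, or
Gaussian mixtures on L2-normalized vectors, so Euclidean distance is monotone
in cosine), one construct label is assigned to each cluster by maximum-weight
bipartite matching between cluster-mean embeddings and label embeddings, and
each (algorithm, k) solution is scored by the number of jingle and jangle
fallacies its induced scale-to-label mapping produces under fixed thresholds.
The sweep marks the overall fallacy minimum ("optimal") and the minimum
subject to a cap on the number of clusters ("parsimonious").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.mixture import GaussianMixture

from .corpus import ValidationError
from .embed import EmbeddingMatrix, SimilarityMatrix, cross_cosine, embed_cluster
from .fallacies import ThresholdSet, detect_fallacies

__all__ = [
    "ALGORITHMS",
    "ClusterSolution",
    "TradeoffCurve",
    "cluster_scales",
    "max_weight_assignment",
    "assign_labels_matching",
    "evaluate_mapping",
    "sweep_solutions",
    "rank_evaluation",
]

ALGORITHMS = (
    "hierarchical-ward",
    "hierarchical-single",
    "hierarchical-complete",
    "hierarchical-average",
    "kmeans",
    "gaussian-mixture",
)

_LINKAGES = {
    "hierarchical-ward": "ward",
    "hierarchical-single": "single",
    "hierarchical-complete": "complete",
    "hierarchical-average": "average",
}

#: retry budget for mixture fits that return empty components
_GMM_RETRIES = 5


@dataclass
class ClusterSolution:
    """One clustering of scales into k non-empty clusters."""

    algorithm: str
    k: int
    assignment: dict[str, int]  # scale_id -> cluster index 0..k-1
    seed: int

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(self.k)}
        for sid, c in self.assignment.items():
            out[c].append(sid)
        return out


def _normalized(E: EmbeddingMatrix) -> np.ndarray:
    return E.X / np.linalg.norm(E.X, axis=1, keepdims=True)


def cluster_scales(
    scale_embeddings: EmbeddingMatrix, algorithm: str, k: int, seed: int = 0
) -> ClusterSolution:
    """Cluster scales on L2-normalized embeddings into k non-empty clusters.

    Hierarchical linkages and k-means cannot produce empty clusters; mixture
    fits that do are retried with documented seed offsets and rejected after
    the retry budget.  Deterministic given (embeddings, algorithm, k, seed).
    """
    n = scale_embeddings.n
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    if algorithm not in ALGORITHMS:
        raise ValidationError(
            f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}"
        )
    X = _normalized(scale_embeddings)
    if algorithm in _LINKAGES:
        if k == n:
            labels = np.arange(n)
        else:
            model = AgglomerativeClustering(
                n_clusters=k, linkage=_LINKAGES[algorithm], metric="euclidean"
            )
            labels = model.fit_predict(X)
    elif algorithm == "kmeans":
        model = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = model.fit_predict(X)
    else:  # gaussian-mixture
        labels = None
        for attempt in range(_GMM_RETRIES):
            model = GaussianMixture(
                n_components=k,
                covariance_type="spherical",
                random_state=seed + attempt,
                reg_covar=1e-6,
            )
            cand = model.fit_predict(X)
            if len(np.unique(cand)) == k:
                labels = cand
                break
        if labels is None:
            raise ValidationError(
                f"gaussian-mixture with k={k} produced empty components in "
                f"{_GMM_RETRIES} seeded attempts"
            )
    labels = _relabel_consecutive(labels)
    if len(np.unique(labels)) != k:
        raise ValidationError(
            f"{algorithm} returned {len(np.unique(labels))} non-empty clusters, "
            f"expected {k}"
        )
    assignment = {sid: int(c) for sid, c in zip(scale_embeddings.ids, labels)}
    return ClusterSolution(algorithm=algorithm, k=k, assignment=assignment, seed=seed)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster labels by first appearance (stable across backends)."""
    order: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


def cluster_embeddings(
    solution: ClusterSolution, scale_embeddings: EmbeddingMatrix
) -> EmbeddingMatrix:
    """Mean scale embedding per cluster, indexed "cluster:<index>"."""
    rows = []
    ids = []
    for c, members in sorted(solution.members().items()):
        rows.append(embed_cluster(scale_embeddings, members))
        ids.append(f"cluster:{c}")
    return EmbeddingMatrix(tuple(ids), np.stack(rows))


def max_weight_assignment(W: np.ndarray) -> dict[int, int]:
    """Maximum-total-weight injective row -> column assignment.

    Rectangular instances (more columns than rows) are allowed; each column
    is used at most once.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[1] < W.shape[0]:
        raise ValidationError(
            f"{W.shape[1]} columns for {W.shape[0]} rows; need at least as "
            "many columns as rows"
        )
    rows, cols = linear_sum_assignment(W, maximize=True)
    return {int(r): int(c) for r, c in zip(rows, cols)}


def assign_labels_matching(
    solution: ClusterSolution,
    cluster_embs: EmbeddingMatrix,
    label_embs: EmbeddingMatrix,
) -> dict[int, str]:
    """Maximum-total-weight one-to-one label assignment to clusters.

    Weights are cosines between cluster-mean and label embeddings; solved as
    a rectangular linear assignment problem (each label used at most once).
    """
    if label_embs.n < solution.k:
        raise ValidationError(
            f"{label_embs.n} labels for {solution.k} clusters; need at least "
            "as many labels as clusters"
        )
    W = cross_cosine(cluster_embs, label_embs).values
    assignment = max_weight_assignment(W)
    return {r: label_embs.ids[c] for r, c in assignment.items()}


def evaluate_mapping(
    solution: ClusterSolution,
    label_for_cluster: dict[int, str],
    scale_sims: SimilarityMatrix,
    label_sims: SimilarityMatrix,
    thresholds: ThresholdSet,
    pool=None,
) -> dict[str, int]:
    """Fallacy counts of the scale-to-label mapping a solution induces.

    Every scale inherits its cluster's label (so same-cluster pairs have
    label similarity 1); thresholds are held fixed, not re-derived.
    """
    unmapped = [c for c in range(solution.k) if c not in label_for_cluster]
    if unmapped:
        raise ValidationError(f"cluster(s) {unmapped} have no label")
    induced = {
        sid: [label_for_cluster[c]] for sid, c in solution.assignment.items()
    }
    pairs = detect_fallacies(scale_sims, induced, label_sims, thresholds, pool)
    jingle = sum(1 for p in pairs if p.type == "jingle")
    jangle = sum(1 for p in pairs if p.type == "jangle")
    return {"jingle": jingle, "jangle": jangle, "total": jingle + jangle}


@dataclass
class TradeoffCurve:
    """Fallacy counts per (algorithm, k), with optimal/parsimonious flags."""

    table: pd.DataFrame  # algorithm, k, jingle, jangle, total, optimal, parsimonious
    baseline_total: int | None
    cap: int
    errors: dict = field(default_factory=dict)  # (algorithm, k) -> message
    solutions: dict = field(default_factory=dict)  # (algorithm, k) -> (solution, mapping)

    def best(self, flag: str) -> pd.Series:
        rows = self.table[self.table[flag]]
        if rows.empty:
            raise ValidationError(f"no solution flagged {flag!r}")
        return rows.iloc[0]


def sweep_solutions(
    scale_embeddings: EmbeddingMatrix,
    label_embs: EmbeddingMatrix,
    algorithms,
    k_range,
    thresholds: ThresholdSet,
    seed: int = 0,
    scale_sims: SimilarityMatrix | None = None,
    label_sims: SimilarityMatrix | None = None,
    baseline_mapping: dict[str, list[str]] | None = None,
    baseline_label_sims: SimilarityMatrix | None = None,
    cap: int = 100,
    pool=None,
) -> TradeoffCurve:
    """Grid evaluation of clustering solutions and their label mappings.

    For each algorithm and k the scales are clustered, labels assigned by
    maximum-weight matching, and the induced mapping scored with fixed
    thresholds.  Cell failures are recorded and the sweep continues.  The
    row minimizing total fallacies is flagged optimal; the minimum among
    rows with k <= cap is flagged parsimonious (smallest k wins ties).  The
    baseline is the fallacy total of the original scale->label mapping.
    """
    from .embed import pairwise_cosine

    k_range = list(k_range)
    if not k_range:
        raise ValidationError("empty k range")
    if max(k_range) > scale_embeddings.n:
        raise ValidationError("k range exceeds the number of scales")
    if label_embs.n < max(k_range):
        raise ValidationError("need at least max(k_range) labels")
    if scale_sims is None:
        scale_sims = pairwise_cosine(scale_embeddings)
    if label_sims is None:
        label_sims = pairwise_cosine(label_embs)

    records = []
    errors: dict = {}
    solutions: dict = {}
    for algorithm in algorithms:
        for k in k_range:
            try:
                sol = cluster_scales(scale_embeddings, algorithm, k, seed=seed)
                cembs = cluster_embeddings(sol, scale_embeddings)
                mapping = assign_labels_matching(sol, cembs, label_embs)
                counts = evaluate_mapping(
                    sol, mapping, scale_sims, label_sims, thresholds, pool
                )
            except (ValidationError, ValueError) as exc:
                errors[(algorithm, k)] = str(exc)
                continue
            solutions[(algorithm, k)] = (sol, mapping)
            records.append(
                {"algorithm": algorithm, "k": k, **counts}
            )
    if not records:
        raise ValidationError(f"every sweep cell failed: {errors}")
    table = pd.DataFrame.from_records(records)
    table["optimal"] = False
    table["parsimonious"] = False
    # smallest k breaks ties in both flags
    ordered = table.sort_values(["total", "k"], kind="stable")
    table.loc[ordered.index[0], "optimal"] = True
    capped = ordered[ordered["k"] <= cap]
    if not capped.empty:
        table.loc[capped.index[0], "parsimonious"] = True

    baseline_total = None
    if baseline_mapping is not None:
        bls = baseline_label_sims if baseline_label_sims is not None else label_sims
        base_pairs = detect_fallacies(
            scale_sims, baseline_mapping, bls, thresholds, pool
        )
        baseline_total = len(base_pairs)
    return TradeoffCurve(
        table=table, baseline_total=baseline_total, cap=cap,
        errors=errors, solutions=solutions,
    )


def rank_evaluation(
    scale_to_label: dict[str, str],
    scale_embeddings: EmbeddingMatrix,
    label_embs: EmbeddingMatrix,
    top_n: int = 5,
) -> dict[str, float]:
    """How semantically proximate each scale's assigned label is.

    Rank 1 is the label most similar to the scale (ties broken by stable
    label order).  Returns the fraction of scales whose assigned label ranks
    in the top_n and the mean rank of the remaining scales (NaN if none).
    """
    missing = [s for s in scale_embeddings.ids if s not in scale_to_label]
    if missing:
        raise ValidationError(f"scale(s) {missing} have no assigned label")
    W = cross_cosine(scale_embeddings, label_embs).values
    ranks = []
    for i, sid in enumerate(scale_embeddings.ids):
        # stable sort: ties keep the earlier label first
        order = np.argsort(-W[i], kind="stable")
        assigned = label_embs.ids.index(scale_to_label[sid])
        rank = int(np.flatnonzero(order == assigned)[0]) + 1
        ranks.append(rank)
    ranks = np.asarray(ranks)
    top = ranks <= top_n
    mean_sub = float(ranks[~top].mean()) if (~top).any() else float("nan")
    return {
        "fraction_top_n": float(top.mean()),
        "mean_rank_suboptimal": mean_sub,
        "n_top": int(top.sum()),
        "n_scales": int(len(ranks)),
    }
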