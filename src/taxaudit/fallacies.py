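"""Jingle-jangle fallacy detection from scale and label similarities.

A jingle fallacy is a pair of scales with (near-)identical labels but
dissimilar content; a jangle fallacy is a pair with (near-)identical content
but dissimilar labels.  "Identical" and "distinct" are operationalized as
quantile cutoffs of the off-diagonal similarity distribution, derived from
assumed bounds on the true number of constructs: with at least K_min equally
populated constructs, a fraction 1/K_min of pairs is same-construct, so the
1 - 1/K_min quantile separates distinct pairs; the upper bound K_max gives
the identical-pair quantile 1 - 1/K_max the same way.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .corpus import ItemPool, ValidationError
from .embed import SimilarityMatrix

__all__ = [
    "ThresholdSet",
    "FallacyPair",
    "FallacySummary",
    "derive_thresholds",
    "pair_label_similarity",
    "detect_fallacies",
    "summarize_fallacies",
]


@dataclass(frozen=True)
class ThresholdSet:
    """Construct-count bounds and the realized similarity cutoffs.

    q_distinct = 1 - 1/K_min and q_identical = 1 - 1/K_max are the quantile
    levels; the cut_* fields are the realized similarity cutoffs for scales
    ("measures") and labels ("constructs").
    """

    k_min: int
    k_max: int
    q_distinct: float
    q_identical: float
    cut_scale_distinct: float
    cut_scale_identical: float
    cut_label_distinct: float
    cut_label_identical: float

    def __post_init__(self) -> None:
        if self.k_min < 2:
            raise ValidationError("K_min must be >= 2")
        if self.k_max <= self.k_min:
            raise ValidationError("K_max must exceed K_min")
        if not self.q_distinct < self.q_identical:
            raise ValidationError("q_distinct must be below q_identical")
        if self.cut_scale_distinct > self.cut_scale_identical:
            raise ValidationError("scale cutoffs out of order")
        if self.cut_label_distinct > self.cut_label_identical:
            raise ValidationError("label cutoffs out of order")

    @staticmethod
    def quantile_levels(k_min: int, k_max: int) -> tuple[float, float]:
        """Quantile levels implied by the construct-count bounds."""
        if k_min < 2 or k_max <= k_min:
            raise ValidationError("need 2 <= K_min < K_max")
        return 1.0 - 1.0 / k_min, 1.0 - 1.0 / k_max

    @classmethod
    def default(cls) -> "ThresholdSet":
        """Fixed default cutoffs for K_min=5 / K_max=100.

        The realized cosine cutoffs (0.37/0.64 for scales, 0.25/0.50 for
        labels) are the conventional values calibrated on large personality
        item pools; use derive_thresholds to re-derive them from data with a
        non-degenerate similarity distribution.
        """
        return cls(
            k_min=5,
            k_max=100,
            q_distinct=0.8,
            q_identical=0.99,
            cut_scale_distinct=0.37,
            cut_scale_identical=0.64,
            cut_label_distinct=0.25,
            cut_label_identical=0.50,
        )


def derive_thresholds(
    scale_sims: SimilarityMatrix,
    label_sims: SimilarityMatrix,
    k_min: int = 5,
    k_max: int = 100,
) -> ThresholdSet:
    """Realize the quantile cutoffs on the observed similarity distributions.

    Cutoffs are linear-interpolation empirical quantiles of the unique
    unordered off-diagonal similarities, computed separately for the scale
    and label matrices.  Constant distributions are rejected.
    """
    q_distinct, q_identical = ThresholdSet.quantile_levels(k_min, k_max)
    cuts = {}
    for name, S in (("scale", scale_sims), ("label", label_sims)):
        vals = S.off_diagonal_values()
        if vals.size < 2:
            raise ValidationError(f"{name} matrix has < 2 off-diagonal values")
        if np.ptp(vals) == 0:
            raise ValidationError(
                f"degenerate {name} similarity distribution (all values equal); "
                "supply explicit cutoffs instead"
            )
        cuts[f"cut_{name}_distinct"] = float(
            np.quantile(vals, q_distinct, method="linear")
        )
        cuts[f"cut_{name}_identical"] = float(
            np.quantile(vals, q_identical, method="linear")
        )
    return ThresholdSet(
        k_min=k_min, k_max=k_max,
        q_distinct=q_distinct, q_identical=q_identical, **cuts,
    )


@dataclass(frozen=True)
class FallacyPair:
    """One detected candidate fallacy between two scales."""

    scale_a: str
    scale_b: str
    type: str  # "jingle" | "jangle"
    scale_sim: float
    label_sim: float
    shared_items: int
    labels_a: tuple[str, ...] = ()
    labels_b: tuple[str, ...] = ()

    @property
    def pair(self) -> frozenset:
        return frozenset((self.scale_a, self.scale_b))


def pair_label_similarity(
    scale_a: str,
    scale_b: str,
    mapping: dict[str, list[str]],
    label_sims: SimilarityMatrix,
) -> float:
    """Label similarity of a scale pair under compound labels.

    Takes the maximum label-label cosine over the cross product of the two
    scales' constituent single labels; a shared single label gives 1.
    """
    for sid in (scale_a, scale_b):
        if sid not in mapping:
            raise ValidationError(f"scale {sid!r} has no label mapping")
    best = -np.inf
    for la in mapping[scale_a]:
        for lb in mapping[scale_b]:
            best = max(best, 1.0 if la == lb else label_sims.get(la, lb))
    return float(best)


def detect_fallacies(
    scale_sims: SimilarityMatrix,
    mapping: dict[str, list[str]],
    label_sims: SimilarityMatrix,
    thresholds: ThresholdSet,
    pool: ItemPool | None = None,
) -> list[FallacyPair]:
    """Evaluate every unordered scale pair against the fallacy criteria.

    jingle: label_sim >= cut_label_identical and scale_sim <= cut_scale_distinct.
    jangle: scale_sim >= cut_scale_identical and label_sim <= cut_label_distinct.
    Comparisons are inclusive; because the distinct cutoff lies below the
    identical cutoff, a pair can satisfy at most one criterion.  Shared item
    counts are attached when a pool is given.
    """
    missing = [s for s in scale_sims.row_ids if s not in mapping]
    if missing:
        raise ValidationError(f"mapping is missing scale(s) {missing}")
    pairs: list[FallacyPair] = []
    for a, b in itertools.combinations(scale_sims.row_ids, 2):
        ssim = scale_sims.get(a, b)
        lsim = pair_label_similarity(a, b, mapping, label_sims)
        if lsim >= thresholds.cut_label_identical and ssim <= thresholds.cut_scale_distinct:
            ftype = "jingle"
        elif ssim >= thresholds.cut_scale_identical and lsim <= thresholds.cut_label_distinct:
            ftype = "jangle"
        else:
            continue
        shared = 0
        if pool is not None and a in pool.scales and b in pool.scales:
            shared = len(
                set(pool.scales[a].item_ids) & set(pool.scales[b].item_ids)
            )
        pairs.append(
            FallacyPair(
                scale_a=a, scale_b=b, type=ftype,
                scale_sim=ssim, label_sim=lsim, shared_items=shared,
                labels_a=tuple(mapping[a]), labels_b=tuple(mapping[b]),
            )
        )
    return pairs


@dataclass
class FallacySummary:
    """Aggregate description of a detected fallacy set."""

    n_jingle: int
    n_jangle: int
    label_participation: dict[str, int]  # label -> number of pairs it occurs in
    mean_shared_items_jangle: float  # NaN when no jangle pairs
    mean_possible_overlap_jangle: float  # mean min(scale sizes); NaN if none
    n_jangle_zero_overlap: int
    overlap_similarity_r: float  # r(shared items, scale sim) over all pairs


def summarize_fallacies(
    pairs: list[FallacyPair],
    pool: ItemPool | None = None,
    scale_sims: SimilarityMatrix | None = None,
) -> FallacySummary:
    """Counts, item-overlap statistics, and label participation."""
    jingles = [p for p in pairs if p.type == "jingle"]
    jangles = [p for p in pairs if p.type == "jangle"]
    participation: dict[str, int] = {}
    for p in pairs:
        for lab in set(p.labels_a) | set(p.labels_b):
            participation[lab] = participation.get(lab, 0) + 1

    if jangles and pool is not None:
        shared = [p.shared_items for p in jangles]
        possible = [
            min(pool.scales[p.scale_a].n_items, pool.scales[p.scale_b].n_items)
            for p in jangles
        ]
        mean_shared = float(np.mean(shared))
        mean_possible = float(np.mean(possible))
        zero_overlap = sum(1 for s in shared if s == 0)
    else:
        mean_shared = float("nan")
        mean_possible = float("nan")
        zero_overlap = sum(1 for p in jangles if p.shared_items == 0)

    r = float("nan")
    if pool is not None and scale_sims is not None:
        xs, ys = [], []
        for a, b in itertools.combinations(scale_sims.row_ids, 2):
            if a in pool.scales and b in pool.scales:
                xs.append(
                    len(set(pool.scales[a].item_ids) & set(pool.scales[b].item_ids))
                )
                ys.append(scale_sims.get(a, b))
        if len(xs) >= 3 and np.ptp(xs) > 0 and np.ptp(ys) > 0:
            r = float(stats.pearsonr(xs, ys)[0])

    return FallacySummary(
        n_jingle=len(jingles),
        n_jangle=len(jangles),
        label_participation=participation,
        mean_shared_items_jangle=mean_shared,
        mean_possible_overlap_jangle=mean_possible,
        n_jangle_zero_overlap=zero_overlap,
        overlap_similarity_r=r,
    )
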