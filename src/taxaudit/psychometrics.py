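"""Validation statistics linking semantic similarity to psychometric structure.

Internal consistency is predicted from mean inter-item similarity through the
Spearman-Brown prophecy formula; structural fidelity contrasts a scale's
within-scale item similarity against its cross-scale similarities inside the
same inventory as a z-score (z > 2 fully recovered, z > 1 partially);
scale-label alignment z-scores a scale's similarity to its assigned label
against non-assigned reference labels.  Empirical counterparts (Cronbach's
alpha on response data, fidelity ratios and prediction error on observed
correlations) quantify how well the semantic predictions track real data.

Conventions: means over unordered distinct pairs; sample (n-1) denominators
for every standard deviation; absolute values of empirical correlations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import ItemPool, Scale, ValidationError
from .embed import SimilarityMatrix

__all__ = [
    "ScaleSimilaritySummary",
    "FidelityResult",
    "AlignmentResult",
    "within_scale_similarity",
    "predict_alpha",
    "cronbach_alpha",
    "scale_similarity_summaries",
    "structural_fidelity",
    "empirical_fidelity_ratio",
    "alignment_score",
    "mean_alignment",
    "prediction_error",
]

#: spreads below this are treated as zero (z-score undefined), absorbing
#: floating-point noise from means of identical similarities
_ZERO_SPREAD = 1e-12


@dataclass
class ScaleSimilaritySummary:
    """Within- and between-scale mean item similarities for one scale."""

    scale_id: str
    within: float
    between: dict[str, float]  # other scale_id -> mean cross-scale similarity
    n_items: int


@dataclass
class FidelityResult:
    """Structural-fidelity z-score for one scale.

    status: "full" (z > 2), "partial" (1 < z <= 2), "none" (z <= 1), or
    "undefined" when the cross-scale similarities have zero spread.
    """

    scale_id: str
    z: float
    status: str

    @staticmethod
    def classify(z: float) -> str:
        if not np.isfinite(z):
            return "undefined"
        if z > 2:
            return "full"
        if z > 1:
            return "partial"
        return "none"


@dataclass
class AlignmentResult:
    """Scale-label alignment z-score for one scale."""

    scale_id: str
    label_id: str
    z: float
    label_sims: dict[str, float]  # label_id -> mean item-label similarity


def within_scale_similarity(S_items: SimilarityMatrix, scale: Scale) -> float:
    """Mean similarity over the scale's unordered distinct item pairs."""
    if scale.n_items < 2:
        raise ValidationError(f"scale {scale.scale_id!r} has < 2 items")
    vals = [
        S_items.get(a, b) for a, b in itertools.combinations(scale.item_ids, 2)
    ]
    return float(np.mean(vals))


def predict_alpha(S: float, N: int) -> float:
    """Spearman-Brown predicted reliability: alpha = N*S / (1 + (N-1)*S)."""
    if N < 2:
        raise ValidationError("Spearman-Brown prediction needs N >= 2 items")
    denom = 1.0 + (N - 1) * S
    if denom <= 0:
        raise ValidationError(
            f"Spearman-Brown denominator {denom:.4g} <= 0 (S={S:.4g}, N={N})"
        )
    return float(N * S / denom)


def cronbach_alpha(responses: pd.DataFrame, scale: Scale) -> float:
    """Cronbach's alpha from observed ratings, listwise-complete rows.

    alpha = N/(N-1) * (1 - sum of item variances / variance of the sum score),
    with sample (n-1) variances.
    """
    if scale.n_items < 2:
        raise ValidationError(f"scale {scale.scale_id!r} has < 2 items")
    missing = [i for i in scale.item_ids if i not in responses.columns]
    if missing:
        raise ValidationError(
            f"scale {scale.scale_id!r}: no responses for item(s) {missing}"
        )
    R = responses[list(scale.item_ids)].dropna(axis=0, how="any")
    if len(R) < 3:
        raise ValidationError(
            f"scale {scale.scale_id!r}: fewer than 3 complete respondent rows"
        )
    N = scale.n_items
    item_var = R.var(axis=0, ddof=1).sum()
    total_var = R.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValidationError(
            f"scale {scale.scale_id!r}: zero total-score variance"
        )
    return float(N / (N - 1) * (1.0 - item_var / total_var))


def _mean_cross_similarity(S: SimilarityMatrix, a: Scale, b: Scale) -> float:
    """Mean similarity over all item pairs across two different scales."""
    sub = np.array(
        [[S.get(i, j) for j in b.item_ids] for i in a.item_ids], dtype=float
    )
    return float(sub.mean())


def scale_similarity_summaries(
    S_items: SimilarityMatrix, scales: list[Scale]
) -> list[ScaleSimilaritySummary]:
    """Within- and between-scale mean item similarities for each scale."""
    out = []
    for a in scales:
        between = {
            b.scale_id: _mean_cross_similarity(S_items, a, b)
            for b in scales
            if b.scale_id != a.scale_id
        }
        out.append(
            ScaleSimilaritySummary(
                scale_id=a.scale_id,
                within=within_scale_similarity(S_items, a),
                between=between,
                n_items=a.n_items,
            )
        )
    return out


def structural_fidelity(
    S_items: SimilarityMatrix, scales: list[Scale]
) -> list[FidelityResult]:
    """Structural-fidelity z-scores for every scale of one inventory.

    For scale j, z = (W_j - mean(B_j)) / sd(B_j) where W_j is the mean
    within-scale item similarity and B_j collects the mean cross-scale item
    similarities to every other scale in the inventory (sample sd).  The
    inventory needs at least 3 scales so that sd(B_j) exists.
    """
    if len(scales) < 3:
        raise ValidationError(
            "structural fidelity needs an inventory with >= 3 scales"
        )
    invs = {s.inventory_id for s in scales}
    if len(invs) > 1:
        raise ValidationError(
            f"scales span multiple inventories {sorted(invs)}; fidelity is "
            "defined within one inventory"
        )
    results = []
    for summ in scale_similarity_summaries(S_items, scales):
        B = np.array(list(summ.between.values()), dtype=float)
        sd = B.std(ddof=1)
        z = (summ.within - B.mean()) / sd if sd > _ZERO_SPREAD else float("nan")
        results.append(
            FidelityResult(scale_id=summ.scale_id, z=z,
                           status=FidelityResult.classify(z))
        )
    return results


def empirical_fidelity_ratio(
    item_correlations: SimilarityMatrix, scales: list[Scale]
) -> dict[str, float]:
    """Within mean |r| divided by the strongest mean |r| for each scale.

    The maximum runs over all scales of the inventory including the scale
    itself, so the ratio is 1 exactly when the within correlation is the
    strongest.  Correlations enter in absolute value.
    """
    if len(scales) < 2:
        raise ValidationError("fidelity ratio needs an inventory with >= 2 scales")
    absS = SimilarityMatrix(
        item_correlations.row_ids,
        item_correlations.col_ids,
        np.abs(item_correlations.values),
        calibrated=item_correlations.calibrated,
    )
    ratios: dict[str, float] = {}
    for summ in scale_similarity_summaries(absS, scales):
        strongest = max([summ.within, *summ.between.values()])
        if strongest <= 0:
            raise ValidationError(
                f"scale {summ.scale_id!r}: all mean |r| are zero; ratio undefined"
            )
        ratios[summ.scale_id] = summ.within / strongest
    return ratios


def alignment_score(
    S_item_label: SimilarityMatrix,
    scale: Scale,
    assigned: str,
    reference_labels: list[str],
) -> AlignmentResult:
    """Z-score of the assigned label's similarity against reference labels.

    S_jl is the mean similarity between the scale's items and label l; the
    z-score contrasts the assigned label against the mean and sample sd of
    the non-assigned reference labels (>= 3 of them required).
    """
    refs = [l for l in reference_labels if l != assigned]
    if len(refs) < 3:
        raise ValidationError(
            "alignment needs >= 3 reference labels besides the assigned one"
        )
    sims = {
        l: float(np.mean([S_item_label.get(i, l) for i in scale.item_ids]))
        for l in [assigned, *refs]
    }
    others = np.array([sims[l] for l in refs], dtype=float)
    sd = others.std(ddof=1)
    z = (sims[assigned] - others.mean()) / sd if sd > _ZERO_SPREAD else float("nan")
    return AlignmentResult(
        scale_id=scale.scale_id, label_id=assigned, z=z, label_sims=sims
    )


def mean_alignment(
    results: list[AlignmentResult], label_subset: set[str] | None = None
) -> float:
    """Mean alignment z over scales (optionally restricted by assigned label)."""
    kept = [
        r for r in results
        if label_subset is None or r.label_id in label_subset
    ]
    if not kept:
        raise ValidationError("no alignment results after subsetting")
    return float(np.mean([r.z for r in kept]))


def prediction_error(
    predicted: SimilarityMatrix, observed: SimilarityMatrix
) -> dict[str, float]:
    """MAE and Pearson r of predicted vs absolute observed correlations.

    Both matrices must be square over the same id set; self-pairs are
    excluded and observed values enter in absolute value.
    """
    if set(predicted.row_ids) != set(observed.row_ids):
        raise ValidationError("predicted and observed id sets differ")
    order = list(predicted.row_ids)
    oidx = [observed.row_ids.index(i) for i in order]
    obs = np.abs(observed.values[np.ix_(oidx, oidx)])
    iu = np.triu_indices(len(order), k=1)
    p = predicted.values[iu]
    o = obs[iu]
    if p.size < 3:
        raise ValidationError("prediction error needs >= 3 off-diagonal pairs")
    if np.ptp(p) == 0 or np.ptp(o) == 0:
        raise ValidationError("correlation undefined for constant vectors")
    r, _ = stats.pearsonr(p, o)
    return {"mae": float(np.mean(np.abs(p - o))), "pearson_r": float(r)}
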