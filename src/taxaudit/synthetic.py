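"""Synthetic planted taxonomies and response data.

The generator emulates the statistical structure the pipeline assumes: K
construct directions in embedding space, m scales per construct scattered
around each direction, p items per scale scattered around each scale vector,
and one label per construct near its direction.  With all noise levels at
zero, items equal their construct direction, within-construct similarity is
exactly 1 and between-construct similarity exactly 0 (directions are
orthonormalized), which makes ground truth exact and recovery properties
testable without any external data or model.

Fallacies are planted by label surgery that leaves everything else intact:
a jingle planting copies one construct's label (plus optional noise) onto
all scales of a distant construct; a jangle planting relabels one scale of
a construct with a label placed at the antipode of its own direction
(cosine -1 to its sibling's label, cosine ~0 to everything else).  Both
constructions have no side effects, so the returned ground-truth pair list
is exhaustive.

Respondent data are drawn from a multivariate normal whose correlation
matrix is the (calibrated) item similarity matrix repaired to the nearest
valid correlation matrix, optionally discretized to equiprobable Likert
levels.  All randomness descends from one user seed through named child
seeds (directions/scales/items/labels for the taxonomy; selection/noise for
planting; one stream for responses).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .corpus import Item, ItemPool, LabelCatalog, LabelEntry, Scale, ValidationError
from .embed import EmbeddingMatrix, calibrate_similarity, pairwise_cosine

__all__ = [
    "PlantedTaxonomy",
    "PlantedFallacySet",
    "generate_taxonomy",
    "plant_fallacies",
    "generate_responses",
    "exchangeable_item_embeddings",
]


@dataclass
class PlantedTaxonomy:
    """A synthetic taxonomy with known construct structure."""

    K: int
    m: tuple[int, ...]  # scales per construct
    p: int  # items per scale
    dim: int
    sigma_scale: float
    sigma_item: float
    sigma_label: float
    separation: float
    seed: int
    directions: np.ndarray  # K x dim orthonormal construct directions
    item_embeddings: EmbeddingMatrix
    label_embeddings: EmbeddingMatrix
    pool: ItemPool
    mapping: dict[str, list[str]]  # scale_id -> [label_id]
    scale_construct: dict[str, int]  # scale_id -> construct index

    @property
    def scale_ids(self) -> list[str]:
        return list(self.pool.scales)

    def construct_scales(self, c: int) -> list[str]:
        return [s for s, cc in self.scale_construct.items() if cc == c]

    @property
    def scale_embeddings(self) -> EmbeddingMatrix:
        """Scale embeddings the pipeline way: sum of member item embeddings."""
        rows = []
        for sid in self.scale_ids:
            sub = self.item_embeddings.subset(self.pool.scales[sid].item_ids)
            rows.append(sub.X.sum(axis=0))
        return EmbeddingMatrix(tuple(self.scale_ids), np.stack(rows))

    @property
    def catalog(self) -> LabelCatalog:
        entries = [LabelEntry(label_id=l, text=l) for l in self.label_embeddings.ids]
        return LabelCatalog(
            entries=entries,
            compound_map={l: [l] for l in self.label_embeddings.ids},
        )


@dataclass
class PlantedFallacySet:
    """Exhaustive ground truth for planted fallacies."""

    jingle: list[frozenset] = field(default_factory=list)
    jangle: list[frozenset] = field(default_factory=list)

    @property
    def n_jingle(self) -> int:
        return len(self.jingle)

    @property
    def n_jangle(self) -> int:
        return len(self.jangle)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("cannot normalize a zero vector")
    return v / n


def _noisy(base: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """normalize(base + sigma * u) with u a random unit direction.

    The draw is consumed even at sigma = 0 so that the same seed produces
    the same noise directions across different sigma values (this is what
    makes detection sensitivity monotone along a sigma grid).
    """
    u = _unit(rng.standard_normal(base.shape[0]))
    return _unit(base + sigma * u)


def generate_taxonomy(
    K: int,
    m: int | tuple[int, ...] = 2,
    p: int = 4,
    dim: int = 64,
    sigma_scale: float = 0.0,
    sigma_item: float = 0.0,
    sigma_label: float = 0.0,
    separation: float = 1.0,
    seed: int = 0,
) -> PlantedTaxonomy:
    """Generate a planted taxonomy of K constructs.

    Construct directions are orthonormalized random vectors, so every pair
    has cosine 0 (requires dim >= K and separation <= 1).  Scale vectors are
    unit-normalized direction + N(0, sigma_scale) perturbations, item vectors
    likewise around their scale vector, and each construct gets one label at
    noise sigma_label around its direction.  Fully reproducible from seed.
    """
    if K < 2:
        raise ValidationError("need K >= 2 constructs")
    m_per = tuple([m] * K) if isinstance(m, int) else tuple(int(x) for x in m)
    if len(m_per) != K or any(x < 1 for x in m_per):
        raise ValidationError("m must be a positive int or a length-K sequence")
    if p < 2:
        raise ValidationError("need p >= 2 items per scale")
    if dim < K:
        raise ValidationError(
            f"dim={dim} < K={K}: orthogonal construct placement impossible"
        )
    if not 0 < separation <= 1:
        raise ValidationError(
            "separation must lie in (0, 1]; orthogonalized directions have "
            "pairwise cosine 0"
        )
    ss = np.random.SeedSequence(seed)
    rng_dir, rng_scale, rng_item, rng_label = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    Q, _ = np.linalg.qr(rng_dir.standard_normal((dim, K)))
    directions = Q.T  # K x dim, orthonormal rows

    items: dict[str, Item] = {}
    scales: dict[str, Scale] = {}
    item_ids: list[str] = []
    item_rows: list[np.ndarray] = []
    mapping: dict[str, list[str]] = {}
    scale_construct: dict[str, int] = {}
    label_ids: list[str] = []
    label_rows: list[np.ndarray] = []

    for c in range(K):
        label_id = f"label_c{c:02d}"
        label_ids.append(label_id)
        label_rows.append(_noisy(directions[c], sigma_label, rng_label))
        for s in range(m_per[c]):
            sid = f"c{c:02d}_s{s}"
            svec = _noisy(directions[c], sigma_scale, rng_scale)
            iids = []
            for i in range(p):
                iid = f"{sid}_i{i}"
                iids.append(iid)
                item_ids.append(iid)
                item_rows.append(_noisy(svec, sigma_item, rng_item))
                items[iid] = Item(
                    item_id=iid,
                    text=f"synthetic item {iid}",
                    scale_id=sid,
                    inventory_id="synthetic",
                    key=1,
                )
            scales[sid] = Scale(
                scale_id=sid,
                inventory_id="synthetic",
                item_ids=tuple(iids),
                label_compound=label_id,
            )
            mapping[sid] = [label_id]
            scale_construct[sid] = c

    return PlantedTaxonomy(
        K=K, m=m_per, p=p, dim=dim,
        sigma_scale=sigma_scale, sigma_item=sigma_item, sigma_label=sigma_label,
        separation=separation, seed=seed,
        directions=directions,
        item_embeddings=EmbeddingMatrix(tuple(item_ids), np.stack(item_rows)),
        label_embeddings=EmbeddingMatrix(tuple(label_ids), np.stack(label_rows)),
        pool=ItemPool(items=items, scales=scales),
        mapping=mapping,
        scale_construct=scale_construct,
    )


def plant_fallacies(
    taxonomy: PlantedTaxonomy,
    n_jingle: int,
    n_jangle: int,
    seed: int = 0,
    sigma_label: float | None = None,
) -> tuple[PlantedTaxonomy, PlantedFallacySet]:
    """Plant exact numbers of jingle and jangle fallacy pairs.

    Each jingle planting consumes two fresh constructs (A, B) and assigns a
    noisy copy of A's label to all of B's scales, contributing m_A * m_B
    ground-truth jingle pairs.  Each jangle planting consumes one fresh
    construct with >= 2 scales and relabels its last scale with a label at
    the antipode of the construct direction, contributing m - 1 ground-truth
    jangle pairs.  Constructs are never reused, so plantings cannot interact;
    an error is raised when the requested pair counts cannot be hit exactly
    with the taxonomy's per-construct scale counts.
    """
    if n_jingle < 0 or n_jangle < 0:
        raise ValidationError("planting counts must be non-negative")
    sigma = taxonomy.sigma_label if sigma_label is None else sigma_label
    ss = np.random.SeedSequence(seed)
    rng_select, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    avail = list(range(taxonomy.K))
    rng_select.shuffle(avail)

    mapping = {s: list(v) for s, v in taxonomy.mapping.items()}
    label_ids = list(taxonomy.label_embeddings.ids)
    label_rows = list(taxonomy.label_embeddings.X)
    planted = PlantedFallacySet()

    # jangle plantings are served first: they specifically need constructs
    # with >= 2 scales, which jingle plantings could otherwise use up
    count = 0
    j = 0
    while count < n_jangle:
        remaining = n_jangle - count
        # greedy largest fit keeps the pair count exactly reachable
        eligible = [cc for cc in avail if 2 <= taxonomy.m[cc] <= remaining + 1]
        if not eligible:
            raise ValidationError(
                "cannot plant the requested fallacies exactly: no construct "
                f"with 2..{remaining + 1} scales left for a jangle planting"
            )
        c = max(eligible, key=lambda cc: (taxonomy.m[cc], -avail.index(cc)))
        avail.remove(c)
        members = taxonomy.construct_scales(c)
        victim = members[-1]
        lid = f"planted_jangle_{j}"
        label_ids.append(lid)
        label_rows.append(_noisy(-taxonomy.directions[c], sigma, rng_noise))
        mapping[victim] = [lid]
        for sib in members[:-1]:
            planted.jangle.append(frozenset((sib, victim)))
        count += len(members) - 1
        j += 1

    count = 0
    j = 0
    while count < n_jingle:
        remaining = n_jingle - count
        # choose the construct pair with the largest cross-pair count that
        # still fits, so the requested total is hit exactly when possible
        candidates = [
            (a, b)
            for i, a in enumerate(avail)
            for b in avail[i + 1:]
            if taxonomy.m[a] * taxonomy.m[b] <= remaining
        ]
        if not candidates:
            raise ValidationError(
                "cannot plant the requested fallacies exactly: no construct "
                f"pair with <= {remaining} cross pair(s) left for a jingle "
                "planting"
            )
        a, b = max(candidates, key=lambda ab: taxonomy.m[ab[0]] * taxonomy.m[ab[1]])
        avail.remove(a)
        avail.remove(b)
        base = taxonomy.label_embeddings.row(f"label_c{a:02d}")
        lid = f"planted_jingle_{j}"
        label_ids.append(lid)
        label_rows.append(_noisy(base, sigma, rng_noise))
        for sid in taxonomy.construct_scales(b):
            mapping[sid] = [lid]
        for sa in taxonomy.construct_scales(a):
            for sb in taxonomy.construct_scales(b):
                planted.jingle.append(frozenset((sa, sb)))
        count += taxonomy.m[a] * taxonomy.m[b]
        j += 1

    modified = replace(
        taxonomy,
        mapping=mapping,
        label_embeddings=EmbeddingMatrix(tuple(label_ids), np.stack(label_rows)),
    )
    return modified, planted


def _nearest_correlation(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped, diagonal-renormalized repair of a target matrix."""
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    w_clipped = np.clip(w, 0.0, None)
    R = (V * w_clipped) @ V.T
    d = np.sqrt(np.clip(np.diag(R), 1e-12, None))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0
    return R, float(np.max(np.abs(R - C)))


def generate_responses(
    item_embeddings: EmbeddingMatrix,
    n: int,
    calibration: list[tuple[float, float]] | None = None,
    seed: int = 0,
    likert_levels: int | None = None,
    repair_tolerance: float = 0.1,
) -> pd.DataFrame:
    """Draw synthetic respondent ratings whose correlations match similarities.

    The target correlation matrix is the (optionally calibrated) pairwise
    item cosine matrix, repaired to the nearest valid correlation matrix by
    eigenvalue clipping and diagonal renormalization.  n multivariate-normal
    respondent vectors are drawn; with likert_levels the standard-normal
    margins are cut at equiprobable quantiles into levels 1..L.  The maximum
    entry change incurred by the repair is recorded in ``attrs`` and flagged
    as a warning when it exceeds repair_tolerance.
    """
    if n < 10:
        raise ValidationError("need n >= 10 respondents")
    if likert_levels is not None and likert_levels < 2:
        raise ValidationError("likert_levels must be >= 2")
    S = pairwise_cosine(item_embeddings)
    if calibration:
        S = calibrate_similarity(S, calibration)
    target = np.clip(S.values, -1.0, 1.0)
    np.fill_diagonal(target, 1.0)
    C, max_delta = _nearest_correlation(target)

    w, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    Z = rng.standard_normal((n, C.shape[0]))
    X = Z @ L.T

    if likert_levels is not None:
        cuts = norm.ppf(np.arange(1, likert_levels) / likert_levels)
        X = (np.digitize(X, cuts) + 1).astype(float)

    df = pd.DataFrame(
        X,
        index=[f"r{i}" for i in range(n)],
        columns=list(item_embeddings.ids),
    )
    df.attrs["repair_max_delta"] = max_delta
    df.attrs["repair_warning"] = bool(max_delta > repair_tolerance)
    return df


def exchangeable_item_embeddings(
    p: int, rho: float, dim: int | None = None, prefix: str = "item"
) -> EmbeddingMatrix:
    """p unit vectors with every pairwise cosine exactly rho.

    Construction: v_i = sqrt(rho) * e0 + sqrt(1 - rho) * e_i on orthonormal
    axes, valid for 0 <= rho <= 1.  Useful for parameter-recovery tests with
    an exchangeable within-scale correlation.
    """
    if not 0 <= rho <= 1:
        raise ValidationError("rho must lie in [0, 1]")
    if dim is None:
        dim = p + 1
    if dim < p + 1:
        raise ValidationError("need dim >= p + 1")
    X = np.zeros((p, dim))
    X[:, 0] = np.sqrt(rho)
    for i in range(p):
        X[i, i + 1] = np.sqrt(1.0 - rho)
    return EmbeddingMatrix(tuple(f"{prefix}{i}" for i in range(p)), X)
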