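"""Semantic vector space: encoders, aggregation, cosine similarity, calibration.

Item texts are encoded to unit vectors; scale embeddings are the element-wise
sum of their item embeddings (cosine-equivalent to the mean); cluster
embeddings are the mean of member scale embeddings; label embeddings encode
either the bare label, a contextualizing template sentence, or a definition
text.  All similarity throughout the package is cosine similarity, optionally
calibrated to the empirical-correlation scale by an affine map fitted on
(cosine, mean |r|) anchor pairs.

The default encoder backend is a deterministic stub that maps each distinct
text to a seeded pseudo-random unit vector.  It carries no semantics; it
exists so every pipeline stage runs reproducibly without model downloads.
Real analyses should use the external sentence-transformer backend.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import LabelEntry, Scale, ValidationError

__all__ = [
    "BackendError",
    "MissingVariantError",
    "EncoderConfig",
    "EmbeddingMatrix",
    "SimilarityMatrix",
    "encode_texts",
    "embed_scale",
    "embed_label",
    "embed_cluster",
    "cosine",
    "pairwise_cosine",
    "cross_cosine",
    "calibrate_similarity",
]

DEFAULT_TEMPLATE = "The personality construct [LABEL]."
_PLACEHOLDER = "[LABEL]"


class BackendError(RuntimeError):
    """The requested encoder backend is unavailable or failed."""


class MissingVariantError(ValueError):
    """A label variant was requested for which no text exists."""


@dataclass(frozen=True)
class EncoderConfig:
    """How texts are turned into vectors.

    backend "stub" uses a seeded text-keyed pseudo-random projection of the
    given dimension; backend "external-model" encodes with a
    sentence-transformers model named by ``model`` (optional dependency).
    """

    backend: str = "stub"
    model: str | None = None
    seed: int = 0
    dim: int = 64
    template: str = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        if self.backend not in ("stub", "external-model"):
            raise ValidationError(f"unknown encoder backend {self.backend!r}")
        if self.backend == "stub" and self.dim < 2:
            raise ValidationError("stub encoder dimension must be >= 2")
        if self.backend == "external-model" and not self.model:
            raise ValidationError("external-model backend requires a model name")
        if _PLACEHOLDER not in self.template:
            raise ValidationError(
                f"label template must contain the placeholder {_PLACEHOLDER!r}"
            )


@dataclass
class EmbeddingMatrix:
    """Id-indexed real vectors; one fixed dimension per matrix."""

    ids: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(str(i) for i in self.ids)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.ids):
            raise ValidationError(
                f"embedding shape {self.X.shape} does not match {len(self.ids)} ids"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate embedding row ids")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError("non-finite embedding entries")
        norms = np.linalg.norm(self.X, axis=1)
        if np.any(norms == 0):
            zero = [self.ids[i] for i in np.flatnonzero(norms == 0)]
            raise ValidationError(f"all-zero embedding row(s): {zero}")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def row(self, rid: str) -> np.ndarray:
        try:
            return self.X[self._index[rid]]
        except KeyError:
            raise KeyError(f"no embedding for id {rid!r}") from None

    def subset(self, ids) -> "EmbeddingMatrix":
        ids = [str(i) for i in ids]
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise ValidationError(f"no embedding for id(s) {missing}")
        return EmbeddingMatrix(tuple(ids), self.X[[self._index[i] for i in ids]])


@dataclass
class SimilarityMatrix:
    """Cosine similarities between two id sets (square when they coincide)."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    values: np.ndarray
    calibrated: bool = False
    _rindex: dict = field(init=False, repr=False)
    _cindex: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.row_ids = tuple(str(i) for i in self.row_ids)
        self.col_ids = tuple(str(i) for i in self.col_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"similarity shape {self.values.shape} does not match ids"
            )
        self._rindex = {r: i for i, r in enumerate(self.row_ids)}
        self._cindex = {c: i for i, c in enumerate(self.col_ids)}

    @property
    def square(self) -> bool:
        return self.row_ids == self.col_ids

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._rindex[str(a)], self._cindex[str(b)]])

    def off_diagonal_values(self) -> np.ndarray:
        """Unique unordered off-diagonal entries (square matrices only)."""
        if not self.square:
            raise ValidationError("off-diagonal values need a square matrix")
        iu = np.triu_indices(len(self.row_ids), k=1)
        return self.values[iu]


def _stub_vector(text: str, seed: int, dim: int) -> np.ndarray:
    """Unit-norm pseudo-random vector, a pure function of (text, seed, dim)."""
    digest = hashlib.blake2b(
        f"{seed}\x1f{text}".encode("utf-8"), digest_size=8
    ).digest()
    rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "big")))
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def encode_texts(texts: list[str], config: EncoderConfig) -> EmbeddingMatrix:
    """Encode texts to an embedding matrix with row ids "0", "1", ...

    The stub backend is deterministic given (texts, seed, dim); identical
    texts get identical rows.  The external backend requires the optional
    sentence-transformers dependency and never falls back silently.
    """
    if not texts:
        raise ValidationError("no texts to encode")
    for i, t in enumerate(texts):
        if not str(t).strip():
            raise ValidationError(f"text {i} is empty")
    ids = tuple(str(i) for i in range(len(texts)))
    if config.backend == "stub":
        X = np.stack([_stub_vector(str(t), config.seed, config.dim) for t in texts])
        return EmbeddingMatrix(ids, X)
    try:
        from sentence_transformers import SentenceTransformer  # type: ignore
    except ImportError as exc:
        raise BackendError(
            "external-model backend requires the optional sentence-transformers "
            "dependency (pip install taxaudit[encoders])"
        ) from exc
    model = SentenceTransformer(config.model)
    X = np.asarray(model.encode([str(t) for t in texts]), dtype=float)
    return EmbeddingMatrix(ids, X)


def encode_unique_texts(texts: list[str], ids: list[str],
                        config: EncoderConfig) -> EmbeddingMatrix:
    """Encode texts but index rows by caller-supplied ids."""
    E = encode_texts(texts, config)
    return EmbeddingMatrix(tuple(ids), E.X)


def embed_scale(items: EmbeddingMatrix, scale: Scale) -> np.ndarray:
    """Scale embedding = element-wise sum of its member item embeddings."""
    missing = [i for i in scale.item_ids if i not in items._index]
    if missing:
        raise ValidationError(
            f"scale {scale.scale_id!r}: no embedding for item(s) {missing}"
        )
    return items.subset(scale.item_ids).X.sum(axis=0)


def embed_label(entry: LabelEntry, variant: str, config: EncoderConfig) -> np.ndarray:
    """Embed a construct label in one of three variants.

    plain encodes the bare label text; contextualized substitutes the label
    into the template sentence; definition encodes the definition text.
    """
    if variant == "plain":
        text = entry.text
    elif variant == "contextualized":
        text = config.template.replace(_PLACEHOLDER, entry.text)
    elif variant == "definition":
        if not entry.definition_text:
            raise MissingVariantError(
                f"label {entry.label_id!r} has no definition text"
            )
        text = entry.definition_text
    else:
        raise ValidationError(f"unknown label variant {variant!r}")
    return encode_texts([text], config).X[0]


def embed_cluster(scales: EmbeddingMatrix, members) -> np.ndarray:
    """Cluster embedding = mean of member scale embeddings."""
    members = list(members)
    if not members:
        raise ValidationError("cluster has no members")
    return scales.subset(members).X.mean(axis=0)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    """cos(a, b) = a.b / (|a| |b|), clipped to [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _normalize_rows(X: np.ndarray) -> np.ndarray:
    return X / np.linalg.norm(X, axis=1, keepdims=True)


def pairwise_cosine(E: EmbeddingMatrix) -> SimilarityMatrix:
    """All pairwise cosines; symmetric with an exact unit diagonal."""
    Xn = _normalize_rows(E.X)
    S = np.clip(Xn @ Xn.T, -1.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(E.ids, E.ids, S)


def cross_cosine(A: EmbeddingMatrix, B: EmbeddingMatrix) -> SimilarityMatrix:
    """Rectangular |A| x |B| cosine matrix between two disjoint id sets."""
    clash = set(A.ids) & set(B.ids)
    if clash:
        raise ValidationError(f"id collision across matrices: {sorted(clash)}")
    S = np.clip(_normalize_rows(A.X) @ _normalize_rows(B.X).T, -1.0, 1.0)
    return SimilarityMatrix(A.ids, B.ids, S)


def calibrate_similarity(
    S: SimilarityMatrix, anchors: list[tuple[float, float]] | None = None
) -> SimilarityMatrix:
    """Map cosine similarities onto the empirical-correlation scale.

    Fits the least-squares affine map through the anchor pairs
    (cosine, mean empirical |r|) and applies it to every entry.  With no
    anchors the map is the identity and only the calibrated flag changes.
    """
    if not anchors:
        return replace(S, values=S.values.copy(), calibrated=True)
    xs = np.asarray([a[0] for a in anchors], dtype=float)
    ys = np.asarray([a[1] for a in anchors], dtype=float)
    if len(xs) < 2:
        raise ValidationError("calibration needs >= 2 anchor pairs (or none)")
    if np.ptp(xs) == 0:
        raise ValidationError(
            "degenerate calibration fit: all anchor similarities are equal"
        )
    slope, intercept = np.polyfit(xs, ys, deg=1)
    return replace(S, values=slope * S.values + intercept, calibrated=True)
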