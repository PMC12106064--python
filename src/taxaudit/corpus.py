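"""Item pools, label catalogs, response matrices, and all file I/O.

The on-disk formats are flat UTF-8 CSV tables with a header row.  An item
pool names, for every item, the inventory and scale it belongs to, its text,
its keying sign, and the (possibly ``/``-separated compound) construct label
of its scale.  Embeddings persist as one ``id`` column plus ``d`` numeric
columns at full decimal precision so files are diff-able and round-trip
exactly.  Readers validate referential integrity and reject rather than
repair broken inputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "Item",
    "Scale",
    "ItemPool",
    "LabelEntry",
    "LabelCatalog",
    "load_item_pool",
    "write_item_pool",
    "split_compound_labels",
    "load_responses",
    "write_responses",
    "read_embeddings",
    "write_embeddings",
    "write_fallacy_report",
    "write_tradeoff_curve",
    "write_json",
    "read_json",
]

#: float format that round-trips IEEE-754 doubles through text
_FLOAT_FMT = "%.17g"

POOL_COLUMNS = ("inventory_id", "scale_id", "item_id", "text", "key", "label")


class SchemaError(ValueError):
    """A file is structurally malformed (missing columns, duplicate keys)."""


class ValidationError(ValueError):
    """Contents violate a domain invariant (dangling ids, short scales)."""


@dataclass(frozen=True)
class Item:
    """A single self-report statement."""

    item_id: str
    text: str
    scale_id: str
    inventory_id: str
    key: int = 1  # keying sign, +1 or -1

    def __post_init__(self) -> None:
        if not self.text or not self.text.strip():
            raise ValidationError(f"item {self.item_id!r}: empty text")
        if self.key not in (1, -1):
            raise ValidationError(
                f"item {self.item_id!r}: key must be +1 or -1, got {self.key!r}"
            )


@dataclass(frozen=True)
class Scale:
    """An ordered set of >= 2 items measuring one putative construct."""

    scale_id: str
    inventory_id: str
    item_ids: tuple[str, ...]
    label_compound: str

    def __post_init__(self) -> None:
        if len(self.item_ids) < 2:
            raise ValidationError(
                f"scale {self.scale_id!r} has {len(self.item_ids)} item(s); "
                "scales need at least 2 (reliability is undefined otherwise)"
            )
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValidationError(f"scale {self.scale_id!r}: duplicate item ids")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


@dataclass
class ItemPool:
    """A validated collection of items grouped into scales and inventories."""

    items: dict[str, Item]
    scales: dict[str, Scale]

    def __post_init__(self) -> None:
        for scale in self.scales.values():
            for iid in scale.item_ids:
                item = self.items.get(iid)
                if item is None:
                    raise ValidationError(
                        f"scale {scale.scale_id!r} references unknown item {iid!r}"
                    )
                if item.scale_id != scale.scale_id:
                    raise ValidationError(
                        f"item {iid!r} claims scale {item.scale_id!r} but is listed "
                        f"under {scale.scale_id!r}"
                    )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def scale_items(self, scale_id: str) -> list[Item]:
        scale = self.scales[scale_id]
        return [self.items[i] for i in scale.item_ids]

    def inventories(self) -> dict[str, list[Scale]]:
        """Scales grouped by inventory, preserving insertion order."""
        out: dict[str, list[Scale]] = {}
        for scale in self.scales.values():
            out.setdefault(scale.inventory_id, []).append(scale)
        return out

    def inventory_scale_counts(self) -> dict[str, int]:
        return {inv: len(scales) for inv, scales in self.inventories().items()}

    def label_mapping(self, catalog: "LabelCatalog") -> dict[str, list[str]]:
        """scale_id -> constituent single label ids, via the catalog."""
        return {
            s.scale_id: catalog.compound_map[s.label_compound]
            for s in self.scales.values()
        }


@dataclass(frozen=True)
class LabelEntry:
    label_id: str
    text: str
    variant: str = "plain"  # plain | contextualized | definition
    definition_text: str | None = None


@dataclass
class LabelCatalog:
    """Single construct labels plus the compound -> singles map."""

    entries: list[LabelEntry]
    compound_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for e in self.entries:
            key = (e.variant, e.text.strip().lower())
            if key in seen:
                raise ValidationError(
                    f"duplicate label text {e.text!r} within variant {e.variant!r}"
                )
            seen[key] = e.label_id
        ids = {e.label_id for e in self.entries}
        for compound, singles in self.compound_map.items():
            if not singles:
                raise ValidationError(f"compound {compound!r} maps to no labels")
            for lid in singles:
                if lid not in ids:
                    raise ValidationError(
                        f"compound {compound!r} maps to unknown label {lid!r}"
                    )

    @property
    def label_ids(self) -> list[str]:
        return [e.label_id for e in self.entries]

    def get(self, label_id: str) -> LabelEntry:
        for e in self.entries:
            if e.label_id == label_id:
                return e
        raise KeyError(label_id)


def split_compound_labels(raw_labels: list[str]) -> LabelCatalog:
    """Split ``/``-separated compound labels into a single-label catalog.

    Constituents are whitespace-trimmed and de-duplicated case-insensitively
    (first-seen casing kept).  Every raw compound maps to its constituent
    single label ids.  The operation is idempotent: feeding the resulting
    single labels back in reproduces the same catalog.
    """
    singles: dict[str, str] = {}  # lowercase -> canonical id/text
    compound_map: dict[str, list[str]] = {}
    for raw in raw_labels:
        parts = [p.strip() for p in str(raw).split("/")]
        if any(not p for p in parts):
            raise ValidationError(f"label {raw!r} has an empty constituent")
        ids: list[str] = []
        for part in parts:
            key = part.lower()
            if key not in singles:
                singles[key] = part
            if singles[key] not in ids:
                ids.append(singles[key])
        compound_map[str(raw)] = ids
    entries = [LabelEntry(label_id=t, text=t) for t in singles.values()]
    return LabelCatalog(entries=entries, compound_map=compound_map)


# ---------------------------------------------------------------------------
# file I/O


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = os.fspath(path)
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_to_csv(df: pd.DataFrame, path: str | os.PathLike, **kw) -> None:
    _atomic_write_text(path, df.to_csv(**kw))


def load_item_pool(path: str | os.PathLike) -> ItemPool:
    """Read and validate an item-pool CSV.

    Required columns: inventory_id, scale_id, item_id, text, key, label.
    Rejects duplicate item ids and scales with fewer than two items.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(POOL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    dupes = df["item_id"][df["item_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(f"{path}: duplicate item_id(s) {sorted(set(dupes))}")

    items: dict[str, Item] = {}
    scale_rows: dict[str, list[pd.Series]] = {}
    for _, row in df.iterrows():
        try:
            key = int(row["key"])
        except ValueError as exc:
            raise SchemaError(
                f"{path}: non-integer key {row['key']!r} for item {row['item_id']!r}"
            ) from exc
        items[row["item_id"]] = Item(
            item_id=row["item_id"],
            text=row["text"],
            scale_id=row["scale_id"],
            inventory_id=row["inventory_id"],
            key=key,
        )
        scale_rows.setdefault(row["scale_id"], []).append(row)

    scales: dict[str, Scale] = {}
    for sid, rows in scale_rows.items():
        invs = {r["inventory_id"] for r in rows}
        if len(invs) > 1:
            raise ValidationError(
                f"scale {sid!r} spans multiple inventories {sorted(invs)}"
            )
        labels = {r["label"] for r in rows}
        if len(labels) > 1:
            raise ValidationError(
                f"scale {sid!r} carries conflicting labels {sorted(labels)}"
            )
        scales[sid] = Scale(
            scale_id=sid,
            inventory_id=rows[0]["inventory_id"],
            item_ids=tuple(r["item_id"] for r in rows),
            label_compound=rows[0]["label"],
        )
    return ItemPool(items=items, scales=scales)


def write_item_pool(pool: ItemPool, path: str | os.PathLike) -> None:
    rows = []
    for scale in pool.scales.values():
        for iid in scale.item_ids:
            item = pool.items[iid]
            rows.append(
                {
                    "inventory_id": item.inventory_id,
                    "scale_id": item.scale_id,
                    "item_id": item.item_id,
                    "text": item.text,
                    "key": item.key,
                    "label": scale.label_compound,
                }
            )
    _atomic_to_csv(pd.DataFrame(rows, columns=list(POOL_COLUMNS)), path, index=False)


def load_responses(path: str | os.PathLike, pool: ItemPool | None = None) -> pd.DataFrame:
    """Read a respondent x item rating matrix (first column = respondent id).

    Missing cells are allowed (empty fields -> NaN); non-numeric cells raise a
    parse error naming the offending row and column.  If a pool is given,
    every column id must resolve to an item in it and every used column needs
    at least two non-missing ratings.
    """
    raw = pd.read_csv(path, index_col=0, float_precision="round_trip")
    bad_cols = []
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        newly_bad = coerced.isna() & raw[col].notna()
        if newly_bad.any():
            row_label = raw.index[np.flatnonzero(newly_bad)[0]]
            raise SchemaError(
                f"{path}: non-numeric rating at row {row_label!r}, column {col!r}"
            )
        raw[col] = coerced.astype(float)
        if coerced.notna().sum() < 2:
            bad_cols.append(col)
    if pool is not None:
        unknown = [c for c in raw.columns if c not in pool.items]
        if unknown:
            raise ValidationError(f"{path}: unknown item id(s) {unknown}")
        if bad_cols:
            raise ValidationError(
                f"{path}: column(s) {bad_cols} have fewer than 2 ratings"
            )
    return raw


def write_responses(responses: pd.DataFrame, path: str | os.PathLike) -> None:
    _atomic_to_csv(responses, path, index=True, float_format=_FLOAT_FMT)


def read_embeddings(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Read an id + d-column embedding CSV -> (ids, n x d array)."""
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "id":
        raise SchemaError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        raise SchemaError(f"{path}: duplicate embedding ids")
    X = df.drop(columns="id").to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{path}: non-finite embedding entries")
    return ids, X


def write_embeddings(ids: list[str], X: np.ndarray, path: str | os.PathLike) -> None:
    """Write embeddings at full double precision (write-read round-trips)."""
    X = np.asarray(X, dtype=float)
    if len(ids) != X.shape[0]:
        raise ValidationError(
            f"{len(ids)} ids but {X.shape[0]} embedding rows"
        )
    df = pd.DataFrame(X, columns=[f"e{j}" for j in range(X.shape[1])])
    df.insert(0, "id", ids)
    _atomic_to_csv(df, path, index=False, float_format=_FLOAT_FMT)


def write_fallacy_report(pairs, path: str | os.PathLike) -> None:
    """Write detected fallacy pairs as CSV (one data row per pair)."""
    rows = [
        {
            "scale_a": p.scale_a,
            "scale_b": p.scale_b,
            "type": p.type,
            "scale_sim": p.scale_sim,
            "label_sim": p.label_sim,
            "shared_items": p.shared_items,
            "labels_a": "/".join(p.labels_a),
            "labels_b": "/".join(p.labels_b),
        }
        for p in pairs
    ]
    cols = [
        "scale_a", "scale_b", "type", "scale_sim", "label_sim",
        "shared_items", "labels_a", "labels_b",
    ]
    _atomic_to_csv(pd.DataFrame(rows, columns=cols), path, index=False,
                   float_format=_FLOAT_FMT)


def write_tradeoff_curve(curve, path: str | os.PathLike) -> None:
    """Write a clustering trade-off curve (see taxaudit.optimize) as CSV."""
    _atomic_to_csv(curve.table, path, index=False, float_format=_FLOAT_FMT)


def write_json(obj, path: str | os.PathLike) -> None:
    _atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | os.PathLike):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
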