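"""Item parameters and item banks for the multidimensional graded response model.

An :class:`ItemParameters` object holds one polytomous item: a discrimination
vector ``a`` (one slope per latent dimension, with structural zeros where the
loading pattern forbids a loading) and a strictly descending vector of
boundary "easiness" intercepts ``d``.  An :class:`ItemBank` collects the
items of a scale together with the loading pattern and display labels.

Banks are serialized as YAML documents; the calibrated bank of the 9-item
liver-stagnation / spleen-deficiency severity scale ships with the package
and is returned by :func:`reference_bank`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .links import LINKS

__all__ = [
    "ItemParameters",
    "ItemBank",
    "read_bank",
    "write_bank",
    "reference_bank",
]


@dataclass(frozen=True)
class ItemParameters:
    """One graded item: discrimination vector and ordered boundary intercepts.

    Parameters
    ----------
    item_id
        Label identifying the item within its bank.
    a
        Discrimination (slope) vector, one entry per latent dimension.
        Entries fixed to zero encode dimensions the item does not load on.
    d
        Boundary intercepts ``d_1 > d_2 > ... > d_m`` (larger values make
        the category-or-above response easier to endorse).  An item with
        ``m`` boundaries has ``m + 1`` response categories coded ``0..m``.
    link
        ``"probit"`` (normal ogive) or ``"logistic"``.
    """

    item_id: str
    a: np.ndarray
    d: np.ndarray
    link: str = "probit"
    label: str = ""
    category_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "d", d)
        if a.ndim != 1 or a.size < 1:
            raise ValueError(f"{self.item_id}: discrimination vector must be 1-D, non-empty")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{self.item_id}: non-finite discrimination entries")
        if d.size < 1:
            raise ValueError(f"{self.item_id}: need at least one boundary (2 categories)")
        if not np.all(np.isfinite(d)):
            raise ValueError(f"{self.item_id}: non-finite boundary parameters")
        if d.size > 1 and not np.all(np.diff(d) < 0):
            raise ValueError(f"{self.item_id}: boundary parameters must be strictly decreasing")
        if self.link not in LINKS:
            raise ValueError(f"{self.item_id}: unknown link {self.link!r}")
        if self.category_labels is not None:
            object.__setattr__(self, "category_labels", tuple(self.category_labels))
            if len(self.category_labels) != d.size + 1:
                raise ValueError(f"{self.item_id}: need one category label per category")

    @property
    def n_dim(self) -> int:
        return int(self.a.size)

    @property
    def n_boundaries(self) -> int:
        return int(self.d.size)

    @property
    def n_categories(self) -> int:
        return int(self.d.size) + 1

    def with_link(self, link: str) -> "ItemParameters":
        return replace(self, link=link)


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of items sharing the same latent space.

    ``loading_pattern`` is a boolean items-by-dimensions matrix marking which
    discriminations are free; when omitted it is inferred from the nonzero
    entries of each item's ``a``.  The scale this package was built around
    has simple structure: each item loads on exactly one of two correlated
    factors (liver stagnation for the mental-symptom items, spleen deficiency
    for the abdominal-discomfort items).
    """

    items: tuple[ItemParameters, ...]
    loading_pattern: np.ndarray | None = None
    dimension_labels: tuple[str, ...] | None = None
    category_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise ValueError("empty item bank")
        D = items[0].n_dim
        if any(it.n_dim != D for it in items):
            raise ValueError("all items must share the same number of dimensions")
        if len({it.item_id for it in items}) != len(items):
            raise ValueError("duplicate item ids in bank")
        if self.loading_pattern is None:
            pattern = np.vstack([it.a != 0 for it in items])
        else:
            pattern = np.asarray(self.loading_pattern, dtype=bool)
            if pattern.shape != (len(items), D):
                raise ValueError("loading_pattern must be items x dimensions")
            for it, row in zip(items, pattern):
                if np.any(it.a[~row] != 0):
                    raise ValueError(f"{it.item_id}: nonzero discrimination on a fixed-zero loading")
        object.__setattr__(self, "loading_pattern", pattern)
        if self.dimension_labels is not None:
            object.__setattr__(self, "dimension_labels", tuple(self.dimension_labels))

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_dim(self) -> int:
        return self.items[0].n_dim

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def link(self) -> str:
        links = {it.link for it in self.items}
        if len(links) != 1:
            raise ValueError("bank mixes link functions")
        return links.pop()

    def is_simple_structure(self) -> bool:
        return bool(np.all(self.loading_pattern.sum(axis=1) == 1))

    def primary_dimension(self, j: int) -> int:
        """Dimension an item loads on; requires simple structure for that item."""
        free = np.flatnonzero(self.loading_pattern[j])
        if free.size != 1:
            raise ValueError(f"item {self.items[j].item_id} does not have a single loading")
        return int(free[0])

    def discrimination_matrix(self) -> np.ndarray:
        return np.vstack([it.a for it in self.items])

    def with_link(self, link: str) -> "ItemBank":
        return replace(self, items=tuple(it.with_link(link) for it in self.items))


# ---------------------------------------------------------------------------
# serialization


def _bank_to_dict(bank: ItemBank) -> dict:
    doc: dict = {
        "n_dimensions": bank.n_dim,
        "link": bank.link,
        "items": [],
    }
    if bank.dimension_labels:
        doc["dimension_labels"] = list(bank.dimension_labels)
    if bank.category_labels:
        doc["category_labels"] = list(bank.category_labels)
    inferred = np.vstack([it.a != 0 for it in bank.items])
    if not np.array_equal(inferred, bank.loading_pattern):
        doc["loading_pattern"] = bank.loading_pattern.astype(int).tolist()
    for it in bank.items:
        rec: dict = {
            "id": it.item_id,
            "a": [float(x) for x in it.a],
            "d": [float(x) for x in it.d],
        }
        if it.label:
            rec["label"] = it.label
        if it.category_labels:
            rec["category_labels"] = list(it.category_labels)
        doc["items"].append(rec)
    return doc


def _bank_from_dict(doc: dict) -> ItemBank:
    link = doc.get("link", "probit")
    default_cats = doc.get("category_labels")
    items = []
    for rec in doc["items"]:
        cats = rec.get("category_labels", default_cats)
        items.append(
            ItemParameters(
                item_id=str(rec["id"]),
                a=np.asarray(rec["a"], dtype=float),
                d=np.asarray(rec["d"], dtype=float),
                link=rec.get("link", link),
                label=rec.get("label", ""),
                category_labels=tuple(cats) if cats else None,
            )
        )
    pattern = doc.get("loading_pattern")
    return ItemBank(
        items=tuple(items),
        loading_pattern=np.asarray(pattern, dtype=bool) if pattern is not None else None,
        dimension_labels=tuple(doc["dimension_labels"]) if "dimension_labels" in doc else None,
        category_labels=tuple(default_cats) if default_cats else None,
    )


def read_bank(path: str | Path) -> ItemBank:
    """Read an item bank from a YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "items" not in doc:
        raise ValueError(f"{path}: not an item-bank document")
    return _bank_from_dict(doc)


def write_bank(bank: ItemBank, path: str | Path) -> None:
    """Write an item bank as a YAML document."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_bank_to_dict(bank), fh, sort_keys=False)


def reference_bank(link: str | None = None) -> ItemBank:
    """The packaged calibration of the 9-item two-factor severity scale.

    Items 1-5 load on the liver-stagnation factor, items 6-9 on the
    spleen-deficiency factor.  ``link`` overrides the file's default link
    without rescaling the slopes.
    """
    source = resources.files("patternirt").joinpath("data/lssd9_bank.yaml")
    doc = yaml.safe_load(source.read_text(encoding="utf-8"))
    bank = _bank_from_dict(doc)
    if link is not None:
        bank = bank.with_link(link)
    return bank


def starting_bank(
    pattern: np.ndarray | Iterable[Sequence[bool]],
    n_categories: int | Sequence[int],
    link: str = "probit",
    item_ids: Sequence[str] | None = None,
) -> ItemBank:
    """Neutral starting values for estimation: free slopes 1, boundaries
    equally spaced and descending, centred on 0."""
    pattern = np.asarray(pattern, dtype=bool)
    J, D = pattern.shape
    if np.isscalar(n_categories):
        n_cats = [int(n_categories)] * J
    else:
        n_cats = [int(c) for c in n_categories]
    if item_ids is None:
        item_ids = [f"item{j + 1}" for j in range(J)]
    items = []
    for j in range(J):
        a = np.where(pattern[j], 1.0, 0.0)
        m = n_cats[j] - 1
        d = np.linspace(1.0, -1.0, m) * (m / 2.0) if m > 1 else np.array([0.0])
        items.append(ItemParameters(item_id=str(item_ids[j]), a=a, d=d, link=link))
    return ItemBank(items=tuple(items), loading_pattern=pattern)
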