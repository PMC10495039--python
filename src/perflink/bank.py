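"""Item banks: graded-response item parameters on a reference metric.

An :class:`Item` holds a logistic discrimination (slope) ``a`` and strictly
increasing category thresholds ``b_1 < ... < b_{m-1}`` for an item with ``m``
ordered categories.  Anchor items carry parameters fixed on the reference
metric (here, a T-score metric with population mean 50 / SD 10 on the
``theta`` scale ``T = 10*theta + 50``); new items are calibrated onto that
metric with the anchors held fixed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = ["Item", "ItemBank"]

_INSTRUMENTS = ("anchor", "new")


@dataclass(frozen=True)
class Item:
    """A single graded-response item.

    Parameters
    ----------
    item_id : str
        Unique identifier.
    instrument : {"anchor", "new"}
        Whether the item belongs to the fixed reference instrument or to the
        instrument being linked.
    slope : float
        Logistic discrimination ``a > 0``.
    thresholds : array-like of float
        Strictly increasing category boundaries ``b_1 < ... < b_{m-1}``.
    fixed : bool
        If True the parameters are held fixed during calibration.
    """

    item_id: str
    instrument: str
    slope: float
    thresholds: tuple[float, ...] = field(default=())
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.instrument not in _INSTRUMENTS:
            raise ValueError(
                f"instrument must be one of {_INSTRUMENTS}, got {self.instrument!r}"
            )
        if not np.isfinite(self.slope) or self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        b = tuple(float(t) for t in self.thresholds)
        if len(b) < 1:
            raise ValueError("an item needs at least one threshold (>=2 categories)")
        if not all(np.isfinite(b)):
            raise ValueError("thresholds must be finite")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError(f"thresholds must be strictly increasing, got {b}")
        object.__setattr__(self, "thresholds", b)

    @property
    def n_cat(self) -> int:
        """Number of ordered response categories (``len(thresholds) + 1``)."""
        return len(self.thresholds) + 1

    @property
    def max_score(self) -> int:
        return self.n_cat - 1

    def with_shifted_thresholds(self, shift: float) -> "Item":
        """Return a copy with every threshold moved by ``shift`` (uniform DIF)."""
        return replace(self, thresholds=tuple(t + shift for t in self.thresholds))


class ItemBank:
    """Ordered collection of :class:`Item` with CSV/JSON round-trips."""

    def __init__(self, items: Iterable[Item]):
        items = list(items)
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item_id in bank")
        self._items = items
        self._index = {iid: j for j, iid in enumerate(ids)}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self) -> Iterator[Item]:
        return iter(self._items)

    def __getitem__(self, key: int | str) -> Item:
        if isinstance(key, str):
            try:
                key = self._index[key]
            except KeyError:
                raise KeyError(f"unknown item_id {key!r}") from None
        return self._items[key]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ItemBank):
            return NotImplemented
        return self._items == other._items

    def index(self, item_id: str) -> int:
        try:
            return self._index[item_id]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id!r}") from None

    # -- views ---------------------------------------------------------------
    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self._items]

    @property
    def slopes(self) -> np.ndarray:
        return np.array([it.slope for it in self._items])

    @property
    def n_cats(self) -> np.ndarray:
        return np.array([it.n_cat for it in self._items])

    @property
    def fixed_mask(self) -> np.ndarray:
        return np.array([it.fixed for it in self._items], dtype=bool)

    @property
    def max_sum_score(self) -> int:
        return int(sum(it.max_score for it in self._items))

    def subset(self, item_ids: Sequence[str]) -> "ItemBank":
        return ItemBank([self[iid] for iid in item_ids])

    def replace_item(self, item: Item) -> "ItemBank":
        items = list(self._items)
        items[self.index(item.item_id)] = item
        return ItemBank(items)

    # -- serialisation -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Tabular view with columns item_id, instrument, n_cat, slope, b1..bK, fixed."""
        max_k = max(it.n_cat - 1 for it in self._items)
        rows = []
        for it in self._items:
            row: dict[str, object] = {
                "item_id": it.item_id,
                "instrument": it.instrument,
                "n_cat": it.n_cat,
                "slope": it.slope,
            }
            for k in range(max_k):
                row[f"b{k + 1}"] = it.thresholds[k] if k < len(it.thresholds) else np.nan
            row["fixed"] = it.fixed
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        b_cols = sorted(
            (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        items = []
        for _, row in df.iterrows():
            n_cat = int(row["n_cat"])
            thresholds = [float(row[c]) for c in b_cols[: n_cat - 1]]
            items.append(
                Item(
                    item_id=str(row["item_id"]),
                    instrument=str(row["instrument"]),
                    slope=float(row["slope"]),
                    thresholds=tuple(thresholds),
                    fixed=bool(row["fixed"]),
                )
            )
        return cls(items)

    def write_csv(self, path) -> None:
        # %.17g guarantees exact float round-trips
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def to_json(self) -> str:
        recs = [
            {
                "item_id": it.item_id,
                "instrument": it.instrument,
                "n_cat": it.n_cat,
                "slope": it.slope,
                "thresholds": list(it.thresholds),
                "fixed": it.fixed,
            }
            for it in self._items
        ]
        return json.dumps(recs, indent=1)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def read_json(cls, path) -> "ItemBank":
        with open(path) as fh:
            recs = json.load(fh)
        return cls(
            Item(
                item_id=r["item_id"],
                instrument=r["instrument"],
                slope=r["slope"],
                thresholds=tuple(r["thresholds"]),
                fixed=r["fixed"],
            )
            for r in recs
        )

    def __repr__(self) -> str:  # pragma: no cover
        n_fixed = int(self.fixed_mask.sum())
        return f"ItemBank({len(self)} items, {n_fixed} fixed)"
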