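"""Response matrices: persons x items ordinal codes plus person covariates.

Codes are 0-based (0..m-1 for an m-category item).  Missing responses are a
first-class concept: internally the integer code ``-1``, in CSV an empty
field.  Optional per-person covariates and (for simulated data) the true
latent traits travel with the matrix so downstream stages never need to
re-align persons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bank import ItemBank

__all__ = ["ResponseMatrix", "MISSING"]

MISSING: int = -1


@dataclass
class ResponseMatrix:
    """Persons x items ordinal response data.

    Attributes
    ----------
    responses : ndarray of int, shape (n_persons, n_items)
        0-based category codes; ``MISSING`` (-1) marks a missing cell.
    item_ids : list of str
        Column labels, aligned with an :class:`~perflink.bank.ItemBank`.
    covariates : pandas.DataFrame
        Per-person named covariates (may be empty).
    true_theta : ndarray or None
        Generating latent traits, present for simulated data only.
    """

    responses: np.ndarray
    item_ids: list[str]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    true_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=np.int64)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D (persons x items)")
        if self.responses.shape[1] != len(self.item_ids):
            raise ValueError("item_ids length does not match response columns")
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item_ids")
        if (self.responses < MISSING).any():
            raise ValueError("codes must be >= 0 or the missing marker -1")
        if len(self.covariates) and len(self.covariates) != self.n_persons:
            raise ValueError("covariates not aligned with persons")
        if self.true_theta is not None:
            self.true_theta = np.asarray(self.true_theta, dtype=float)
            if self.true_theta.shape != (self.n_persons,):
                raise ValueError("true_theta not aligned with persons")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def column(self, item_id: str) -> np.ndarray:
        return self.responses[:, self.item_ids.index(item_id)]

    def columns(self, item_ids: Sequence[str]) -> np.ndarray:
        idx = [self.item_ids.index(i) for i in item_ids]
        return self.responses[:, idx]

    def missing_mask(self) -> np.ndarray:
        return self.responses == MISSING

    def select_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        return ResponseMatrix(
            self.columns(item_ids),
            list(item_ids),
            self.covariates.copy(),
            None if self.true_theta is None else self.true_theta.copy(),
        )

    def select_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ResponseMatrix(
            self.responses[mask],
            list(self.item_ids),
            self.covariates.loc[mask].reset_index(drop=True)
            if len(self.covariates)
            else pd.DataFrame(),
            None if self.true_theta is None else self.true_theta[mask],
        )

    def complete_cases(self, item_ids: Sequence[str] | None = None) -> "ResponseMatrix":
        """Persons with no missing response on the selected items."""
        cols = self.columns(item_ids) if item_ids is not None else self.responses
        keep = (cols != MISSING).all(axis=1)
        rm = self.select_persons(keep)
        return rm if item_ids is None else rm.select_items(item_ids)

    def validate_against(self, bank: ItemBank) -> None:
        """Raise if any code exceeds its item's category range."""
        for iid in self.item_ids:
            if iid not in bank:
                raise ValueError(f"item {iid!r} not in bank")
            col = self.column(iid)
            top = bank[iid].n_cat - 1
            bad = np.nonzero(col > top)[0]
            if bad.size:
                raise ValueError(
                    f"item {iid!r}: code {col[bad[0]]} exceeds max {top} "
                    f"(row {bad[0]})"
                )

    # -- serialisation -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        resp = pd.DataFrame(self.responses, columns=self.item_ids).astype("Int64")
        resp = resp.mask(resp == MISSING)
        parts = [resp]
        if len(self.covariates):
            parts.append(self.covariates.reset_index(drop=True))
        if self.true_theta is not None:
            parts.append(pd.DataFrame({"true_theta": self.true_theta}))
        return pd.concat(parts, axis=1)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path, item_ids: Sequence[str] | None = None) -> "ResponseMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df, item_ids=item_ids)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, item_ids: Sequence[str] | None = None
    ) -> "ResponseMatrix":
        """Build from a table; non-item columns become covariates.

        Without an explicit ``item_ids`` list every column whose non-missing
        values are all non-negative integers is treated as an item.
        """
        if item_ids is None:
            item_ids = []
            for c in df.columns:
                if c == "true_theta":
                    continue
                vals = df[c].dropna()
                num = pd.to_numeric(vals, errors="coerce")
                if len(num) and num.notna().all() and (num % 1 == 0).all() and (num >= 0).all():
                    item_ids.append(c)
        item_ids = list(item_ids)
        missing_cols = [c for c in item_ids if c not in df.columns]
        if missing_cols:
            raise ValueError(f"item columns absent from file: {missing_cols}")
        resp = np.full((len(df), len(item_ids)), MISSING, dtype=np.int64)
        for j, c in enumerate(item_ids):
            num = pd.to_numeric(df[c], errors="coerce")
            bad = num.notna() & ((num % 1 != 0) | (num < 0))
            if bad.any():
                row = int(np.nonzero(bad.to_numpy())[0][0])
                raise ValueError(f"malformed code in column {c!r}, row {row + 2}")
            ok = num.notna().to_numpy()
            resp[ok, j] = num.to_numpy(dtype=float)[ok].astype(np.int64)
        cov_cols = [c for c in df.columns if c not in item_ids and c != "true_theta"]
        covariates = df[cov_cols].reset_index(drop=True) if cov_cols else pd.DataFrame()
        theta = df["true_theta"].to_numpy(dtype=float) if "true_theta" in df else None
        return cls(resp, item_ids, covariates, theta)
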