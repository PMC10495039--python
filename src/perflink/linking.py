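"""Fixed-anchor linking and the sum-score -> T-score crosswalk.

The linking workflow: fit a unidimensional GRM to the pooled anchor + new
items with the anchor parameters held at their published reference-metric
values and a standard-normal latent prior.  Because the anchors pin the
metric, the freely estimated new-item parameters land on the reference
T-score scale.  A summed-score EAP crosswalk (Lord-Wingersky recursion plus
Bayes over the quadrature grid) then maps every attainable sum score of a
designated item subset to (theta, SE, T).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .bank import Item, ItemBank
from .data import MISSING, ResponseMatrix
from .grm import (
    CalibrationResult,
    QuadratureGrid,
    ScoredPerson,
    em_calibrate,
    eap_score_matrix,
    lw_sumscore_dist,
    make_grid,
    s_x2_itemfit,
    starting_values,
    to_tscore,
)

__all__ = [
    "CrosswalkTable",
    "fixed_anchor_link",
    "build_crosswalk",
    "convert_scores",
    "GRMLinker",
]


def _bank_hash(bank: ItemBank) -> str:
    return hashlib.sha256(bank.to_json().encode()).hexdigest()[:16]


@dataclass
class CrosswalkTable:
    """Sum score -> (theta, SE, T-score) lookup for one item subset."""

    table: pd.DataFrame  # columns sum_score, theta, se, t_score
    item_subset: list[str]
    bank_hash: str
    grid_note: str
    note: str = "summed-score EAP crosswalk; complete response sets only"

    def __post_init__(self) -> None:
        t = self.table
        if list(t["sum_score"]) != list(range(len(t))):
            raise ValueError("crosswalk rows must cover 0..S_max contiguously")
        th = t["theta"].to_numpy()
        if np.any(np.diff(th) <= 0):
            raise ValueError("crosswalk theta must be strictly increasing")
        if not np.allclose(t["t_score"], 10 * th + 50):
            raise ValueError("t_score must equal 10*theta + 50")

    def lookup(self, sum_score: int) -> pd.Series:
        if not 0 <= sum_score < len(self.table):
            raise ValueError(f"sum score {sum_score} outside table range")
        return self.table.iloc[int(sum_score)]

    def t_to_sum(self, t_score: float) -> int:
        """Reverse lookup: nearest sum score by |T difference|, ties to lower."""
        diff = np.abs(self.table["t_score"].to_numpy() - t_score)
        best = np.nonzero(diff == diff.min())[0]
        return int(best.min())

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# items: {','.join(self.item_subset)}\n")
            fh.write(f"# anchor_bank_hash: {self.bank_hash}\n")
            fh.write(f"# grid: {self.grid_note}\n")
            fh.write(f"# note: {self.note}\n")
            self.table.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "CrosswalkTable":
        meta: dict[str, str] = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                else:
                    body.write(line)
        body.seek(0)
        return cls(
            table=pd.read_csv(body, float_precision="round_trip"),
            item_subset=meta.get("items", "").split(","),
            bank_hash=meta.get("anchor_bank_hash", ""),
            grid_note=meta.get("grid", ""),
            note=meta.get("note", ""),
        )


def fixed_anchor_link(
    rm: ResponseMatrix,
    anchor_bank: ItemBank,
    free_item_ids: list[str],
    grid: QuadratureGrid | None = None,
    tol: float = 1e-4,
    max_cycles: int = 500,
) -> CalibrationResult:
    """Calibrate free items onto the anchors' metric.

    ``anchor_bank`` supplies reference-metric parameters for the anchor
    items (any free items it happens to contain are used as starting
    values); other free items start from their marginal category
    proportions.  Delegates to :func:`~perflink.grm.em_calibrate` with the
    anchors fixed; the returned bank's anchor rows are identical to the
    input.
    """
    if not free_item_ids:
        raise ValueError("no free items to calibrate")
    if grid is None:
        grid = make_grid()
    anchor_ids = [it.item_id for it in anchor_bank if it.fixed]
    for iid in anchor_ids + list(free_item_ids):
        if iid not in rm.item_ids:
            raise ValueError(f"item {iid!r} absent from response matrix")
    items: list[Item] = [anchor_bank[iid] for iid in anchor_ids]
    for iid in free_item_ids:
        if iid in anchor_bank and not anchor_bank[iid].fixed:
            start = anchor_bank[iid]
            items.append(Item(iid, start.instrument, start.slope, start.thresholds, False))
            continue
        col = rm.column(iid)
        n_cat = int(col[col != MISSING].max()) + 1
        slope, b = starting_values(col, n_cat)
        items.append(Item(iid, "new", slope, tuple(b), False))
    bank0 = ItemBank(items)
    sub = rm.select_items(bank0.item_ids)
    sub.validate_against(bank0)
    return em_calibrate(sub, bank0, grid, tol=tol, max_cycles=max_cycles)


def build_crosswalk(
    bank_subset: ItemBank, grid: QuadratureGrid | None = None
) -> CrosswalkTable:
    """Summed-score EAP crosswalk for a calibrated item subset.

    For each attainable sum score s the posterior over the grid is
    proportional to P(S = s | theta_q) w_q; theta is its mean, SE its SD,
    and T = 10 theta + 50.  Theta is strictly increasing in s (sum scores
    order the posterior in the monotone-likelihood-ratio sense), asserted
    on every built table.
    """
    if grid is None:
        grid = make_grid()
    f = lw_sumscore_dist(bank_subset, grid.nodes)  # (S+1, Q)
    mass = f * grid.weights[None, :]
    denom = mass.sum(axis=1)
    theta = (mass @ grid.nodes) / denom
    second = (mass @ grid.nodes**2) / denom
    se = np.sqrt(np.maximum(second - theta**2, 0.0))
    table = pd.DataFrame(
        {
            "sum_score": np.arange(f.shape[0]),
            "theta": theta,
            "se": se,
            "t_score": 10 * theta + 50,
        }
    )
    return CrosswalkTable(
        table=table,
        item_subset=bank_subset.item_ids,
        bank_hash=_bank_hash(bank_subset),
        grid_note=f"{grid.n_nodes} nodes on [{grid.nodes[0]:g}, {grid.nodes[-1]:g}]",
    )


def convert_scores(
    rm: ResponseMatrix,
    crosswalk: CrosswalkTable,
    bank_subset: ItemBank,
    grid: QuadratureGrid | None = None,
) -> list[ScoredPerson]:
    """Score persons through the crosswalk.

    Persons with a complete response set on the crosswalk items are scored
    by table lookup; persons with missing responses fall back to pattern
    EAP under the same bank and grid, with the method recorded.
    """
    if grid is None:
        grid = make_grid()
    X = rm.columns(crosswalk.item_subset)
    rm.select_items(crosswalk.item_subset).validate_against(bank_subset)
    complete = (X != MISSING).all(axis=1)
    out: list[ScoredPerson] = []
    theta_p, se_p, used_p = eap_score_matrix(X, bank_subset, grid)
    for i in range(X.shape[0]):
        if complete[i]:
            row = crosswalk.lookup(int(X[i].sum()))
            out.append(
                ScoredPerson(
                    theta_eap=float(row["theta"]),
                    se_eap=float(row["se"]),
                    t_score=float(row["t_score"]),
                    items_used=X.shape[1],
                    method="sumscore_lookup",
                )
            )
        else:
            out.append(
                ScoredPerson(
                    theta_eap=float(theta_p[i]),
                    se_eap=float(se_p[i]),
                    t_score=float(to_tscore(float(theta_p[i]))),
                    items_used=int(used_p[i]),
                    method="pattern_eap",
                )
            )
    return out


class GRMLinker(BaseEstimator, TransformerMixin):
    """Fixed-anchor GRM calibration and EAP T-scoring as an estimator.

    Parameters
    ----------
    anchor_bank : ItemBank
        Anchor items (``fixed=True``) with reference-metric parameters;
        may also carry starting values for free items.
    free_items : list of str, optional
        Items to calibrate (default: every response column that is not an
        anchor).
    n_nodes, span : quadrature settings (61 nodes on [-6, 6] by default).
    tol, max_cycles : EM convergence controls.

    Attributes (after ``fit``)
    --------------------------
    bank_ : ItemBank — calibrated pooled bank (anchors untouched).
    calibration_ : CalibrationResult
    loglik_trace_, n_cycles_, converged_
    ``transform`` returns a DataFrame of EAP theta, SE, T-score and items
    used; ``crosswalk`` builds the sum-score conversion table.
    """

    def __init__(
        self,
        anchor_bank: ItemBank | None = None,
        free_items: list[str] | None = None,
        n_nodes: int = 61,
        span: float = 6.0,
        tol: float = 1e-4,
        max_cycles: int = 500,
    ):
        self.anchor_bank = anchor_bank
        self.free_items = free_items
        self.n_nodes = n_nodes
        self.span = span
        self.tol = tol
        self.max_cycles = max_cycles

    def _grid(self) -> QuadratureGrid:
        return make_grid(self.n_nodes, self.span)

    def fit(self, rm: ResponseMatrix, y=None) -> "GRMLinker":
        if self.anchor_bank is None:
            raise ValueError("anchor_bank is required")
        anchor_ids = [it.item_id for it in self.anchor_bank if it.fixed]
        free = self.free_items
        if free is None:
            free = [i for i in rm.item_ids if i not in anchor_ids]
        self.calibration_ = fixed_anchor_link(
            rm, self.anchor_bank, free, self._grid(), self.tol, self.max_cycles
        )
        self.bank_ = self.calibration_.bank_out
        self.loglik_trace_ = self.calibration_.loglik_trace
        self.n_cycles_ = self.calibration_.n_cycles
        self.converged_ = self.calibration_.converged
        return self

    def transform(self, rm: ResponseMatrix, items: list[str] | None = None) -> pd.DataFrame:
        """EAP theta/SE/T-scores under the calibrated bank.

        ``items`` restricts scoring to a subset (e.g. anchors only or the
        linked battery only); default uses every calibrated item.
        """
        bank = self.bank_ if items is None else self.bank_.subset(items)
        X = rm.columns(bank.item_ids)
        theta, se, used = eap_score_matrix(X, bank, self._grid())
        return pd.DataFrame(
            {
                "theta": theta,
                "se": se,
                "t_score": 10 * theta + 50,
                "items_used": used,
            }
        )

    def crosswalk(self, items: list[str] | None = None) -> CrosswalkTable:
        if items is None:
            items = [it.item_id for it in self.bank_ if not it.fixed]
        return build_crosswalk(self.bank_.subset(items), self._grid())

    def item_fit(self, rm: ResponseMatrix, min_expected: float = 1.0):
        """S-X2 item fit of the calibrated bank on the fitting data."""
        sub = rm.select_items(self.bank_.item_ids)
        return s_x2_itemfit(sub, self.bank_, self._grid(), min_expected)
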