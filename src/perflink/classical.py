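"""Classical test theory and Mokken scalability diagnostics.

Covers the descriptive battery run on a pooled ordinal item set before IRT
calibration: Cronbach's alpha with leave-one-out deltas, corrected
item-total correlations, Loevinger's scalability coefficients (pairwise,
per-item, scale) and a rest-score-group monotonicity check.  All statistics
use complete cases over the selected item subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .data import ResponseMatrix

__all__ = [
    "cronbach_alpha",
    "corrected_item_total",
    "loevinger_h",
    "check_monotonicity",
    "ScaleEvalReport",
    "ScaleEvaluator",
]


def _complete_columns(rm: ResponseMatrix, items: list[str] | None) -> tuple[np.ndarray, list[str]]:
    items = list(items) if items is not None else list(rm.item_ids)
    sub = rm.complete_cases(items)
    return sub.responses.astype(float), items


def cronbach_alpha(
    rm: ResponseMatrix, items: list[str] | None = None
) -> tuple[float, dict[str, float]]:
    """Cronbach's alpha and per-item deletion deltas.

    alpha = (J / (J-1)) * (1 - sum_j var(X_j) / var(sum X)); the deletion
    delta for item j is alpha-without-j minus alpha.  Complete cases.
    """
    X, items = _complete_columns(rm, items)
    n, J = X.shape
    if J < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 2:
        raise ValueError("alpha needs at least 2 complete rows")

    def _alpha(M: np.ndarray) -> float:
        j = M.shape[1]
        tot_var = M.sum(axis=1).var(ddof=1)
        if tot_var <= 0:
            raise ValueError("zero total-score variance")
        return (j / (j - 1)) * (1 - M.var(axis=0, ddof=1).sum() / tot_var)

    alpha = _alpha(X)
    deltas = {}
    for j, iid in enumerate(items):
        reduced = np.delete(X, j, axis=1)
        deltas[iid] = _alpha(reduced) - alpha
    return float(alpha), deltas


def corrected_item_total(
    rm: ResponseMatrix, items: list[str] | None = None
) -> dict[str, float]:
    """Pearson correlation of each item with the sum of the remaining items.

    A constant item yields NaN (flagged by the caller), never a silent drop.
    """
    X, items = _complete_columns(rm, items)
    out = {}
    for j, iid in enumerate(items):
        rest = np.delete(X, j, axis=1).sum(axis=1)
        x = X[:, j]
        if x.std() == 0 or rest.std() == 0:
            out[iid] = float("nan")
            warnings.warn(f"constant item or rest score for {iid!r}", RuntimeWarning)
            continue
        out[iid] = float(np.corrcoef(x, rest)[0, 1])
    return out


def _comonotone_exy(x: np.ndarray, y: np.ndarray) -> float:
    """Max attainable E[XY] given both empirical marginals (comonotone coupling)."""
    n = x.size
    vx, cx = np.unique(x, return_counts=True)
    vy, cy = np.unique(y, return_counts=True)
    px, py = cx / n, cy / n
    i = j = 0
    rx, ry = px[0], py[0]
    exy = 0.0
    while i < vx.size and j < vy.size:
        m = min(rx, ry)
        exy += m * vx[i] * vy[j]
        rx -= m
        ry -= m
        if rx <= 1e-15:
            i += 1
            rx = px[i] if i < vx.size else 0.0
        if ry <= 1e-15:
            j += 1
            ry = py[j] if j < vy.size else 0.0
    return exy


def loevinger_h(
    rm: ResponseMatrix, items: list[str] | None = None
) -> tuple[float, dict[str, float], dict[tuple[str, str], float]]:
    """Loevinger's scalability coefficients (H_scale, per-item H_i, pairwise H_ij).

    H_ij = cov(X_i, X_j) / cov_max(X_i, X_j), where cov_max is the largest
    covariance attainable under the observed marginal category frequencies
    (comonotone pairing of the two marginals).  H_i and H_scale are
    ratio-of-sums aggregates over the pairs containing i and over all
    pairs.
    """
    X, items = _complete_columns(rm, items)
    J = len(items)
    if J < 2:
        raise ValueError("H needs at least 2 items")
    mean = X.mean(axis=0)
    cov = np.zeros((J, J))
    covmax = np.zeros((J, J))
    for i in range(J):
        for j in range(i + 1, J):
            c = float(np.mean(X[:, i] * X[:, j]) - mean[i] * mean[j])
            cm = _comonotone_exy(X[:, i], X[:, j]) - mean[i] * mean[j]
            if cm <= 1e-12:
                raise ValueError(
                    f"zero maximum covariance for pair ({items[i]!r}, {items[j]!r})"
                )
            cov[i, j] = cov[j, i] = c
            covmax[i, j] = covmax[j, i] = cm
    h_pair = {
        (items[i], items[j]): cov[i, j] / covmax[i, j]
        for i in range(J)
        for j in range(i + 1, J)
    }
    h_item = {
        items[i]: float(cov[i].sum() / covmax[i].sum()) for i in range(J)
    }
    iu = np.triu_indices(J, 1)
    h_scale = float(cov[iu].sum() / covmax[iu].sum())
    return h_scale, h_item, h_pair


def _rest_score_groups(rest: np.ndarray, min_group: int) -> np.ndarray:
    """Pool rest scores into ordered groups of at least ``min_group`` persons."""
    values = np.unique(rest)
    labels = np.empty(rest.size, dtype=int)
    group = 0
    count = 0
    for v in values:
        sel = rest == v
        labels[sel] = group
        count += int(sel.sum())
        if count >= min_group:
            group += 1
            count = 0
    if count and group > 0:
        labels[labels == group] = group - 1  # merge trailing remainder
    return labels


def check_monotonicity(
    rm: ResponseMatrix,
    items: list[str] | None = None,
    min_group: int | None = None,
    alpha: float = 0.05,
    minvi: float = 0.03,
) -> dict[str, int]:
    """Count significant ("active") monotonicity violations per item.

    For each item, persons are pooled into rest-score groups (rest score =
    total minus the item; adjacent scores merged until each group holds at
    least ``min_group`` persons, default max(50, n/10)).  A violation is a
    higher rest-score group with a lower estimated P(X >= k) by at least
    ``minvi`` (the conventional minimum violation size, screening out
    trivial wiggles in flat ICC regions); each is tested by a one-sided
    two-proportion z-test at ``alpha`` and only significant violations are
    counted.
    """
    X, items = _complete_columns(rm, items)
    n = X.shape[0]
    if min_group is None:
        min_group = max(50, n // 10)
    out: dict[str, int] = {}
    for j, iid in enumerate(items):
        rest = np.delete(X, j, axis=1).sum(axis=1)
        labels = _rest_score_groups(rest, min_group)
        n_groups = labels.max() + 1
        if n_groups < 2:
            warnings.warn(
                f"item {iid!r}: fewer than 2 rest-score groups, "
                "monotonicity not assessable",
                RuntimeWarning,
            )
            out[iid] = 0
            continue
        active = 0
        m = int(X[:, j].max()) + 1
        sizes = np.array([(labels == g).sum() for g in range(n_groups)])
        for k in range(1, m):
            ge = (X[:, j] >= k).astype(float)
            p = np.array([ge[labels == g].mean() for g in range(n_groups)])
            for g in range(n_groups):
                for h in range(g + 1, n_groups):
                    if p[g] - p[h] >= minvi:
                        pool = (p[g] * sizes[g] + p[h] * sizes[h]) / (sizes[g] + sizes[h])
                        se = np.sqrt(pool * (1 - pool) * (1 / sizes[g] + 1 / sizes[h]))
                        if se == 0:
                            continue
                        z = (p[g] - p[h]) / se
                        if stats.norm.sf(z) < alpha:
                            active += 1
        out[iid] = active
    return out


@dataclass
class ScaleEvalReport:
    alpha: float
    alpha_if_deleted: dict[str, float]
    item_total_corr: dict[str, float]
    h_scale: float
    h_item: dict[str, float]
    h_pair: dict[tuple[str, str], float]
    monotonicity_violations: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Per-item table mirroring the usual published layout."""
        items = list(self.item_total_corr)
        return pd.DataFrame(
            {
                "item_id": items,
                "r_itc": [self.item_total_corr[i] for i in items],
                "H_i": [self.h_item[i] for i in items],
                "alpha_if_deleted_delta": [self.alpha_if_deleted[i] for i in items],
                "monotonicity_violations": [
                    self.monotonicity_violations[i] for i in items
                ],
            }
        )


class ScaleEvaluator(BaseEstimator):
    """Classical + Mokken scale diagnostics as a fit-once estimator.

    Parameters
    ----------
    items : list of str, optional
        Item subset to analyze (default: every item in the matrix).
    min_group : int, optional
        Minimum rest-score group size for the monotonicity check.
    alpha_level : float
        Significance level of the one-sided violation test.

    Attributes (after ``fit``)
    --------------------------
    alpha_, alpha_if_deleted_, item_total_corr_, h_scale_, h_item_,
    h_pair_, monotonicity_violations_, report_ : ScaleEvalReport
    """

    def __init__(self, items=None, min_group=None, alpha_level: float = 0.05):
        self.items = items
        self.min_group = min_group
        self.alpha_level = alpha_level

    def fit(self, rm: ResponseMatrix, y=None) -> "ScaleEvaluator":
        if not isinstance(rm, ResponseMatrix):
            rm = ResponseMatrix(np.asarray(rm), [f"item{i}" for i in range(np.asarray(rm).shape[1])])
        self.alpha_, self.alpha_if_deleted_ = cronbach_alpha(rm, self.items)
        self.item_total_corr_ = corrected_item_total(rm, self.items)
        self.h_scale_, self.h_item_, self.h_pair_ = loevinger_h(rm, self.items)
        self.monotonicity_violations_ = check_monotonicity(
            rm, self.items, self.min_group, self.alpha_level
        )
        self.report_ = ScaleEvalReport(
            alpha=self.alpha_,
            alpha_if_deleted=self.alpha_if_deleted_,
            item_total_corr=self.item_total_corr_,
            h_scale=self.h_scale_,
            h_item=self.h_item_,
            h_pair=self.h_pair_,
            monotonicity_violations=self.monotonicity_violations_,
        )
        return self
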