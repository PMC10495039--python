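"""Differential item functioning by ordinal logistic regression.

Per item, three nested cumulative-logit (proportional-odds) models are
compared: trait only (m1), trait + group (m2, uniform DIF), trait + group +
trait x group (m3, non-uniform DIF).  Likelihood-ratio p-values and the
Nagelkerke pseudo-R2 change between m3 and m1 quantify DIF; items exceeding
a configurable R2-change threshold (default 0.03) are flagged.  Multi-level
group variables enter as indicator sets, so the R2 change is joint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .data import MISSING, ResponseMatrix

__all__ = [
    "fit_proportional_odds",
    "nagelkerke_r2",
    "dif_scan",
    "DIFResult",
    "DIFScanner",
]


def fit_proportional_odds(
    y: np.ndarray, X: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative-logit proportional-odds fit.

    Returns ``(coefficients, cutpoints, loglik)``.  With no covariates the
    maximized log-likelihood has the closed multinomial form
    ``sum_k n_k log(n_k / n)`` and the cutpoints are the logit cumulative
    proportions.  Divergent coefficients (|beta| > 15) are reported as
    probable separation.
    """
    y = np.asarray(y, dtype=np.int64)
    cats, counts = np.unique(y, return_counts=True)
    if cats.size < 2:
        raise ValueError("response needs at least 2 observed categories")
    n = y.size
    if X is None or (hasattr(X, "shape") and np.size(X) == 0):
        p = counts / n
        cum = np.cumsum(p)[:-1]
        cutpoints = np.log(cum / (1 - cum))
        loglik = float(np.sum(counts * np.log(p)))
        return np.empty(0), cutpoints, loglik
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("X rows must match y length")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant covariate column")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    # recode to consecutive categories for statsmodels
    ycode = np.searchsorted(cats, y)
    model = OrderedModel(ycode, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", disp=False, maxiter=500)
    if not res.mle_retvals.get("converged", True):
        warnings.warn("proportional-odds fit did not converge", RuntimeWarning)
    beta = np.asarray(res.params[: X.shape[1]])
    if np.any(np.abs(beta) > 15):
        warnings.warn(
            "divergent coefficient: probable (quasi-)separation", RuntimeWarning
        )
    # statsmodels stores the first cutpoint and log-increments
    raw = np.asarray(res.params[X.shape[1]:])
    cutpoints = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
    return beta, cutpoints, float(res.llf)


def nagelkerke_r2(loglik_model: float, loglik_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2 (Cox-Snell rescaled to a [0, 1] maximum)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_model < loglik_null - 1e-8:
        raise ValueError("model log-likelihood below null log-likelihood")
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_model))
    max_r2 = 1.0 - np.exp((2.0 / n) * loglik_null)
    if max_r2 <= 0:
        return 0.0
    return float(cox_snell / max_r2)


@dataclass
class DIFResult:
    item_id: str
    group_var: str
    loglik_m1: float
    loglik_m2: float
    loglik_m3: float
    lr_p_uniform: float
    lr_p_nonuniform: float
    lr_p_total: float
    r2_m1: float
    r2_m3: float
    r2_change: float
    flagged: bool


def dif_scan(
    rm: ResponseMatrix,
    items: list[str],
    group_var: str,
    trait_scores: np.ndarray,
    threshold: float = 0.03,
) -> list[DIFResult]:
    """Screen each item for DIF with respect to one group variable.

    ``trait_scores`` is the conditioning trait (typically the EAP score from
    the full fixed-anchor calibration).  Per item, m1/m2/m3 are fitted on
    persons with an observed response; likelihood-ratio p-values for
    uniform (m2 vs m1), non-uniform (m3 vs m2) and total (m3 vs m1) DIF are
    reported along with the Nagelkerke R2 change m3 - m1.  Items with
    R2 change above ``threshold`` are flagged.
    """
    if group_var not in rm.covariates.columns:
        raise ValueError(f"unknown group variable {group_var!r}")
    groups = rm.covariates[group_var]
    levels = groups.dropna().unique()
    if len(levels) < 2:
        raise ValueError(f"group variable {group_var!r} has fewer than 2 levels")
    counts = groups.value_counts()
    small = counts[counts < 10]
    if len(small):
        warnings.warn(
            f"group level(s) with <10 respondents: {list(small.index)}",
            RuntimeWarning,
        )
    dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
    trait = np.asarray(trait_scores, dtype=float)
    if trait.shape != (rm.n_persons,):
        raise ValueError("trait_scores not aligned with persons")
    L1 = dummies.shape[1]  # group df
    results = []
    for iid in items:
        y = rm.column(iid)
        keep = (y != MISSING) & np.isfinite(trait) & groups.notna().to_numpy()
        yk = y[keep]
        tk = trait[keep]
        G = dummies.to_numpy()[keep]
        n = yk.size
        X1 = tk[:, None]
        X2 = np.column_stack([X1, G])
        X3 = np.column_stack([X2, G * tk[:, None]])
        _, _, ll_null = fit_proportional_odds(yk, None)
        _, _, ll1 = fit_proportional_odds(yk, X1)
        _, _, ll2 = fit_proportional_odds(yk, X2)
        _, _, ll3 = fit_proportional_odds(yk, X3)
        # enforce nesting against small numeric slack
        ll2 = max(ll2, ll1)
        ll3 = max(ll3, ll2)
        r2_1 = nagelkerke_r2(ll1, ll_null, n)
        r2_3 = nagelkerke_r2(ll3, ll_null, n)
        dr2 = max(r2_3 - r2_1, 0.0)
        results.append(
            DIFResult(
                item_id=iid,
                group_var=group_var,
                loglik_m1=ll1,
                loglik_m2=ll2,
                loglik_m3=ll3,
                lr_p_uniform=float(stats.chi2.sf(2 * (ll2 - ll1), L1)),
                lr_p_nonuniform=float(stats.chi2.sf(2 * (ll3 - ll2), L1)),
                lr_p_total=float(stats.chi2.sf(2 * (ll3 - ll1), 2 * L1)),
                r2_m1=r2_1,
                r2_m3=r2_3,
                r2_change=dr2,
                flagged=bool(dr2 > threshold),
            )
        )
    return results


class DIFScanner(BaseEstimator):
    """Ordinal-logistic DIF screening over one or more group variables.

    Parameters
    ----------
    group_vars : list of str
        Covariate names to screen.
    items : list of str, optional
        Items to screen (default: all items in the matrix).
    threshold : float
        Nagelkerke R2-change flagging threshold (default 0.03).

    Attributes (after ``fit``)
    --------------------------
    results_ : list[DIFResult]
    table_ : pandas.DataFrame — one row per item x group variable.
    flagged_ : list[tuple[str, str]]
    """

    def __init__(self, group_vars: list[str] | None = None,
                 items: list[str] | None = None, threshold: float = 0.03):
        self.group_vars = group_vars
        self.items = items
        self.threshold = threshold

    def fit(self, rm: ResponseMatrix, trait_scores: np.ndarray) -> "DIFScanner":
        if not self.group_vars:
            raise ValueError("group_vars is required")
        items = self.items if self.items is not None else list(rm.item_ids)
        self.results_ = []
        for gv in self.group_vars:
            self.results_.extend(
                dif_scan(rm, items, gv, trait_scores, self.threshold)
            )
        self.table_ = pd.DataFrame([vars(r) for r in self.results_])
        self.flagged_ = [
            (r.item_id, r.group_var) for r in self.results_ if r.flagged
        ]
        return self
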