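"""Ordinal factor analysis on polychoric correlations.

Two workhorses:

* a confirmatory factor model (each item loads exactly one factor,
  correlated factors) fitted by diagonally weighted least squares (DWLS):
  the weighted discrepancy between observed and model-implied polychoric
  correlations, weights being inverse asymptotic variances of the
  polychorics.  Fit indices (CFI/TLI/RMSEA/SRMSR) use the standard
  discrepancy-based chi-square formulas against an independence baseline —
  no mean-variance (WLSMV) robustification.

* a bifactor decomposition by Schmid-Leiman: a first-order correlated-factor
  solution on the user-supplied subdomain partition, a second-order general
  factor extracted from the factor correlations, and orthogonalization into
  general + specific loadings.  From these come the essential-
  unidimensionality indices ECV, omegaH and (from the same partition) PUC.
  Anchoring the first-order structure on the partition, rather than on an
  oblique rotation, keeps the decomposition well defined when the data are
  close to unidimensional — the case an oblique rotation degenerates on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .data import ResponseMatrix
from .polychoric import PolychoricMatrix, polychoric_matrix

__all__ = [
    "FactorSolution",
    "BifactorSolution",
    "fit_factor_model",
    "latent_instrument_correlation",
    "bifactor_indices",
    "bifactor_indices_from_loadings",
    "puc_from_partition",
    "PolychoricCFA",
    "BifactorAnalyzer",
]


# ---------------------------------------------------------------------------
# confirmatory DWLS
# ---------------------------------------------------------------------------
@dataclass
class FactorSolution:
    loadings: pd.DataFrame  # items x factors (zero where unpatterned)
    factor_corr: pd.DataFrame
    residual_corr: np.ndarray  # items x items, zero diagonal
    fit: dict[str, float]  # CFI, TLI, RMSEA, SRMSR, chi2, df
    converged: bool
    heywood: bool
    item_ids: list[str] = field(default_factory=list)


def _pattern_to_assignment(
    pattern: dict[str, list[str]], item_ids: list[str]
) -> np.ndarray:
    factors = list(pattern)
    assign = np.full(len(item_ids), -1, dtype=int)
    for f, ids in pattern.items():
        for iid in ids:
            if iid not in item_ids:
                raise ValueError(f"unknown item {iid!r} in pattern")
            j = item_ids.index(iid)
            if assign[j] != -1:
                raise ValueError(f"item {iid!r} assigned to two factors")
            assign[j] = factors.index(f)
    if (assign == -1).any():
        missing = [item_ids[j] for j in np.nonzero(assign == -1)[0]]
        raise ValueError(f"items without a factor: {missing}")
    return assign


def fit_factor_model(
    pm: PolychoricMatrix, pattern: dict[str, list[str]]
) -> FactorSolution:
    """DWLS fit of a simple-structure factor model to polychorics.

    ``pattern`` maps factor names to item-id lists; each item loads exactly
    one factor and every factor needs at least two items (single-item
    factors are unidentified and rejected).
    """
    item_ids = pm.item_ids
    assign = _pattern_to_assignment(pattern, item_ids)
    factors = list(pattern)
    k = len(factors)
    for f, ids in pattern.items():
        if len(ids) < 2:
            raise ValueError(
                f"factor {f!r} has {len(ids)} item(s); single-item factors "
                "are not identified"
            )
    J = len(item_ids)
    iu, ju = np.triu_indices(J, 1)
    r_obs = pm.rho[iu, ju]
    w = 1.0 / np.clip(pm.avar[iu, ju], 1e-12, None)
    n_phi = k * (k - 1) // 2
    pl, pj = np.triu_indices(k, 1)

    def implied(x: np.ndarray) -> np.ndarray:
        lam = x[:J]
        phi = np.eye(k)
        if n_phi:
            phi[pl, pj] = phi[pj, pl] = np.tanh(x[J:])
        return lam[iu] * lam[ju] * phi[assign[iu], assign[ju]]

    def objective(x: np.ndarray) -> float:
        d = r_obs - implied(x)
        return float(np.sum(w * d * d))

    x0 = np.concatenate([np.full(J, 0.6), np.zeros(n_phi)])
    bounds = [(-1.2, 1.2)] * J + [(-5.0, 5.0)] * n_phi
    res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
    lam = res.x[:J].copy()
    phi = np.eye(k)
    if n_phi:
        phi[pl, pj] = phi[pj, pl] = np.tanh(res.x[J:])
    # resolve the sign indeterminacy per factor toward positive loadings,
    # flipping the matching factor correlations to keep the model invariant
    flip = np.ones(k)
    for f in range(k):
        if lam[assign == f].sum() < 0:
            flip[f] = -1.0
            lam[assign == f] *= -1.0
    phi = phi * np.outer(flip, flip)
    heywood = bool((np.abs(lam) > 1.0).any())
    if heywood:
        warnings.warn("Heywood case: |loading| > 1", RuntimeWarning)

    resid = np.zeros((J, J))
    model = lam[iu] * lam[ju] * phi[assign[iu], assign[ju]]
    resid[iu, ju] = resid[ju, iu] = r_obs - model

    chi2 = objective(res.x)
    n_free = J + n_phi
    df = J * (J - 1) // 2 - n_free
    chi2_base = float(np.sum(w * r_obs * r_obs))
    df_base = J * (J - 1) // 2
    N = max(pm.n_obs, 2)
    d_m = max(chi2 - df, 0.0)
    d_b = max(chi2_base - df_base, 0.0)
    cfi = 1.0 if d_b == 0 else 1.0 - d_m / max(d_b, d_m)
    if df > 0 and df_base > 0 and chi2_base / df_base > 1:
        tli = ((chi2_base / df_base) - (chi2 / df)) / ((chi2_base / df_base) - 1)
        tli = min(tli, 1.0)
    else:
        tli = 1.0
    rmsea = np.sqrt(max(chi2 / df - 1, 0.0) / (N - 1)) if df > 0 else 0.0
    srmsr = float(np.sqrt(np.mean((r_obs - model) ** 2)))

    L = np.zeros((J, k))
    L[np.arange(J), assign] = lam
    return FactorSolution(
        loadings=pd.DataFrame(L, index=item_ids, columns=factors),
        factor_corr=pd.DataFrame(phi, index=factors, columns=factors),
        residual_corr=resid,
        fit={
            "CFI": float(cfi),
            "TLI": float(tli),
            "RMSEA": float(rmsea),
            "SRMSR": srmsr,
            "chi2": float(chi2),
            "df": int(df),
        },
        converged=bool(res.success),
        heywood=heywood,
        item_ids=item_ids,
    )


def latent_instrument_correlation(
    rm: ResponseMatrix, anchor_items: list[str], new_items: list[str]
) -> float:
    """Correlation of the latent variables underlying two instruments.

    Fits a two-factor model (one factor per instrument) on the polychoric
    matrix of the pooled items and returns the factor correlation.
    """
    if len(anchor_items) < 2 or len(new_items) < 2:
        raise ValueError("each instrument needs at least 2 items")
    pm = polychoric_matrix(rm, list(anchor_items) + list(new_items))
    sol = fit_factor_model(pm, {"anchor": list(anchor_items), "new": list(new_items)})
    return float(sol.factor_corr.iloc[0, 1])


# ---------------------------------------------------------------------------
# exploratory bifactor (Schmid-Leiman)
# ---------------------------------------------------------------------------
def _principal_axis(R: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis factoring; returns (J, k) loadings."""
    J = R.shape[0]
    try:
        h2 = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        h2 = np.full(J, 0.5)
    h2 = np.clip(h2, 0.05, 0.995)
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        order = np.argsort(vals)[::-1][:k]
        lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
        h2_new = np.clip((lam**2).sum(axis=1), 0.0, 0.995)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    vals, vecs = np.linalg.eigh(Rr)
    order = np.argsort(vals)[::-1][:k]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    # orient each factor positively
    lam *= np.where(lam.sum(axis=0) < 0, -1.0, 1.0)
    return lam


def puc_from_partition(partition: dict[str, list[str]], item_ids: list[str]) -> float:
    """Percentage of uncontaminated correlations for an item partition.

    PUC = [C(J,2) - sum_s C(J_s,2)] / C(J,2): the share of item pairs not
    sharing a specific factor.
    """
    covered = [iid for ids in partition.values() for iid in ids]
    if sorted(covered) != sorted(item_ids):
        raise ValueError("partition must cover every item exactly once")
    J = len(item_ids)
    total = J * (J - 1) // 2
    within = sum(len(ids) * (len(ids) - 1) // 2 for ids in partition.values())
    return (total - within) / total


@dataclass
class BifactorSolution:
    general_loadings: pd.Series
    specific_loadings: pd.DataFrame  # items x specific factors (SL solution)
    ecv: float
    omega_h: float
    puc: float
    specific_groups: dict[str, list[str]]
    factor_match: dict[str, int] = field(default_factory=dict)


def bifactor_indices_from_loadings(
    g: np.ndarray,
    specific: np.ndarray,
    group_cols: dict[str, int],
    partition: dict[str, list[str]],
    item_ids: list[str],
) -> tuple[float, float, float]:
    """(ECV, omegaH, PUC) from a fixed general/specific loading matrix.

    ECV = sum g^2 / (sum g^2 + sum_all lambda_s^2);
    omegaH = (sum g)^2 / [(sum g)^2 + sum_s (sum_{j in s} lambda_js)^2
             + sum_j (1 - h2_j)] with h2 the row communality;
    PUC from the partition by the pair-counting formula.
    """
    g = np.asarray(g, dtype=float)
    specific = np.asarray(specific, dtype=float)
    ssg = float(np.sum(g**2))
    sss = float(np.sum(specific**2))
    ecv = ssg / (ssg + sss)
    h2 = g**2 + (specific**2).sum(axis=1)
    sum_g = float(np.sum(g))
    spec_terms = 0.0
    for grp, col in group_cols.items():
        rows = [item_ids.index(i) for i in partition[grp]]
        spec_terms += float(specific[rows, col].sum()) ** 2
    omega_h = sum_g**2 / (sum_g**2 + spec_terms + float(np.sum(1 - h2)))
    return ecv, omega_h, puc_from_partition(partition, item_ids)


def bifactor_indices(
    pm: PolychoricMatrix,
    specific_groups: dict[str, list[str]],
    n_specific: int | None = None,
) -> BifactorSolution:
    """Schmid-Leiman bifactor analysis with ECV/omegaH/PUC.

    First-order correlated factors follow the supplied subdomain partition
    (one factor per group, fitted by DWLS on the polychorics); a
    second-order general factor is extracted by principal axis from the
    factor correlations, and the Schmid-Leiman transform orthogonalizes the
    solution into one general + uncorrelated specific factors:
    ``g = pattern @ gamma`` and ``lambda_s = pattern * sqrt(1 - gamma^2)``.
    """
    if n_specific is None:
        n_specific = len(specific_groups)
    if n_specific != len(specific_groups):
        raise ValueError("n_specific must equal the number of partition groups")
    if n_specific < 2:
        raise ValueError("need at least 2 specific factors")
    item_ids = pm.item_ids
    # validates the partition early (also used for PUC)
    puc = puc_from_partition(specific_groups, item_ids)
    first = fit_factor_model(pm, specific_groups)
    pattern = first.loadings.to_numpy()  # (J, k), simple structure
    phi = first.factor_corr.to_numpy()
    if np.linalg.matrix_rank(phi) < phi.shape[0]:
        raise ValueError("singular factor correlation matrix")
    # second-order single factor on the factor correlations
    gamma = _principal_axis(phi, 1)[:, 0]
    gamma = np.clip(np.abs(gamma), 0.0, 0.9995)
    g = pattern @ gamma
    spec = pattern * np.sqrt(1.0 - gamma**2)[None, :]
    if g.sum() < 0:
        g = -g
    groups = list(specific_groups)
    match = {grp: k for k, grp in enumerate(groups)}
    ecv, omega_h, _ = bifactor_indices_from_loadings(
        g, spec, match, specific_groups, item_ids
    )
    return BifactorSolution(
        general_loadings=pd.Series(g, index=item_ids, name="g"),
        specific_loadings=pd.DataFrame(
            spec, index=item_ids, columns=[f"S{c + 1}" for c in range(spec.shape[1])]
        ),
        ecv=float(ecv),
        omega_h=float(omega_h),
        puc=float(puc),
        specific_groups=specific_groups,
        factor_match=match,
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------
class PolychoricCFA(BaseEstimator):
    """Confirmatory DWLS factor analysis on polychoric correlations.

    Parameters
    ----------
    pattern : dict[str, list[str]]
        Factor name -> item ids (each item on exactly one factor).

    Attributes (after ``fit``)
    --------------------------
    polychoric_ : PolychoricMatrix
    loadings_, factor_corr_, residual_corr_, fit_indices_, converged_
    """

    def __init__(self, pattern: dict[str, list[str]] | None = None):
        self.pattern = pattern

    def fit(self, rm: ResponseMatrix, y=None) -> "PolychoricCFA":
        pattern = self.pattern
        if pattern is None:
            pattern = {"F1": list(rm.item_ids)}
        items = [iid for ids in pattern.values() for iid in ids]
        self.polychoric_ = polychoric_matrix(rm, items)
        sol = fit_factor_model(self.polychoric_, pattern)
        self.solution_ = sol
        self.loadings_ = sol.loadings
        self.factor_corr_ = sol.factor_corr
        self.residual_corr_ = sol.residual_corr
        self.fit_indices_ = sol.fit
        self.converged_ = sol.converged
        return self


class BifactorAnalyzer(BaseEstimator):
    """Exploratory Schmid-Leiman bifactor analysis with ECV/omegaH/PUC.

    Parameters
    ----------
    specific_groups : dict[str, list[str]]
        Partition of the items into subdomains, one specific factor each.
    n_specific : int, optional
        Number of first-order factors (default: number of groups).
    """

    def __init__(self, specific_groups: dict[str, list[str]] | None = None,
                 n_specific: int | None = None):
        self.specific_groups = specific_groups
        self.n_specific = n_specific

    def fit(self, rm: ResponseMatrix, y=None) -> "BifactorAnalyzer":
        if self.specific_groups is None:
            raise ValueError("specific_groups partition is required")
        items = [iid for ids in self.specific_groups.values() for iid in ids]
        self.polychoric_ = polychoric_matrix(rm, items)
        sol = bifactor_indices(self.polychoric_, self.specific_groups, self.n_specific)
        self.solution_ = sol
        self.general_loadings_ = sol.general_loadings
        self.specific_loadings_ = sol.specific_loadings
        self.ecv_ = sol.ecv
        self.omega_h_ = sol.omega_h
        self.puc_ = sol.puc
        return self
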