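"""Polychoric correlations: the substrate for ordinal factor analysis.

Each ordinal item is treated as a discretized standard normal variate;
thresholds come from inverse-normal transforms of cumulative marginal
proportions and each pairwise latent correlation maximizes the bivariate
normal contingency-table likelihood with the thresholds held fixed (the
usual two-step estimator), on pairwise-complete observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.stats import multivariate_normal

from .data import MISSING, ResponseMatrix

__all__ = ["PolychoricMatrix", "polychoric_matrix", "polychoric_rho"]

_RHO_BOUND = 0.999


@dataclass
class PolychoricMatrix:
    """Symmetric polychoric correlation matrix with per-item thresholds."""

    rho: np.ndarray
    thresholds: list[np.ndarray]
    item_ids: list[str]
    pairwise_n: np.ndarray
    avar: np.ndarray  # asymptotic variance of each pairwise rho
    n_obs: int

    @property
    def n_items(self) -> int:
        return len(self.item_ids)


def _thresholds_from_margin(col: np.ndarray) -> np.ndarray:
    obs = col[col != MISSING]
    if obs.size == 0:
        raise ValueError("item has no observed responses")
    counts = np.bincount(obs)
    if (counts > 0).sum() < 2:
        raise ValueError("item shows a single observed category")
    cum = np.cumsum(counts)[:-1] / obs.size
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    tau = stats.norm.ppf(cum)
    return np.maximum.accumulate(tau + np.arange(tau.size) * 1e-9)


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Bivariate-normal rectangle probabilities over the threshold grid."""
    gx = np.concatenate([[-np.inf], tau_x, [np.inf]])
    gy = np.concatenate([[-np.inf], tau_y, [np.inf]])
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    finite = np.isfinite(pts).all(axis=1)
    F = np.zeros(pts.shape[0])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    if finite.any():
        F[finite] = mvn.cdf(pts[finite])
    # cells touching +inf reduce to marginal or joint limits
    xinf = np.isinf(pts[:, 0]) & (pts[:, 0] > 0)
    yinf = np.isinf(pts[:, 1]) & (pts[:, 1] > 0)
    F[xinf & ~np.isinf(pts[:, 1])] = stats.norm.cdf(pts[xinf & ~np.isinf(pts[:, 1]), 1])
    F[yinf & ~np.isinf(pts[:, 0])] = stats.norm.cdf(pts[yinf & ~np.isinf(pts[:, 0]), 0])
    F[xinf & yinf] = 1.0
    # -inf rows/cols are 0 (already)
    F = F.reshape(gx.size, gy.size)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-12, None)


def polychoric_rho(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, int]:
    """Two-step polychoric correlation for one item pair.

    Returns ``(rho, avar, n)`` with the asymptotic variance taken from the
    observed information (negative second derivative of the pairwise
    profile log-likelihood at the optimum, numerically).  Falls back to the
    Pearson correlation of the codes, with a warning, if the likelihood
    optimization fails.
    """
    both = (x != MISSING) & (y != MISSING)
    xs, ys = x[both], y[both]
    n = int(both.sum())
    if n < 10:
        raise ValueError("too few pairwise-complete observations")
    tau_x = _thresholds_from_margin(xs)
    tau_y = _thresholds_from_margin(ys)
    table = np.zeros((tau_x.size + 1, tau_y.size + 1))
    np.add.at(table, (xs, ys), 1.0)

    def negll(rho: float) -> float:
        return -float(np.sum(table * np.log(_cell_probs(tau_x, tau_y, rho))))

    try:
        res = optimize.minimize_scalar(
            negll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
            options={"xatol": 1e-6},
        )
        rho = float(res.x)
        h = 1e-4
        r_lo = max(rho - h, -_RHO_BOUND)
        r_hi = min(rho + h, _RHO_BOUND)
        d2 = (negll(r_hi) - 2 * negll(rho) + negll(r_lo)) / ((r_hi - rho) * (rho - r_lo))
        avar = 1.0 / d2 if d2 > 0 else np.nan
    except Exception:  # pragma: no cover - defensive fallback
        warnings.warn("polychoric optimization failed, using Pearson fallback",
                      RuntimeWarning)
        rho = float(np.corrcoef(xs, ys)[0, 1])
        avar = (1 - rho**2) ** 2 / n
    if not np.isfinite(avar) or avar <= 0:
        avar = (1 - rho**2) ** 2 / n
    return rho, float(avar), n


def polychoric_matrix(
    rm: ResponseMatrix, items: list[str] | None = None
) -> PolychoricMatrix:
    """Pairwise polychoric correlation matrix for the selected items."""
    items = list(items) if items is not None else list(rm.item_ids)
    cols = [rm.column(i) for i in items]
    thresholds = [_thresholds_from_margin(c) for c in cols]
    J = len(items)
    rho = np.eye(J)
    avar = np.zeros((J, J))
    pairwise_n = np.zeros((J, J), dtype=int)
    for i in range(J):
        pairwise_n[i, i] = int((cols[i] != MISSING).sum())
        for j in range(i + 1, J):
            r, v, n = polychoric_rho(cols[i], cols[j])
            rho[i, j] = rho[j, i] = np.clip(r, -_RHO_BOUND, _RHO_BOUND)
            avar[i, j] = avar[j, i] = v
            pairwise_n[i, j] = pairwise_n[j, i] = n
    return PolychoricMatrix(
        rho=rho,
        thresholds=thresholds,
        item_ids=items,
        pairwise_n=pairwise_n,
        avar=avar,
        n_obs=rm.n_persons,
    )
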