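"""Graded response model (GRM) machinery.

The GRM for an item with ``m`` ordered categories and parameters
``(a, b_1 < ... < b_{m-1})`` sets cumulative category probabilities

    P*(X >= k | theta) = 1 / (1 + exp(-a (theta - b_k)))

with ``P*(X >= 0) = 1`` and ``P*(X >= m) = 0``; category probabilities are
adjacent differences.  This module provides:

* category probabilities and response-pattern likelihoods,
* a normal-prior quadrature grid,
* marginal maximum likelihood estimation by EM with a fixable parameter
  mask (the basis of fixed-anchor linking),
* expected a posteriori (EAP) trait scoring and the affine T transform
  ``T = 10 theta + 50``,
* the Lord-Wingersky recursion for summed-score distributions,
* the S-X2 item-fit statistic (observed vs expected category frequencies
  conditional on rest scores).

The latent prior is standard normal throughout and is never re-estimated:
holding the prior at N(0, 1) while anchor parameters stay fixed is what
keeps estimated parameters, and therefore T-scores, on the anchor metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .bank import Item, ItemBank
from .data import MISSING, ResponseMatrix

__all__ = [
    "QuadratureGrid",
    "make_grid",
    "grm_category_probs",
    "pattern_loglik",
    "em_calibrate",
    "CalibrationResult",
    "eap_score",
    "eap_score_matrix",
    "ScoredPerson",
    "to_tscore",
    "lw_sumscore_dist",
    "s_x2_itemfit",
    "ItemFitResult",
    "starting_values",
    "calibration_standard_errors",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# quadrature
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class QuadratureGrid:
    """Equally spaced nodes with normalized standard-normal prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or weights.shape != nodes.shape:
            raise ValueError("nodes and weights must be 1-D and aligned")
        if np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing")
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / weights.sum())

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


def make_grid(n_nodes: int = 61, span: float = 6.0) -> QuadratureGrid:
    """Equally spaced grid on [-span, span] with N(0,1) mass weights."""
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    nodes = np.linspace(-span, span, n_nodes)
    return QuadratureGrid(nodes, stats.norm.pdf(nodes))


# ---------------------------------------------------------------------------
# category probabilities and likelihoods
# ---------------------------------------------------------------------------
def _cat_probs(slope: float, thresholds: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities, shape (n_cat, len(theta))."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(thresholds, dtype=float)
    # cumulative P*(X>=k), k = 1..m-1; exp overflow saturates correctly
    with np.errstate(over="ignore"):
        cum = 1.0 / (1.0 + np.exp(-slope * (theta[None, :] - b[:, None])))
    upper = np.vstack([np.ones_like(theta)[None, :], cum])
    lower = np.vstack([cum, np.zeros_like(theta)[None, :]])
    return upper - lower


def grm_category_probs(item: Item, theta: float | np.ndarray) -> np.ndarray:
    """P(X = k | theta) for k = 0..m-1.

    Returns a length-m vector for scalar ``theta``, else shape
    ``(m, len(theta))``.
    """
    p = _cat_probs(item.slope, np.array(item.thresholds), theta)
    return p[:, 0] if np.isscalar(theta) else p


def _bank_probs(bank: ItemBank, grid: QuadratureGrid) -> list[np.ndarray]:
    return [_cat_probs(it.slope, np.array(it.thresholds), grid.nodes) for it in bank]


def _log_pattern_likelihoods(
    X: np.ndarray, bank: ItemBank, grid: QuadratureGrid
) -> np.ndarray:
    """log P(pattern_i | theta_q), shape (n, Q); missing items contribute 0."""
    n, J = X.shape
    logL = np.zeros((n, grid.n_nodes))
    probs = _bank_probs(bank, grid)
    for j in range(J):
        obs = X[:, j] != MISSING
        if not obs.any():
            continue
        logP = np.log(np.clip(probs[j], _EPS, None))
        logL[obs] += logP[X[obs, j], :]
    return logL


def pattern_loglik(
    pattern: np.ndarray, bank: ItemBank, theta: float
) -> float:
    """Log-likelihood of one response pattern at a fixed theta.

    Missing entries (code -1) are skipped; an all-missing pattern has
    log-likelihood 0.
    """
    pattern = np.asarray(pattern)
    if pattern.shape != (len(bank),):
        raise ValueError("pattern length must equal bank size")
    ll = 0.0
    for code, item in zip(pattern, bank):
        if code == MISSING:
            continue
        if not 0 <= code < item.n_cat:
            raise ValueError(
                f"code {code} out of range for item {item.item_id!r}"
            )
        p = grm_category_probs(item, float(theta))[int(code)]
        ll += float(np.log(max(p, _EPS)))
    return ll


# ---------------------------------------------------------------------------
# EAP scoring and T transform
# ---------------------------------------------------------------------------
def to_tscore(theta: float | np.ndarray) -> float | np.ndarray:
    """Affine T-score transform: T = 10 * theta + 50."""
    return 10.0 * np.asarray(theta, dtype=float) + 50.0 if not np.isscalar(theta) else 10.0 * theta + 50.0


@dataclass(frozen=True)
class ScoredPerson:
    theta_eap: float
    se_eap: float
    t_score: float
    items_used: int
    method: str = "pattern_eap"


def eap_score_matrix(
    X: np.ndarray, bank: ItemBank, grid: QuadratureGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EAP trait estimates for a whole response matrix.

    Returns ``(theta, se, items_used)`` arrays.  The posterior over the
    grid is likelihood x prior mass; persons with no observed responses get
    the prior mean and SD.
    """
    logL = _log_pattern_likelihoods(X, bank, grid)
    logpost = logL + np.log(grid.weights)[None, :]
    logpost -= logpost.max(axis=1, keepdims=True)
    mass = np.exp(logpost)
    mass /= mass.sum(axis=1, keepdims=True)
    theta = mass @ grid.nodes
    second = mass @ (grid.nodes**2)
    se = np.sqrt(np.maximum(second - theta**2, 0.0))
    items_used = (X != MISSING).sum(axis=1)
    return theta, se, items_used


def eap_score(
    pattern: np.ndarray, bank: ItemBank, grid: QuadratureGrid
) -> ScoredPerson:
    """EAP score for a single response pattern."""
    pattern = np.asarray(pattern, dtype=np.int64).reshape(1, -1)
    if pattern.shape[1] != len(bank):
        raise ValueError("pattern length must equal bank size")
    theta, se, used = eap_score_matrix(pattern, bank, grid)
    return ScoredPerson(
        theta_eap=float(theta[0]),
        se_eap=float(se[0]),
        t_score=float(to_tscore(float(theta[0]))),
        items_used=int(used[0]),
    )


# ---------------------------------------------------------------------------
# EM calibration with fixable parameters
# ---------------------------------------------------------------------------
@dataclass
class CalibrationResult:
    """Outcome of a marginal maximum likelihood EM calibration."""

    bank_out: ItemBank
    loglik_trace: list[float]
    n_cycles: int
    converged: bool
    max_param_change: float
    collapsed: dict[str, list[int]] = field(default_factory=dict)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _item_params_to_x(item: Item) -> np.ndarray:
    """(log a, b1, log increments) — enforces a > 0 and ordered thresholds."""
    b = np.array(item.thresholds)
    x = np.empty(1 + b.size)
    x[0] = np.log(item.slope)
    x[1] = b[0]
    if b.size > 1:
        x[2:] = np.log(np.diff(b))
    return x


def _x_to_params(x: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(x[0]))
    b = np.empty(x.size - 1)
    b[0] = x[1]
    if b.size > 1:
        b[1:] = b[0] + np.cumsum(np.exp(x[2:]))
    return a, b


def _expected_negloglik(
    x: np.ndarray, r: np.ndarray, nodes: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative expected complete-data log-likelihood and its gradient.

    ``r`` holds expected category counts, shape (m, Q).
    """
    a, b = _x_to_params(x)
    m = r.shape[0]
    with np.errstate(over="ignore"):  # exp overflow -> cum saturates, correct limit
        cum = 1.0 / (1.0 + np.exp(-a * (nodes[None, :] - b[:, None])))  # (m-1, Q)
    dcum = cum * (1.0 - cum)
    upper = np.vstack([np.ones_like(nodes)[None, :], cum])
    lower = np.vstack([cum, np.zeros_like(nodes)[None, :]])
    P = np.clip(upper - lower, _EPS, None)  # (m, Q)
    f = -float(np.sum(r * np.log(P)))

    ratio = r / P  # (m, Q)
    # d/db_j: P_{j-1} gains +a*dcum_j, P_j gains -a*dcum_j  (j = 1..m-1,
    # 0-indexed row j-1 in `cum`)
    g_b = np.empty(m - 1)
    for j in range(1, m):
        g_b[j - 1] = float(np.sum(a * dcum[j - 1] * (ratio[j - 1] - ratio[j])))
    # d/da: sum_k ratio_k * [ (theta-b_k) dcum_k - (theta-b_{k+1}) dcum_{k+1} ]
    tb = (nodes[None, :] - b[:, None]) * dcum  # (m-1, Q)
    upper_d = np.vstack([np.zeros_like(nodes)[None, :], tb])
    lower_d = np.vstack([tb, np.zeros_like(nodes)[None, :]])
    g_a = float(np.sum(ratio * (upper_d - lower_d)))

    grad = np.empty_like(x)
    grad[0] = a * g_a
    grad[1] = g_b.sum()
    if m > 2:
        d = np.exp(x[2:])
        # b_j depends on increments i <= j-1 (0-indexed increments start at b_2)
        grad[2:] = d * np.cumsum(g_b[::-1])[::-1][1:]
    return f, -grad  # negative gradient of expected loglik


def _collapse_empty_categories(
    X: np.ndarray, bank: ItemBank, free: np.ndarray
) -> tuple[np.ndarray, ItemBank, dict[str, list[int]]]:
    """Recode unobserved categories of free items away before estimation.

    Anchors are never collapsed: their parameters are external.  Returns the
    recoded matrix, adjusted bank and an old-code -> new-code map per
    affected item.
    """
    X = X.copy()
    items = list(bank)
    collapsed: dict[str, list[int]] = {}
    for j, item in enumerate(items):
        if not free[j]:
            continue
        col = X[:, j]
        obs = col[col != MISSING]
        counts = np.bincount(obs, minlength=item.n_cat)
        if (counts > 0).all():
            continue
        observed = np.nonzero(counts > 0)[0]
        if observed.size < 2:
            raise ValueError(
                f"free item {item.item_id!r} has fewer than 2 observed categories"
            )
        remap = np.searchsorted(observed, np.arange(item.n_cat))
        remap = np.clip(remap, 0, observed.size - 1)
        mask = col != MISSING
        X[mask, j] = remap[col[mask]]
        # keep thresholds bracketing the retained categories
        kept_b = [item.thresholds[k - 1] for k in observed[1:]]
        items[j] = Item(
            item.item_id, item.instrument, item.slope, tuple(kept_b), item.fixed
        )
        collapsed[item.item_id] = [int(v) for v in remap]
    return X, ItemBank(items), collapsed


def starting_values(col: np.ndarray, n_cat: int, slope: float = 1.5) -> tuple[float, np.ndarray]:
    """Crude start for a free item from its marginal category proportions."""
    obs = col[col != MISSING]
    counts = np.bincount(obs, minlength=n_cat).astype(float)
    props = (counts + 0.5) / (counts.sum() + 0.5 * n_cat)
    cum = np.cumsum(props)[:-1]
    b = stats.norm.ppf(np.clip(cum, 1e-4, 1 - 1e-4))
    b = np.maximum.accumulate(b + np.arange(b.size) * 1e-6)
    return slope, b


def em_calibrate(
    rm: ResponseMatrix | np.ndarray,
    bank: ItemBank,
    grid: QuadratureGrid | None = None,
    fix_mask: np.ndarray | None = None,
    tol: float = 1e-4,
    max_cycles: int = 500,
) -> CalibrationResult:
    """Marginal maximum likelihood EM with a fixed-parameter mask.

    The E-step forms each person's posterior mass over the quadrature nodes
    from the pattern likelihood times the N(0,1) prior weights and
    accumulates expected category counts per (item, category, node).  The
    M-step re-maximizes each *free* item's expected complete-data
    multinomial log-likelihood by quasi-Newton iterations on the
    ``(log a, b_1, log increments)`` reparameterization, which preserves
    threshold order without post-hoc sorting.  Items in ``fix_mask`` (by
    default the bank's own ``fixed`` flags) are never touched, which is the
    mechanism of fixed-anchor linking.

    Convergence: maximum absolute parameter change < ``tol`` (default 1e-4)
    or ``max_cycles``.  The marginal log-likelihood trace is recorded each
    cycle and is nondecreasing up to numerical tolerance.
    """
    X = rm.responses if isinstance(rm, ResponseMatrix) else np.asarray(rm)
    if X.shape[1] != len(bank):
        raise ValueError("response columns must match bank size")
    if grid is None:
        grid = make_grid()
    if fix_mask is None:
        fix_mask = bank.fixed_mask
    fix_mask = np.asarray(fix_mask, dtype=bool)
    free = ~fix_mask
    log_w = np.log(grid.weights)

    def marginal_loglik(b: ItemBank) -> float:
        logL = _log_pattern_likelihoods(X, b, grid) + log_w[None, :]
        mx = logL.max(axis=1, keepdims=True)
        return float(np.sum(mx[:, 0] + np.log(np.exp(logL - mx).sum(axis=1))))

    if not free.any():
        # nothing to estimate: report the likelihood of the supplied bank
        return CalibrationResult(
            bank_out=bank,
            loglik_trace=[marginal_loglik(bank)],
            n_cycles=0,
            converged=True,
            max_param_change=0.0,
        )

    X, bank, collapsed = _collapse_empty_categories(X, bank, free)
    items = list(bank)
    trace: list[float] = []
    max_change = np.inf
    cycle = 0
    for cycle in range(1, max_cycles + 1):
        cur = ItemBank(items)
        logL = _log_pattern_likelihoods(X, cur, grid) + log_w[None, :]
        mx = logL.max(axis=1, keepdims=True)
        L = np.exp(logL - mx)
        denom = L.sum(axis=1, keepdims=True)
        trace.append(float(np.sum(mx[:, 0] + np.log(denom[:, 0]))))
        post = L / denom  # (n, Q)

        max_change = 0.0
        for j in np.nonzero(free)[0]:
            item = items[j]
            col = X[:, j]
            r = np.zeros((item.n_cat, grid.n_nodes))
            for k in range(item.n_cat):
                sel = col == k
                if sel.any():
                    r[k] = post[sel].sum(axis=0)
            x0 = _item_params_to_x(item)
            res = optimize.minimize(
                _expected_negloglik,
                x0,
                args=(r, grid.nodes),
                jac=True,
                method="BFGS",
                options={"maxiter": 100, "gtol": 1e-7},
            )
            a_new, b_new = _x_to_params(res.x)
            a_new = float(np.clip(a_new, 1e-3, 50.0))
            change = max(
                abs(a_new - item.slope),
                float(np.max(np.abs(b_new - np.array(item.thresholds)))),
            )
            max_change = max(max_change, change)
            items[j] = Item(
                item.item_id, item.instrument, a_new, tuple(b_new), item.fixed
            )
        if max_change < tol:
            break

    out = ItemBank(items)
    trace.append(marginal_loglik(out))
    converged = max_change < tol
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_cycles} cycles "
            f"(last max parameter change {max_change:.2e})",
            RuntimeWarning,
        )
    return CalibrationResult(
        bank_out=out,
        loglik_trace=trace,
        n_cycles=cycle,
        converged=converged,
        max_param_change=float(max_change),
        collapsed=collapsed,
    )


def calibration_standard_errors(
    rm: ResponseMatrix | np.ndarray,
    bank: ItemBank,
    grid: QuadratureGrid | None = None,
) -> dict[str, np.ndarray]:
    """Observed-information standard errors for free item parameters.

    Uses per-item blocks of the numerically differentiated marginal
    log-likelihood Hessian at the supplied (converged) bank; cross-item
    information is ignored, a documented approximation.  Returns, per free
    item, SEs ordered as (slope, b_1, ..., b_{m-1}).
    """
    X = rm.responses if isinstance(rm, ResponseMatrix) else np.asarray(rm)
    if grid is None:
        grid = make_grid()
    log_w = np.log(grid.weights)

    def ll_for(j: int, params: np.ndarray) -> float:
        a = params[0]
        b = np.sort(params[1:])
        items = list(bank)
        items[j] = Item(
            items[j].item_id, items[j].instrument, a, tuple(b), items[j].fixed
        )
        logL = _log_pattern_likelihoods(X, ItemBank(items), grid) + log_w[None, :]
        mx = logL.max(axis=1, keepdims=True)
        return float(np.sum(mx[:, 0] + np.log(np.exp(logL - mx).sum(axis=1))))

    out: dict[str, np.ndarray] = {}
    for j, item in enumerate(bank):
        if item.fixed:
            continue
        p0 = np.concatenate([[item.slope], item.thresholds])
        h = 1e-4 * np.maximum(1.0, np.abs(p0))
        k = p0.size
        H = np.zeros((k, k))
        f0 = ll_for(j, p0)
        fp = np.empty(k)
        fm = np.empty(k)
        for i in range(k):
            e = np.zeros(k)
            e[i] = h[i]
            fp[i] = ll_for(j, p0 + e)
            fm[i] = ll_for(j, p0 - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(k):
            for l in range(i + 1, k):
                e_i = np.zeros(k)
                e_i[i] = h[i]
                e_l = np.zeros(k)
                e_l[l] = h[l]
                f_pp = ll_for(j, p0 + e_i + e_l)
                H[i, l] = H[l, i] = (f_pp - fp[i] - fp[l] + f0) / (h[i] * h[l])
        info = -H
        try:
            cov = np.linalg.inv(info)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(k, np.nan)
        out[item.item_id] = se
    return out


# ---------------------------------------------------------------------------
# Lord-Wingersky recursion
# ---------------------------------------------------------------------------
def lw_sumscore_dist(bank: ItemBank, theta: float | np.ndarray) -> np.ndarray:
    """Summed-score distribution P(S = s | theta) by the Lord-Wingersky
    recursion.

    Returns shape ``(S_max + 1,)`` for scalar theta, else
    ``(S_max + 1, len(theta))``; columns sum to 1.
    """
    if len(bank) == 0:
        raise ValueError("bank must be nonempty")
    scalar = np.isscalar(theta)
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    f = _cat_probs(bank[0].slope, np.array(bank[0].thresholds), th)
    for item in list(bank)[1:]:
        p = _cat_probs(item.slope, np.array(item.thresholds), th)
        s_old, m = f.shape[0], p.shape[0]
        new = np.zeros((s_old + m - 1, th.size))
        for k in range(m):
            new[k : k + s_old] += f * p[k][None, :]
        f = new
    return f[:, 0] if scalar else f


# ---------------------------------------------------------------------------
# S-X2 item fit
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ItemFitResult:
    item_id: str
    s_x2: float
    df: int
    p: float | None
    collapsed_cells: int


def _collapse_row(obs: np.ndarray, exp: np.ndarray, min_expected: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Merge adjacent cells with small expected counts toward the nearer tail."""
    obs = list(obs.astype(float))
    exp = list(exp.astype(float))
    merged = 0
    while len(exp) > 1 and min(exp) < min_expected:
        i = int(np.argmin(exp))
        if i == 0:
            tgt = 1
        elif i == len(exp) - 1:
            tgt = i - 1
        else:
            tgt = i - 1 if i < len(exp) / 2 else i + 1
        lo, hi = min(i, tgt), max(i, tgt)
        obs[lo] += obs[hi]
        exp[lo] += exp[hi]
        del obs[hi], exp[hi]
        merged += 1
    return np.array(obs), np.array(exp), merged


def s_x2_itemfit(
    rm: ResponseMatrix | np.ndarray,
    bank: ItemBank,
    grid: QuadratureGrid | None = None,
    min_expected: float = 1.0,
) -> list[ItemFitResult]:
    """S-X2 item fit: observed vs expected category frequencies by rest score.

    For each item the expected conditional category distribution given the
    rest score ``s`` is

        E(k | s) = sum_q P_j(k | theta_q) f_{-j}(s | theta_q) w_q
                   / sum_q f_{-j}(s | theta_q) w_q

    with ``f_{-j}`` the Lord-Wingersky summed-score distribution of the
    remaining items — i.e. the model expectation integrated over the
    posterior of theta given the rest score.  Complete cases only.  Adjacent
    cells with expected count below ``min_expected`` are merged toward the
    nearer tail.  Degrees of freedom: sum over rest-score rows of
    (cells - 1), minus the number of *estimated* parameters of the item
    (zero for fixed items); if df <= 0 the item is reported without a
    p-value.
    """
    X = rm.responses if isinstance(rm, ResponseMatrix) else np.asarray(rm)
    if grid is None:
        grid = make_grid()
    complete = (X != MISSING).all(axis=1)
    X = X[complete]
    if X.shape[0] == 0:
        raise ValueError("no complete cases for S-X2")
    results = []
    all_items = list(bank)
    for j, item in enumerate(all_items):
        rest_bank = ItemBank(all_items[:j] + all_items[j + 1 :])
        rest_scores = X.sum(axis=1) - X[:, j]
        S_rest = rest_bank.max_sum_score
        f_rest = lw_sumscore_dist(rest_bank, grid.nodes)  # (S_rest+1, Q)
        P_j = _cat_probs(item.slope, np.array(item.thresholds), grid.nodes)
        wf = f_rest * grid.weights[None, :]
        denom = wf.sum(axis=1)  # (S_rest+1,)
        num = wf @ P_j.T  # (S_rest+1, m)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_cond = num / denom[:, None]

        chi2 = 0.0
        df = 0
        merged_total = 0
        for s in range(S_rest + 1):
            sel = rest_scores == s
            n_s = int(sel.sum())
            if n_s == 0 or denom[s] <= 0:
                continue
            obs = np.bincount(X[sel, j], minlength=item.n_cat).astype(float)
            exp = n_s * e_cond[s]
            obs_c, exp_c, merged = _collapse_row(obs, exp, min_expected)
            merged_total += merged
            if exp_c.size < 2:
                continue
            chi2 += float(np.sum((obs_c - exp_c) ** 2 / exp_c))
            df += exp_c.size - 1
        n_params = 0 if item.fixed else item.n_cat  # slope + (m-1) thresholds
        df -= n_params
        p = float(stats.chi2.sf(chi2, df)) if df >= 1 else None
        results.append(
            ItemFitResult(
                item_id=item.item_id,
                s_x2=float(chi2),
                df=int(df),
                p=p,
                collapsed_cells=merged_total,
            )
        )
    return results
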