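"""Synthetic ordinal response data with the structure the pipeline assumes.

The generators emulate a linking study in which a short patient-reported
anchor form (4 items here) and a longer performance battery (9 items) are
administered to the same sample: five-category graded responses driven by a
latent physical-function trait, an optional general+specific (bifactor)
structure with assessment-type/subdomain specific factors, group-specific
threshold shifts (uniform DIF), completely-at-random item missingness, and
nuisance covariates constructed to correlate with the anchor-minus-battery
score difference.  Every generator is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bank import Item, ItemBank
from .data import MISSING, ResponseMatrix
from .grm import _cat_probs

__all__ = [
    "SimScenario",
    "make_item_bank",
    "simulate_unidimensional",
    "simulate_bifactor",
    "inject_dif",
    "attach_difference_covariates",
    "apply_missingness",
    "attach_group_covariates",
]


@dataclass
class SimScenario:
    """Configuration of a bifactor data-generating scenario.

    Per-item loadings must satisfy the communality constraint
    ``general^2 + specific^2 < 1``; the remainder is unique normal noise.
    ``specific_groups`` maps a specific-factor label to the item ids it
    contaminates; each item may appear in at most one group.
    """

    n_persons: int
    general_loadings: dict[str, float]
    specific_loadings: dict[str, float] = field(default_factory=dict)
    specific_groups: dict[str, list[str]] = field(default_factory=dict)
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for grp, ids in self.specific_groups.items():
            for iid in ids:
                if iid in seen:
                    raise ValueError(f"item {iid!r} in more than one specific group")
                seen.add(iid)
        for iid, g in self.general_loadings.items():
            s = self.specific_loadings.get(iid, 0.0)
            if not (0 <= g < 1 and 0 <= s < 1):
                raise ValueError("loadings must lie in [0, 1)")
            if g * g + s * s >= 1:
                raise ValueError(
                    f"item {iid!r}: communality {g * g + s * s:.3f} >= 1"
                )


def make_item_bank(
    n_anchor: int,
    n_new: int,
    n_cat: int = 5,
    slope_range: tuple[float, float] = (0.8, 2.5),
    threshold_span: tuple[float, float] = (-2.5, 2.5),
    seed: int = 0,
) -> ItemBank:
    """Random graded-response bank: ``n_anchor`` fixed anchors + ``n_new``
    free items, slopes uniform in ``slope_range`` and sorted threshold draws
    within ``threshold_span``."""
    if n_anchor < 0 or n_new < 0 or n_anchor + n_new == 0:
        raise ValueError("need a positive total item count")
    if n_cat < 2:
        raise ValueError("n_cat must be >= 2")
    if slope_range[0] <= 0 or slope_range[0] > slope_range[1]:
        raise ValueError("slope_range must be positive and ordered")
    if threshold_span[0] >= threshold_span[1]:
        raise ValueError("threshold_span must be an increasing interval")
    rng = np.random.default_rng(seed)
    items = []
    for i in range(n_anchor + n_new):
        anchor = i < n_anchor
        b = np.sort(rng.uniform(*threshold_span, size=n_cat - 1))
        # enforce strict increase with a minimal gap
        b = np.maximum.accumulate(b + np.arange(n_cat - 1) * 1e-9)
        items.append(
            Item(
                item_id=f"ANC_{i + 1}" if anchor else f"NEW_{i - n_anchor + 1}",
                instrument="anchor" if anchor else "new",
                slope=float(rng.uniform(*slope_range)),
                thresholds=tuple(b),
                fixed=anchor,
            )
        )
    return ItemBank(items)


def _draw_responses(bank: ItemBank, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw GRM responses for all persons, one item at a time."""
    n = theta.size
    X = np.empty((n, len(bank)), dtype=np.int64)
    for j, item in enumerate(bank):
        probs = _cat_probs(item.slope, np.array(item.thresholds), theta)  # (m, n)
        cum = np.cumsum(probs, axis=0)
        u = rng.random(n)
        X[:, j] = (u[None, :] > cum).sum(axis=0)
    return X


def simulate_unidimensional(
    bank: ItemBank,
    n: int,
    theta_mean: float = 0.0,
    theta_sd: float = 1.0,
    seed: int = 0,
) -> ResponseMatrix:
    """Simulate responses under the logistic GRM with theta ~ N(mean, sd^2)."""
    if len(bank) == 0:
        raise ValueError("bank must be nonempty")
    if theta_sd <= 0:
        raise ValueError("theta_sd must be positive")
    rng = np.random.default_rng(seed)
    theta = rng.normal(theta_mean, theta_sd, size=n)
    X = _draw_responses(bank, theta, rng)
    return ResponseMatrix(X, bank.item_ids, true_theta=theta)


def simulate_bifactor(bank: ItemBank, scenario: SimScenario) -> ResponseMatrix:
    """Simulate under a normal-ogive bifactor structure.

    Person latent propensity for item j is
    ``lambda_g_j G + lambda_s_j S_{g(j)} + sqrt(1 - communality) e_j`` with
    G, all S and e independent standard normal; the propensity is cut at the
    item's thresholds to yield ordinal codes.  With all specific loadings
    zero this reduces to a unidimensional normal-ogive model with loading
    ``lambda_g_j``.
    """
    missing = [iid for iid in bank.item_ids if iid not in scenario.general_loadings]
    if missing:
        raise ValueError(f"no general loading for items {missing}")
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_persons
    G = rng.normal(scenario.theta_mean, scenario.theta_sd, size=n)
    S = {grp: rng.normal(size=n) for grp in scenario.specific_groups}
    group_of = {
        iid: grp for grp, ids in scenario.specific_groups.items() for iid in ids
    }
    X = np.empty((n, len(bank)), dtype=np.int64)
    for j, item in enumerate(bank):
        lg = scenario.general_loadings[item.item_id]
        ls = scenario.specific_loadings.get(item.item_id, 0.0)
        grp = group_of.get(item.item_id)
        if ls > 0 and grp is None:
            raise ValueError(
                f"item {item.item_id!r} has a specific loading but no group"
            )
        uniq = np.sqrt(1.0 - lg * lg - ls * ls)
        prop = lg * G + (ls * S[grp] if grp is not None else 0.0) + uniq * rng.normal(size=n)
        X[:, j] = np.searchsorted(np.array(item.thresholds), prop, side="right")
    return ResponseMatrix(X, bank.item_ids, true_theta=G)


def inject_dif(bank: ItemBank, item_id: str, shift: float) -> ItemBank:
    """Focal-group bank variant with one item's thresholds shifted by +shift.

    Shifting thresholds up makes the item harder for the focal group at
    equal theta (uniform DIF); the reference bank is left untouched.
    """
    item = bank[item_id]  # KeyError if unknown
    return bank.replace_item(item.with_shifted_thresholds(shift))


def attach_group_covariates(
    rm: ResponseMatrix,
    groups: dict[str, list],
    seed: int = 0,
    probs: dict[str, list[float]] | None = None,
) -> ResponseMatrix:
    """Attach categorical person covariates drawn independently of the trait."""
    rng = np.random.default_rng(seed)
    cov = rm.covariates.copy() if len(rm.covariates) else pd.DataFrame(index=range(rm.n_persons))
    for name, levels in groups.items():
        p = probs.get(name) if probs else None
        cov[name] = rng.choice(levels, size=rm.n_persons, p=p)
    return ResponseMatrix(rm.responses, rm.item_ids, cov.reset_index(drop=True), rm.true_theta)


def attach_difference_covariates(
    rm: ResponseMatrix,
    anchor_ids: list[str],
    new_ids: list[str],
    target_r: dict[str, float],
    seed: int = 0,
) -> ResponseMatrix:
    """Nuisance covariates correlated with the anchor-minus-battery score gap.

    The per-person difference signal is the standardized anchor mean score
    minus the standardized battery mean score (measurement error makes this
    non-degenerate even for unidimensional data).  Each covariate is built
    as ``r * z_diff + sqrt(1 - r^2) * noise`` so its population correlation
    with the difference equals ``target_r``.
    """
    for name, r in target_r.items():
        if not abs(r) < 1:
            raise ValueError(f"target_r[{name!r}] must satisfy |r| < 1")
    rng = np.random.default_rng(seed)

    def z(ids: list[str]) -> np.ndarray:
        cols = rm.columns(ids).astype(float)
        cols[rm.columns(ids) == MISSING] = np.nan
        m = np.nanmean(cols, axis=1)
        m = np.where(np.isnan(m), np.nanmean(m), m)
        return (m - m.mean()) / m.std()

    diff = z(anchor_ids) - z(new_ids)
    sd = diff.std()
    if sd < 1e-12:
        raise ValueError("degenerate difference variance")
    zd = (diff - diff.mean()) / sd
    cov = rm.covariates.copy() if len(rm.covariates) else pd.DataFrame(index=range(rm.n_persons))
    for name, r in target_r.items():
        cov[name] = r * zd + np.sqrt(1 - r * r) * rng.normal(size=rm.n_persons)
    return ResponseMatrix(rm.responses, rm.item_ids, cov.reset_index(drop=True), rm.true_theta)


def apply_missingness(
    rm: ResponseMatrix,
    rate: float,
    item_ids: list[str] | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Set responses missing completely at random at ``rate`` within the
    masked items (all items if None)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return rm
    rng = np.random.default_rng(seed)
    X = rm.responses.copy()
    cols = (
        [rm.item_ids.index(i) for i in item_ids]
        if item_ids is not None
        else list(range(rm.n_items))
    )
    mask = rng.random((rm.n_persons, len(cols))) < rate
    for c, col in enumerate(cols):
        X[mask[:, c], col] = MISSING
    return ResponseMatrix(X, rm.item_ids, rm.covariates, rm.true_theta)
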