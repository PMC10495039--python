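"""Group-level agreement between two score sets on a common metric.

After linking, anchor-based and battery-based T-scores for the same persons
should agree *on average* even though individual scores differ.  This
module quantifies that: paired standardized mean differences (SMD = mean
difference / SD of differences) with normal-approximation CIs, Bland-Altman
summaries with a difference-vs-average trend test, subgroup stratification
with the conventional negligible/small/medium/large labels at 0.2/0.5/0.8,
ceiling/floor rates, and correlations of the score difference with nuisance
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "paired_smd",
    "bland_altman",
    "subgroup_agreement",
    "ceiling_floor",
    "diff_covariate_corr",
    "AgreementReport",
    "smd_label",
]

_SMD_CUTS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def smd_label(smd: float) -> str:
    """Effect-size label: negligible < 0.2 <= small < 0.5 <= medium < 0.8 <= large."""
    for cut, label in _SMD_CUTS:
        if abs(smd) < cut:
            return label
    return "large"


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and equally long")
    return a, b


def paired_smd(a, b) -> tuple[float, tuple[float, float]]:
    """Paired standardized mean difference and 95% CI.

    smd = mean(a - b) / sd(a - b); CI by the normal approximation
    smd +/- 1.96 sqrt(1/n + smd^2 / (2n)).  Identical inputs give exactly
    0.  A zero difference-SD with nonzero mean difference is an error.
    """
    a, b = _check_pair(a, b)
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        if abs(d.mean()) > 0:
            raise ValueError("degenerate difference SD with nonzero mean")
        return 0.0, (0.0, 0.0)
    smd = float(d.mean() / sd)
    half = 1.96 * np.sqrt(1.0 / n + smd * smd / (2.0 * n))
    return smd, (smd - half, smd + half)


def bland_altman(a, b) -> dict[str, float]:
    """Bland-Altman summary of paired differences.

    Returns mean difference, SD of differences, 95% limits of agreement
    (mean +/- 1.96 SD) and the least-squares trend of (a - b) on
    (a + b)/2 with its p-value (proportional bias check).
    """
    a, b = _check_pair(a, b)
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    avg = (a + b) / 2.0
    sd = float(d.std(ddof=1))
    mean_diff = float(d.mean())
    if avg.std() == 0 or sd == 0:
        slope, trend_p = 0.0, 1.0
    else:
        fit = stats.linregress(avg, d)
        slope, trend_p = float(fit.slope), float(fit.pvalue)
    return {
        "mean_diff": mean_diff,
        "sd_diff": sd,
        "loa_low": mean_diff - 1.96 * sd,
        "loa_high": mean_diff + 1.96 * sd,
        "trend_slope": slope,
        "trend_p": trend_p,
    }


def ceiling_floor(
    scores, max_score: float, min_score: float, tol: float = 1e-9
) -> tuple[float, float]:
    """Fractions of persons at the instrument's maximum / minimum attainable score."""
    s = np.asarray(scores, dtype=float)
    return (
        float(np.mean(np.abs(s - max_score) <= tol)),
        float(np.mean(np.abs(s - min_score) <= tol)),
    )


def diff_covariate_corr(a, b, covariates: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation of the paired difference with each covariate."""
    a, b = _check_pair(a, b)
    d = a - b
    out = {}
    for name in covariates.columns:
        x = pd.to_numeric(covariates[name], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(d)
        if x[ok].std() == 0:
            raise ValueError(f"constant covariate {name!r}")
        out[name] = float(np.corrcoef(d[ok], x[ok])[0, 1])
    return out


@dataclass
class AgreementReport:
    """Per-subgroup SMDs plus Bland-Altman, ceiling/floor and difference
    correlations."""

    subgroups: pd.DataFrame  # stratum, n, mean_a, mean_b, smd, ci_low, ci_high, label
    bland_altman: dict[str, float]
    ceiling_a: float = np.nan
    ceiling_b: float = np.nan
    floor_a: float = np.nan
    floor_b: float = np.nan
    diff_covariate_r: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.subgroups


def subgroup_agreement(
    a, b, strata: pd.Series | np.ndarray | None = None
) -> AgreementReport:
    """Paired SMD with CI for the full sample and every stratum.

    Strata with fewer than 3 persons are reported with their n but without
    SMD/CI.  Labels follow the 0.2/0.5/0.8 effect-size cuts.
    """
    a, b = _check_pair(a, b)
    rows = []

    def add_row(name: str, sel: np.ndarray) -> None:
        n = int(sel.sum())
        row = {
            "stratum": name,
            "n": n,
            "mean_a": float(a[sel].mean()) if n else np.nan,
            "mean_b": float(b[sel].mean()) if n else np.nan,
            "smd": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "label": "",
        }
        if n >= 3:
            smd, (lo, hi) = paired_smd(a[sel], b[sel])
            row.update(smd=smd, ci_low=lo, ci_high=hi, label=smd_label(smd))
        rows.append(row)

    add_row("full sample", np.ones(a.size, dtype=bool))
    if strata is not None:
        strata = pd.Series(np.asarray(strata))
        for level in strata.dropna().unique():
            add_row(str(level), (strata == level).to_numpy())
    return AgreementReport(
        subgroups=pd.DataFrame(rows), bland_altman=bland_altman(a, b)
    )
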