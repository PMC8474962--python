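"""Cohort-level statistics: exact Mann-Whitney comparisons, normality
screening, linear regression goodness of fit, Spearman correlation, and the
treated-vs-control endpoint report.

Group comparisons at preclinical sample sizes (here n = 5 vs 4) use the
exact Mann-Whitney test: the two-sided p-value is the probability, under
full enumeration of all C(n1+n2, n1) group assignments of the mid-ranks, of
a U statistic at least as far from its null mean n1*n2/2 as observed. The
normal approximation (with tie correction) is used only above 20 total
observations. Normality is screened with Shapiro-Wilk but group tests stay
nonparametric regardless.

r-squared is reported as linear-regression goodness of fit; Spearman rho is
reported separately (exact permutation p for n <= 9) — the two are never
conflated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "mann_whitney_exact",
    "shapiro_wilk",
    "linear_r2",
    "spearman_r",
    "treatment_report",
]

EXACT_MW_LIMIT = 20  # full enumeration up to this many total observations
EXACT_SPEARMAN_LIMIT = 9  # full permutation up to this n


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_sided: float
    method: str  # "exact" | "normal-approx" | "shapiro-wilk"
    n1: int
    n2: int = 0


def mann_whitney_exact(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    The U statistic is for group ``x`` (number of (x, y) pairs with x > y,
    ties counting one half). Exact p enumerates every split of the combined
    mid-ranks; e.g. full separation at n = 5 vs 4 gives U = 0 and
    p = 2/126.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be nonempty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if n1 + n2 <= EXACT_MW_LIMIT:
        dev_obs = abs(u_obs - mu)
        base = n1 * (n1 + 1) / 2.0
        hits = 0
        for combo in combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        p = hits / comb(n1 + n2, n1)
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal-approx"
    return TestResult(statistic=u_obs, p_two_sided=min(p, 1.0), method=method, n1=n1, n2=n2)


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality screen (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires n >= 3")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk approximation valid only up to n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("sample has zero variance")
    w, p = stats.shapiro(x)
    return TestResult(statistic=float(w), p_two_sided=float(p), method="shapiro-wilk", n1=x.size)


def linear_r2(x, y) -> tuple[float, float, float]:
    """OLS fit of y on x: (slope, intercept, r^2).

    r^2 = 1 - SSres/SStot; a constant y is reported as r^2 = 0 by convention
    (no variance explained). Constant x is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("var(x) = 0: regression undefined")
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return slope, intercept, 0.0
    ss_res = float(((y - slope * x - intercept) ** 2).sum())
    return slope, intercept, 1.0 - ss_res / ss_tot


def _pearson_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    return float((rx @ ry) / denom)


def spearman_r(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties.

    Two-sided p by full permutation of one margin for n <= 9, by the
    t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _pearson_of_ranks(rx, ry)
    n = x.size
    if n <= EXACT_SPEARMAN_LIMIT:
        hits = 0
        for perm in permutations(range(n)):
            if abs(_pearson_of_ranks(rx, ry[list(perm)])) >= abs(rho) - 1e-12:
                hits += 1
        p = hits / factorial(n)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


#: endpoint markers compared between arms, with the response direction
#: expected under effective chemotherapy (cell kill raises water diffusivity,
#: shrinks the tumor, and lowers cellular density)
TREATMENT_MARKERS = {
    "adc_mean_mm2_s": "up",
    "vmri_mm3": "down",
    "cell_density_per_mm2": "down",
}


def treatment_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Treated-vs-control endpoint comparison table.

    For each endpoint marker (ADCmean, vMRI, cell density) reports per-arm
    mean and range, the exact Mann-Whitney p, and whether the group
    difference lies in the expected treatment-response direction. Markers
    with identical arms get p = 1 and no directional flag.
    """
    for col in ("arm", *TREATMENT_MARKERS):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column '{col}'")
    rows = []
    for marker, direction in TREATMENT_MARKERS.items():
        sub = cohort.dropna(subset=[marker])
        treated = sub.loc[sub["arm"] == "treated", marker].to_numpy(float)
        control = sub.loc[sub["arm"] == "control", marker].to_numpy(float)
        if treated.size == 0 or control.size == 0:
            raise ValueError(f"marker '{marker}' missing a treated or control arm")
        res = mann_whitney_exact(treated, control)
        diff = treated.mean() - control.mean()
        in_direction = diff > 0 if direction == "up" else diff < 0
        rows.append(
            {
                "marker": marker,
                "treated_mean": treated.mean(),
                "treated_min": treated.min(),
                "treated_max": treated.max(),
                "control_mean": control.mean(),
                "control_min": control.min(),
                "control_max": control.max(),
                "u_statistic": res.statistic,
                "p_two_sided": res.p_two_sided,
                "method": res.method,
                "expected_direction": direction,
                "direction_ok": bool(in_direction) and diff != 0,
                "significant": res.p_two_sided < 0.05,
            }
        )
    return pd.DataFrame(rows)
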