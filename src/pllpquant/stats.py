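"""Cohort statistics: ΔΔCt fold changes, Mann–Whitney tests, effect sizes.

The primary two-sample test is the two-tailed Mann–Whitney U (Wilcoxon
rank-sum), exact by enumeration for small untied samples and otherwise a
tie-corrected normal approximation with continuity correction.  A Welch
t-test is available for sensitivity checks.  qPCR relative quantification
follows the ΔΔCt convention: technical replicates are averaged per sample,
ΔCt = Ct(target) − Ct(reference), ΔΔCt is taken against the control-group
mean, and fold change = 2^(−ΔΔCt).
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .exceptions import UndefinedStatisticError
from .types import GroupSummary, TestResult

#: exact Mann–Whitney is used when the number of distinct labelings
#: C(n_x + n_y, n_x) does not exceed this and there are no ties
EXACT_ENUMERATION_LIMIT = 10 ** 6


def delta_delta_ct(plate: pd.DataFrame, target_gene: str, ref_gene: str,
                   control_group: str) -> dict[str, float]:
    """Fold change per non-control group by the ΔΔCt method.

    ``plate`` needs columns gene, sample, group, replicate, ct.  Technical
    replicates are averaged per (gene, sample) before anything else.
    Raises if any sample lacks the reference gene.
    """
    required = {"gene", "sample", "group", "replicate", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate missing columns {sorted(missing)}")
    if control_group not in set(plate["group"]):
        raise ValueError(f"control group {control_group!r} not on the plate")

    per_sample = (plate.groupby(["group", "sample", "gene"], sort=False)["ct"]
                  .mean().unstack("gene"))
    for gene in (target_gene, ref_gene):
        if gene not in per_sample.columns:
            raise ValueError(f"gene {gene!r} not on the plate")
        absent = per_sample[per_sample[gene].isna()].index
        if len(absent):
            sample = absent[0][1]
            raise ValueError(f"sample {sample!r} lacks Ct values for {gene!r}")

    delta_ct = per_sample[target_gene] - per_sample[ref_gene]
    group_means = delta_ct.groupby(level="group").mean()
    control_mean = group_means[control_group]
    return {
        str(group): float(2.0 ** -(mean - control_mean))
        for group, mean in group_means.items() if group != control_group
    }


@lru_cache(maxsize=256)
def _u_counts(n: int, m: int) -> np.ndarray:
    """Number of (n out of n+m) labelings giving each rank-sum-derived U,
    via the standard recurrence c(u; n, m) = c(u−m; n−1, m) + c(u; n, m−1)."""
    if n == 0 or m == 0:
        return np.ones(1)
    a = _u_counts(n - 1, m)   # last element of x-group ranked above all of y: U gains m
    b = _u_counts(n, m - 1)
    out = np.zeros(n * m + 1)
    out[m:m + len(a)] += a
    out[:len(b)] += b
    return out


def mann_whitney_u(x, y, method: str = "auto") -> TestResult:
    """Two-tailed Mann–Whitney U test.

    U is computed from midranks (ties allowed).  ``method='auto'`` picks the
    exact null distribution when the samples are untied and
    C(n_x+n_y, n_x) ≤ 10⁶, else a tie-corrected normal approximation with
    continuity correction.  With all values identical, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples need at least one value")
    n_x, n_y = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:n_x].sum()
    u_x = r_x - n_x * (n_x + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    if method == "auto":
        method = ("exact" if not has_ties
                  and math.comb(n_x + n_y, n_x) <= EXACT_ENUMERATION_LIMIT
                  else "normal_approx_tie_corrected")
    if method == "exact" and has_ties:
        raise ValueError("exact method is not defined with ties")

    if method == "exact":
        counts = _u_counts(n_x, n_y)
        total = counts.sum()
        u_lo = min(u_x, n_x * n_y - u_x)
        p = min(1.0, 2.0 * counts[:int(u_lo) + 1].sum() / total)
    elif method == "normal_approx_tie_corrected":
        n = n_x + n_y
        mu = n_x * n_y / 2.0
        tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) \
            if n > 1 else 0.0
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0  # all values identical
        else:
            z = (abs(u_x - mu) - 0.5) / math.sqrt(var)  # continuity correction
            z = max(z, 0.0)
            p = min(1.0, 2.0 * sps.norm.sf(z))
    else:
        raise ValueError(f"unknown method {method!r}")

    return TestResult(statistic_U=float(u_x), p_two_tailed=float(p),
                      n_x=n_x, n_y=n_y, method=method)


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t-test (statistic, two-tailed p); sensitivity check."""
    res = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float),
                        equal_var=False)
    return float(res.statistic), float(res.pvalue)


def significance_label(p: float) -> str:
    """Star annotation: ns for p > 0.05, then *, **, ***, **** at
    p ≤ 0.05, 0.01, 0.001, 0.0001 (most extreme bracket wins)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p = {p} outside [0, 1]")
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def percent_change(reference_mean: float, test_mean: float) -> float:
    """Signed percent change of ``test_mean`` relative to ``reference_mean``."""
    if reference_mean == 0:
        raise UndefinedStatisticError("percent change undefined for zero reference")
    return 100.0 * (test_mean - reference_mean) / reference_mean


def summarize_groups(table: pd.DataFrame, value_col: str,
                     group_col: str = "group",
                     dispersion_mode: str = "SD") -> list[GroupSummary]:
    """Per-group n, mean, SD (n−1 denominator) and SEM.

    ``dispersion_mode`` records whether plots should show mean ± SD or
    mean ± SEM.  Groups of n = 1 get NaN dispersion.
    """
    if dispersion_mode not in ("SD", "SEM"):
        raise ValueError("dispersion_mode must be 'SD' or 'SEM'")
    out = []
    for group, sub in table.groupby(group_col, sort=False):
        vals = sub[value_col].to_numpy(dtype=float)
        n = vals.size
        if n == 0:
            raise ValueError(f"group {group!r} has no values")
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
        sem = sd / math.sqrt(n) if n > 1 else float("nan")
        out.append(GroupSummary(group=str(group), n=n, mean=mean, sd=sd,
                                sem=sem, dispersion_mode=dispersion_mode))
    return out


def proportion_with_ci(k: int, n: int, level: float = 0.95
                       ) -> tuple[float, tuple[float, float]]:
    """Proportion k/n with its Wilson score interval."""
    if not 0 <= k <= n or n < 1:
        raise ValueError("need 0 <= k <= n, n >= 1")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="wilson")
    return k / n, (float(lo), float(hi))


def compare_cohorts(cohort: pd.DataFrame, value_col: str,
                    group_col: str = "genotype",
                    reference_group: str | None = None) -> pd.DataFrame:
    """Tidy comparison table: each group against the reference (default: the
    first group in the table) — effect %, U, two-tailed p, star label."""
    groups = list(dict.fromkeys(cohort[group_col]))
    if reference_group is None:
        reference_group = groups[0]
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in table")
    ref_vals = cohort.loc[cohort[group_col] == reference_group, value_col]
    rows = []
    for group in groups:
        if group == reference_group:
            continue
        vals = cohort.loc[cohort[group_col] == group, value_col]
        res = mann_whitney_u(ref_vals, vals)
        rows.append({
            "reference": reference_group,
            "group": group,
            "n_ref": res.n_x,
            "n": res.n_y,
            "mean_ref": float(ref_vals.mean()),
            "mean": float(vals.mean()),
            "effect_percent": percent_change(float(ref_vals.mean()),
                                             float(vals.mean())),
            "U": res.statistic_U,
            "p_two_tailed": res.p_two_tailed,
            "method": res.method,
            "label": significance_label(res.p_two_tailed),
        })
    return pd.DataFrame(rows)
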