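"""Cohort-level statistics: exclusions, 2x2 risk measures, group tests.

The risk layer reproduces a demographics-vs-outcome table: for each
binary attribute, a 2x2 table of exposure by delivery outcome yields a
relative risk (RR), odds ratio (OR), 95% confidence intervals (Katz log
method for RR, Woolf log method for OR) and a two-sided Fisher exact
p-value.  Group comparisons use Welch's t-test, one-way ANOVA with
Tukey's HSD (Tukey-Kramer for unequal n), and OLS slope tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable", "ContingencyResult", "apply_exclusions",
           "contingency_stats", "welch_t", "anova_tukey",
           "slope_regression"]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-outcome counts.

    a = exposed cases, b = exposed non-cases, c = unexposed cases,
    d = unexposed non-cases ("case" = preterm delivery throughout the
    cohort analyses).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"count {name} must be a non-negative "
                                 f"integer, got {v!r}")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one count")


@dataclass
class ContingencyResult:
    rr: float
    or_: float
    rr_ci: tuple[float, float]
    or_ci: tuple[float, float]
    fisher_p: float
    haldane_corrected: bool = False


def apply_exclusions(samples: pd.DataFrame,
                     blood_col: str = "blood_flag",
                     intercourse_col: str = "intercourse_flag",
                     ) -> tuple[pd.DataFrame, dict]:
    """Drop samples with blood or recent unprotected intercourse.

    Returns the retained rows and a log with per-reason counts (a row
    carrying both flags counts once in retention but under both
    reasons).
    """
    for col in (blood_col, intercourse_col):
        if col not in samples.columns:
            raise ValueError(f"missing exclusion flag column {col!r}")
    blood = samples[blood_col].astype(bool)
    sex = samples[intercourse_col].astype(bool)
    excluded = blood | sex
    log = {
        "n_input": int(len(samples)),
        "blood": int(blood.sum()),
        "intercourse": int(sex.sum()),
        "excluded": int(excluded.sum()),
        "retained": int((~excluded).sum()),
    }
    return samples.loc[~excluded].copy(), log


def _ratio(num: float, den: float) -> float:
    if num == 0:
        return 0.0
    if den == 0:
        return math.inf
    return num / den


def contingency_stats(t: ContingencyTable) -> ContingencyResult:
    """RR, OR, 95% CIs and two-sided Fisher exact p for a 2x2 table.

    Point estimates use the raw counts (zero numerators give 0, zero
    denominators an infinite marker).  When any cell is zero the CIs —
    and only the CIs — use the Haldane-Anscombe 0.5 correction, flagged
    in the result.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    risk_exp = _ratio(a, a + b)
    risk_unexp = _ratio(c, c + d)
    rr = _ratio(risk_exp, risk_unexp) if risk_exp != 0 else 0.0
    or_ = _ratio(a * d, b * c)

    haldane = 0 in (a, b, c, d)
    if haldane:
        af, bf, cf, df = (x + 0.5 for x in (a, b, c, d))
    else:
        af, bf, cf, df = float(a), float(b), float(c), float(d)
    rr_pt = (af / (af + bf)) / (cf / (cf + df))
    se_log_rr = math.sqrt(1 / af - 1 / (af + bf) + 1 / cf - 1 / (cf + df))
    rr_ci = (rr_pt * math.exp(-Z95 * se_log_rr),
             rr_pt * math.exp(Z95 * se_log_rr))
    or_pt = (af * df) / (bf * cf)
    se_log_or = math.sqrt(1 / af + 1 / bf + 1 / cf + 1 / df)
    or_ci = (or_pt * math.exp(-Z95 * se_log_or),
             or_pt * math.exp(Z95 * se_log_or))

    fisher_p = float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    return ContingencyResult(rr=rr, or_=or_, rr_ci=rr_ci, or_ci=or_ci,
                             fisher_p=fisher_p, haldane_corrected=haldane)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Two zero-variance groups with equal means return (0, df, 1) by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if np.var(x) == 0 and np.var(y) == 0:
        df = float(len(x) + len(y) - 2)
        if np.mean(x) == np.mean(y):
            return 0.0, df, 1.0
        return math.inf if np.mean(x) > np.mean(y) else -math.inf, df, 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def anova_tukey(groups: dict) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey's HSD pairwise comparisons.

    ``groups`` maps group name to a sequence of values.  Returns
    (F, p, pairwise DataFrame with columns group1, group2, diff,
    p_adj).  Tukey uses the studentized range distribution with
    Tukey-Kramer standard errors for unequal group sizes.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    for k, arr in zip(names, arrays):
        if len(arr) < 2:
            raise ValueError(f"group {k!r} needs >= 2 values")
    if all(np.var(a) == 0 for a in arrays) and \
            len({float(a[0]) for a in arrays}) == 1:
        F, p = 0.0, 1.0
    else:
        F, p = (float(v) for v in stats.f_oneway(*arrays))
    rows = []
    if len(names) >= 3:
        hsd = stats.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append(dict(
                    group1=names[i], group2=names[j],
                    diff=float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    p_adj=float(hsd.pvalue[i, j])))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "diff",
                                           "p_adj"])
    return F, p, pairwise


def slope_regression(x, y) -> tuple[float, float, float]:
    """OLS of y on x; returns (slope, R^2, p for slope != 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2), float(res.pvalue)
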