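"""Two-group comparison statistics for matched cohorts.

Mirrors the analysis plan of a small matched fracture study: per-group
normality is gated by the Anderson-Darling test at alpha = 0.05; measures
normal in both groups are compared with a two-sample pooled-variance t
test (two-sided by default, a one-sided fracture < control alternative is
available), otherwise with the Wilcoxon rank-sum (Mann-Whitney) test.
Group summaries are reported as mean +/- SD when normal and median [IQR]
otherwise; the mean difference (fracture - control) carries a pooled-SD
t-based 95% CI and Cohen's d.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "CohortComparison", "compare_groups",
           "compare_many"]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    normal: bool

    def display(self) -> str:
        if self.normal:
            return f"{self.mean:.3g} +/- {self.sd:.3g}"
        return f"{self.median:.3g} [{self.q1:.3g}-{self.q3:.3g}]"


@dataclass(frozen=True)
class CohortComparison:
    """Comparison of one measure between the fracture and control groups."""

    measure: str
    fracture: GroupSummary
    control: GroupSummary
    test: str                     # "two_sample_t" | "wilcoxon_rank_sum"
    p_value: float
    mean_difference: float        # fracture - control
    ci95: tuple[float, float]
    cohens_d: float
    alpha: float = 0.05
    alternative: str = "two-sided"
    warnings_: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "fracture": self.fracture.display(),
            "control": self.control.display(),
            "normal_fracture": self.fracture.normal,
            "normal_control": self.control.normal,
            "test": self.test,
            "p_value": self.p_value,
            "mean_difference": self.mean_difference,
            "ci95": list(self.ci95),
            "cohens_d": self.cohens_d,
            "alpha": self.alpha,
            "alternative": self.alternative,
            "warnings": list(self.warnings_),
        }


def _summary(x: np.ndarray, normal: bool) -> GroupSummary:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return GroupSummary(n=x.size, mean=float(x.mean()),
                        sd=float(x.std(ddof=1)), median=float(med),
                        q1=float(q1), q3=float(q3), normal=normal)


def _anderson_normal(x: np.ndarray, notes: list[str], label: str) -> bool:
    """Anderson-Darling normality decision at the 5% level."""
    if np.ptp(x) == 0:
        notes.append(f"{label} group is constant; normality test "
                     "inapplicable, falling back to rank-sum")
        return False
    try:
        res = sps.anderson(x, dist="norm", method="interpolate")
        return bool(res.pvalue > 0.05)
    except TypeError:  # older scipy: fixed critical-value table
        res = sps.anderson(x, dist="norm")
        idx = int(np.argmin(np.abs(np.asarray(res.significance_level) - 5.0)))
        return bool(res.statistic < res.critical_values[idx])


def compare_groups(data: pd.DataFrame, measure: str,
                   group_col: str = "group", alpha: float = 0.05,
                   alternative: str = "two-sided") -> CohortComparison:
    """Compare one measure between the fracture and control groups.

    ``alternative`` is "two-sided" (default) or "less" for the one-sided
    hypothesis that the fracture group's values are lower.
    """
    if alternative not in ("two-sided", "less"):
        raise ValueError("alternative must be 'two-sided' or 'less'")
    if measure not in data.columns:
        raise ValueError(f"measure {measure!r} not in table")
    frac = data.loc[data[group_col] == "fracture", measure].to_numpy(float)
    ctrl = data.loc[data[group_col] == "control", measure].to_numpy(float)
    if frac.size < 2 or ctrl.size < 2:
        raise ValueError("need at least two subjects per group")
    if not (np.all(np.isfinite(frac)) and np.all(np.isfinite(ctrl))):
        raise ValueError(f"measure {measure!r} contains non-finite values")

    notes: list[str] = []
    norm_f = _anderson_normal(frac, notes, "fracture")
    norm_c = _anderson_normal(ctrl, notes, "control")

    if norm_f and norm_c:
        test = "two_sample_t"
        stat = sps.ttest_ind(frac, ctrl, equal_var=True,
                             alternative=alternative)
        p = float(stat.pvalue)
    else:
        test = "wilcoxon_rank_sum"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ties warning on tiny samples
            stat = sps.mannwhitneyu(frac, ctrl, alternative=alternative)
        p = float(stat.pvalue)

    n1, n2 = frac.size, ctrl.size
    diff = float(frac.mean() - ctrl.mean())
    dof = n1 + n2 - 2
    sp2 = ((n1 - 1) * frac.var(ddof=1) + (n2 - 1) * ctrl.var(ddof=1)) / dof
    sp = math.sqrt(max(sp2, 0.0))
    if sp > 0:
        se = sp * math.sqrt(1 / n1 + 1 / n2)
        tcrit = float(sps.t.ppf(0.975, dof))
        ci = (diff - tcrit * se, diff + tcrit * se)
        d = diff / sp
    else:
        ci = (diff, diff)
        d = 0.0
        notes.append("pooled SD is zero; effect size set to 0")

    return CohortComparison(
        measure=measure,
        fracture=_summary(frac, norm_f),
        control=_summary(ctrl, norm_c),
        test=test, p_value=p, mean_difference=diff, ci95=ci,
        cohens_d=float(d), alpha=alpha, alternative=alternative,
        warnings_=tuple(notes),
    )


def compare_many(data: pd.DataFrame, measures: list[str],
                 **kwargs) -> list[CohortComparison]:
    """`compare_groups` over several measures (no multiplicity correction)."""
    return [compare_groups(data, m, **kwargs) for m in measures]
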