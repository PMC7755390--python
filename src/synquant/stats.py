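"""Hierarchical group statistics with normality-gated test selection.

The unit of analysis for all group comparisons is the animal: cell-level
values are first averaged per (animal, group), and only those per-animal
means enter the tests.  Test selection follows the normality gate used in
the source analyses: Shapiro-Wilk per group at α = 0.05; two groups →
Student's t (equal variance) or Mann-Whitney U; more than two → one-way
ANOVA with Tukey's range post hoc, or Kruskal-Wallis.  Cumulative
frequency (ECDF) summaries are computed on cell-level values to show the
diversity across the whole pool of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd


@dataclass
class TestReport:
    """Outcome of one group comparison.

    ``branch`` records which test fired: "t", "mannwhitney", "anova",
    "kruskal", or "degenerate".  ``posthoc`` is a pairwise table (group1,
    group2, meandiff, p_adj, reject) present only after an omnibus test.
    """

    test_name: str
    statistic: float
    p_value: float
    branch: str
    alpha: float = 0.05
    normality_p: dict[str, float] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        d = {
            "test": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "branch": self.branch,
            "alpha": self.alpha,
            "normality_p": self.normality_p,
            "degenerate": self.degenerate,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def animal_means(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a cell-level table to one arithmetic mean per animal.

    Expects columns value, animal_id, group_label (cell_id optional).
    """
    if table.empty:
        raise ValueError("empty measurement table")
    out = (
        table.groupby(["animal_id", "group_label"], as_index=False, sort=True)["value"]
        .mean()
    )
    return out


def _groups_from_table(per_animal: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        str(g): grp["value"].to_numpy(dtype=float)
        for g, grp in per_animal.groupby("group_label", sort=True)
    }


def compare_groups(
    per_animal: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = False,
) -> TestReport:
    """Normality-gated comparison of per-animal means across groups.

    Two groups: Shapiro-Wilk on each; both normal → two-tailed two-sample
    t-test (equal variance unless ``welch``), else Mann-Whitney U.  More
    than two: all normal → one-way ANOVA + Tukey post hoc, else
    Kruskal-Wallis.  Groups whose values are all identical across the
    board make the variance degenerate; the report then carries the
    p = 1 convention and a flag.
    """
    groups = _groups_from_table(per_animal)
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 animals")

    values = list(groups.values())
    labels = list(groups.keys())
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0 or all(np.ptp(v) == 0 for v in values) and len(
        {v[0] for v in values}
    ) == 1:
        name = "anova" if len(groups) > 2 else "t"
        return TestReport(
            test_name=name, statistic=0.0, p_value=1.0, branch="degenerate",
            alpha=alpha, degenerate=True,
        )

    normality_p: dict[str, float] = {}
    all_normal = True
    for g, v in groups.items():
        if len(v) < 3 or np.ptp(v) == 0:
            # Shapiro-Wilk needs ≥3 distinct-capable values; treat tiny or
            # constant groups as failing the gate conservatively.
            normality_p[g] = float("nan")
            all_normal = all_normal and len(v) >= 3
            if len(v) >= 3 and np.ptp(v) == 0:
                all_normal = False
            continue
        p = sps.shapiro(v).pvalue
        normality_p[g] = float(p)
        if p < alpha:
            all_normal = False

    posthoc = None
    if len(groups) == 2:
        a, b = values
        if all_normal:
            stat, p = sps.ttest_ind(a, b, equal_var=not welch)
            branch, name = "t", "welch_t" if welch else "student_t"
        else:
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            branch, name = "mannwhitney", "mannwhitney_u"
    else:
        if all_normal:
            stat, p = sps.f_oneway(*values)
            branch, name = "anova", "oneway_anova"
            flat = np.concatenate(values)
            glab = np.concatenate([[lab] * len(v) for lab, v in zip(labels, values)])
            tk = pairwise_tukeyhsd(flat, glab, alpha=alpha)
            posthoc = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            ).rename(columns={"p-adj": "p_adj"})
        else:
            stat, p = sps.kruskal(*values)
            branch, name = "kruskal", "kruskal_wallis"

    return TestReport(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        branch=branch,
        alpha=alpha,
        normality_p=normality_p,
        posthoc=posthoc,
    )


def oneway_anova_f(per_animal: pd.DataFrame) -> tuple[float, float]:
    """One-way ANOVA F and p on per-animal means (no gating), for
    reproducing deposited summary statistics."""
    groups = _groups_from_table(per_animal)
    stat, p = sps.f_oneway(*groups.values())
    return float(stat), float(p)


def ecdf(values) -> pd.DataFrame:
    """Empirical cumulative distribution: sorted unique values with the
    cumulative fraction of observations ≤ each value (final fraction 1)."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    uniq, counts = np.unique(v, return_counts=True)
    frac = np.cumsum(counts) / v.size
    return pd.DataFrame({"value": uniq, "cum_fraction": frac})


def sem_summary(per_animal: pd.DataFrame) -> pd.DataFrame:
    """Mean ± s.e.m. per group from per-animal values.

    s.e.m. = sample sd (ddof=1) / √n; reported as NaN when n < 2.
    """
    rows = []
    for g, grp in per_animal.groupby("group_label", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) >= 2 else float("nan")
        rows.append({"group_label": g, "n": len(v), "mean": float(v.mean()), "sem": sem})
    return pd.DataFrame(rows)
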