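"""Hierarchical (per-animal) statistics.

Cells within a mouse are not independent replicates: all tests collapse
per-cell values to per-mouse means first and test at the mouse level
("nested" testing), which keeps the type-I error at its nominal level
where naive per-cell pooling inflates it badly.  Normality is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "nested_t_test",
    "paired_t_test",
    "anova_vs_control",
    "export_violin_data",
]

Hierarchical = Mapping[str, Sequence[float]]  # unit id (mouse) -> per-cell values


@dataclass
class TestResult:
    test: str
    statistic: float
    dof: float
    p_value: float
    group_means: tuple[float, ...]
    n_units: tuple[int, ...]
    n_values: tuple[int, ...]


def _unit_means(sample: Hierarchical, min_units: int = 2) -> np.ndarray:
    if len(sample) < min_units:
        raise ValueError(f"need >= {min_units} units (mice), got {len(sample)}")
    means = []
    for unit, values in sample.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"unit {unit!r} has no values")
        means.append(values.mean())
    return np.asarray(means)


def nested_t_test(a: Hierarchical, b: Hierarchical, name: str = "nested t") -> TestResult:
    """Two-sided two-sample t-test on per-unit means (equal variance).

    Each mouse contributes one number (its mean over cells); with one value
    per unit this reduces to the classical two-sample t-test.
    """
    ma, mb = _unit_means(a), _unit_means(b)
    t, p = sps.ttest_ind(ma, mb, equal_var=True)
    if np.isnan(t):  # zero variance in both groups, identical means
        t, p = 0.0, 1.0
    return TestResult(
        test=name,
        statistic=float(t),
        dof=float(len(ma) + len(mb) - 2),
        p_value=float(p),
        group_means=(float(ma.mean()), float(mb.mean())),
        n_units=(len(ma), len(mb)),
        n_values=(sum(len(np.atleast_1d(v)) for v in a.values()),
                  sum(len(np.atleast_1d(v)) for v in b.values())),
    )


def paired_t_test(pre: Hierarchical, post: Hierarchical,
                  name: str = "paired t") -> TestResult:
    """Two-sided paired t-test on per-unit means of matched units.

    The revisit design: each mouse is measured before and after.
    """
    if set(pre) != set(post):
        raise ValueError(
            f"unmatched units: pre-only {sorted(set(pre) - set(post))}, "
            f"post-only {sorted(set(post) - set(pre))}"
        )
    units = sorted(pre)
    if len(units) < 2:
        raise ValueError("paired test needs >= 2 matched units")
    mpre = np.array([np.mean(np.asarray(pre[u], dtype=float)) for u in units])
    mpost = np.array([np.mean(np.asarray(post[u], dtype=float)) for u in units])
    t, p = sps.ttest_rel(mpost, mpre)
    if np.isnan(t):
        t, p = 0.0, 1.0
    return TestResult(
        test=name,
        statistic=float(t),
        dof=float(len(units) - 1),
        p_value=float(p),
        group_means=(float(mpre.mean()), float(mpost.mean())),
        n_units=(len(units), len(units)),
        n_values=(sum(len(np.atleast_1d(pre[u])) for u in units),
                  sum(len(np.atleast_1d(post[u])) for u in units)),
    )


def anova_vs_control(
    groups: Mapping[str, Hierarchical],
    control_label: str = "CONTROL",
):
    """One-way ANOVA on per-unit means plus Holm-adjusted pairwise
    comparisons of every group against the control.

    Returns (TestResult for the ANOVA, comparisons DataFrame with columns
    comparison/t/dof/p_raw/p_holm).  Holm is slightly conservative
    relative to Dunnett but needs no multivariate-t quantiles.
    """
    if control_label not in groups:
        raise ValueError(f"control label {control_label!r} absent from groups")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    means = {g: _unit_means(s) for g, s in groups.items()}
    F, p = sps.f_oneway(*means.values())
    if np.isnan(F):
        F, p = 0.0, 1.0
    k = len(means)
    n_tot = sum(len(m) for m in means.values())
    anova = TestResult(
        test="one-way ANOVA (per-mouse means)",
        statistic=float(F),
        dof=float(k - 1),
        p_value=float(p),
        group_means=tuple(float(m.mean()) for m in means.values()),
        n_units=tuple(len(m) for m in means.values()),
        n_values=tuple(
            sum(len(np.atleast_1d(v)) for v in s.values()) for s in groups.values()
        ),
    )
    rows = []
    others = [g for g in groups if g != control_label]
    for g in others:
        t, praw = sps.ttest_ind(means[g], means[control_label], equal_var=True)
        if np.isnan(t):
            t, praw = 0.0, 1.0
        rows.append({"comparison": f"{g} vs {control_label}", "t": float(t),
                     "dof": len(means[g]) + len(means[control_label]) - 2,
                     "p_raw": float(praw)})
    comps = pd.DataFrame(rows)
    if len(comps):
        comps["p_holm"] = multipletests(comps["p_raw"], method="holm")[1]
    else:
        comps["p_holm"] = pd.Series(dtype=float)
    return anova, comps


def export_violin_data(
    cells: pd.DataFrame,
    grouping: Sequence[str] = ("genotype", "timepoint_days"),
    value_col: str = "normalized_ratio",
):
    """Tidy violin-plot export: long per-cell rows plus per-mouse means.

    Returns (long DataFrame with group/mouse/value, means DataFrame) -
    the pooled violins and the coloured per-mouse overlay dots.
    """
    grouping = list(grouping)
    missing = [c for c in grouping + ["mouse_id", value_col] if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table lacks columns {missing}")
    if len(cells) == 0:
        long = pd.DataFrame(columns=grouping + ["mouse_id", "value"])
        means = pd.DataFrame(columns=grouping + ["mouse_id", "mean_value", "n_cells"])
        return long, means
    long = cells[grouping + ["mouse_id", value_col]].rename(columns={value_col: "value"})
    means = (
        long.groupby(grouping + ["mouse_id"], as_index=False)["value"]
        .agg(mean_value="mean", n_cells="count")
    )
    return long.reset_index(drop=True), means
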