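"""Per-subject summaries and cohort statistics.

The detection logic rests on bilateral comparison: for each view pair the two
breasts' average permittivities are compared through a normalized difference

    delta = (eps_L - eps_R) / ((eps_L + eps_R) / 2)

and the contralateral ratio

    rho = max(eps_L, eps_R) / min(eps_L, eps_R),

with rho near 1 for healthy symmetry and elevated when one breast carries a
tumor.  Cohort-level comparisons use one-way ANOVA across the four views,
two-way ANOVA (group x view, Type-II sums of squares) and pooled two-sample
t-tests at a 0.05 significance threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
VIEW_PAIRS = {"CC": ("LCC", "RCC"), "MLO": ("LMLO", "RMLO")}


@dataclass
class StatResult:
    """Outcome of a single hypothesis test."""

    name: str  # "F" or "t"
    value: float
    df1: float
    df2: Optional[float]
    p_value: float
    significant: bool
    degenerate: bool = False

    @classmethod
    def make(cls, name, value, df1, df2, p, degenerate=False):
        return cls(name, float(value), df1, df2, float(p), bool(p < ALPHA), degenerate)


@dataclass
class SubjectRecord:
    """Per-subject summary feeding the cohort statistics."""

    subject_id: str
    group: str
    eps_avg: dict[str, float]  # per view (LCC/RCC/LMLO/RMLO) breast average
    separation_mm: dict[str, float]
    area_ratio: dict[str, float]
    ratio: dict[str, float] = field(default_factory=dict)  # per view pair (CC/MLO)
    norm_diff: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair_name, (left, right) in VIEW_PAIRS.items():
            if left in self.eps_avg and right in self.eps_avg and pair_name not in self.ratio:
                self.ratio[pair_name] = contralateral_ratio(
                    self.eps_avg[left], self.eps_avg[right]
                )
                self.norm_diff[pair_name] = normalized_difference(
                    self.eps_avg[left], self.eps_avg[right]
                )


def breast_average(image, mask: np.ndarray) -> float:
    """Mean reconstructed permittivity over the breast mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty breast mask")
    return float(np.asarray(image.epsilon_map)[mask].mean())


def normalized_difference(eps_left: float, eps_right: float) -> float:
    """Left-right difference normalized to the mean of the two breast averages."""
    if eps_left <= 0 or eps_right <= 0:
        raise ValueError("breast averages must be positive")
    return (eps_left - eps_right) / ((eps_left + eps_right) / 2.0)


def contralateral_ratio(eps_a: float, eps_b: float) -> float:
    """Higher-over-lower ratio of the two breast averages; >= 1, symmetric."""
    if eps_a <= 0 or eps_b <= 0:
        raise ValueError("breast averages must be positive")
    return max(eps_a, eps_b) / min(eps_a, eps_b)


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatResult:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >= 2 groups, each nonempty")
    n_total = sum(len(a) for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    if df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0:
        if ss_between == 0:
            return StatResult.make("F", 0.0, df_between, df_within, 1.0, degenerate=True)
        return StatResult.make("F", math.inf, df_between, df_within, 0.0, degenerate=True)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return StatResult.make("F", f, df_between, df_within, p)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], two_tailed: bool = True
) -> StatResult:
    """Pooled-variance two-sample t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    df = len(a) + len(b) - 2
    pooled = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
    if pooled == 0:
        t = 0.0 if a.mean() == b.mean() else math.inf * np.sign(a.mean() - b.mean())
        p = 1.0 if t == 0 else 0.0
        return StatResult.make("t", t, df, None, p, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=True, alternative="two-sided" if two_tailed else "greater")
    return StatResult.make("t", res.statistic, df, None, res.pvalue)


def two_way_anova(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "group",
    factor_b: str = "view",
) -> dict[str, StatResult]:
    """Two-way ANOVA with interaction, Type-II sums of squares.

    ``data`` holds one row per observation with columns for the response and
    the two categorical factors.  Unbalanced designs are allowed; empty factor
    cells are an error.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    levels_a = data[factor_a].unique()
    levels_b = data[factor_b].unique()
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs >= 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if (la, lb) not in counts.index:
                raise ValueError(f"empty cell: {factor_a}={la!r}, {factor_b}={lb!r}")
    if len(data) - len(levels_a) * len(levels_b) < 1:
        raise ValueError("no residual degrees of freedom for the interaction model")
    model = ols(f"Q('{response}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])
    out: dict[str, StatResult] = {}
    keymap = {
        f"C(Q('{factor_a}'))": factor_a,
        f"C(Q('{factor_b}'))": factor_b,
        f"C(Q('{factor_a}')):C(Q('{factor_b}'))": "interaction",
    }
    for row, key in keymap.items():
        out[key] = StatResult.make(
            "F", table.loc[row, "F"], float(table.loc[row, "df"]), df_resid, table.loc[row, "PR(>F)"]
        )
    return out


def records_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Long-format table: one row per (subject, view)."""
    rows = []
    for r in records:
        for view, eps in r.eps_avg.items():
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "view": view,
                    "eps_avg": eps,
                    "separation_mm": r.separation_mm.get(view, np.nan),
                    "area_ratio": r.area_ratio.get(view, np.nan),
                }
            )
    return pd.DataFrame(rows)


def ratios_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """One row per (subject, view pair) with ratio and normalized difference."""
    rows = []
    for r in records:
        for pair_name, rho in r.ratio.items():
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "group": r.group,
                    "view_pair": pair_name,
                    "ratio": rho,
                    "norm_diff": r.norm_diff[pair_name],
                }
            )
    return pd.DataFrame(rows)


def group_mean_ratio(records: Sequence[SubjectRecord], group: str, view_pair: str = "CC") -> float:
    """Mean contralateral ratio over the subjects of one group for one view pair."""
    vals = [r.ratio[view_pair] for r in records if r.group == group and view_pair in r.ratio]
    if not vals:
        raise ValueError(f"no {view_pair} ratios for group {group!r}")
    return float(np.mean(vals))


def cohort_report(records: Sequence[SubjectRecord]) -> dict:
    """Summary tables and the standard test battery for a cohort.

    Returns a dict with DataFrames ``subjects`` (per-view quantities),
    ``ratios`` (per view pair), ``group_mean_ratios``, and a ``tests`` dict of
    StatResult (plus skip reasons for tests the cohort cannot support).
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    subjects = records_frame(records)
    ratios = ratios_frame(records)
    gmr = (
        ratios.groupby(["group", "view_pair"], observed=True)["ratio"]
        .mean()
        .reset_index()
        .rename(columns={"ratio": "mean_ratio"})
    )
    tests: dict[str, object] = {}
    groups_present = subjects["group"].unique()
    for g in groups_present:
        sub = subjects[subjects["group"] == g]
        for response in ("eps_avg", "separation_mm", "area_ratio"):
            key = f"oneway_{response}_{g}"
            by_view = [sub[sub["view"] == v][response].dropna().to_numpy() for v in sorted(sub["view"].unique())]
            if len(sub["subject_id"].unique()) < 2 or any(len(v) == 0 for v in by_view):
                tests[key] = "skipped: not enough subjects"
            else:
                tests[key] = one_way_anova(by_view)
    if len(groups_present) == 2:
        for response in ("eps_avg", "separation_mm", "area_ratio"):
            try:
                tests[f"twoway_{response}"] = two_way_anova(subjects, response)
            except ValueError as exc:
                tests[f"twoway_{response}"] = f"skipped: {exc}"
        for pair_name in ratios["view_pair"].unique():
            sel = ratios[ratios["view_pair"] == pair_name]
            a = sel[sel["group"] == "healthy"]["ratio"].to_numpy()
            b = sel[sel["group"] == "cancer"]["ratio"].to_numpy()
            key = f"ttest_ratio_{pair_name}"
            if len(a) >= 2 and len(b) >= 2:
                tests[key] = two_sample_t(a, b)
            else:
                tests[key] = "skipped: not enough subjects"
    else:
        tests["twoway"] = "skipped: need both groups"
    return {
        "subjects": subjects,
        "ratios": ratios,
        "group_mean_ratios": gmr,
        "tests": tests,
    }
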