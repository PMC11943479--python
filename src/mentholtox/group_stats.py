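"""Group-comparison statistics: ANOVA with Dunnett/Tukey post-hoc tests.

One-way designs use an omnibus F test followed by either Dunnett many-to-one
comparisons against a designated control or Tukey all-pairs comparisons.
Two-way designs (time × treatment) report the omnibus ANOVA table and, per
treatment, the earliest time point at which it first differs from the
control — with the family-wise error rate controlled over the entire
time × treatment comparison family (Dunnett within each time slice, Šidák
across time slices).

Data that violate ANOVA assumptions (per-group Shapiro-Wilk normality or
median-centered Levene variance homogeneity) can be log-transformed first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedData",
    "DunnettResult",
    "TukeyResult",
    "TwoWayDunnettResult",
    "TransformReport",
    "check_and_transform",
    "anova_dunnett",
    "anova_dunnett_arrays",
    "anova_tukey",
    "two_way_anova_dunnett",
]


@dataclass(frozen=True)
class GroupedData:
    """Tidy measurements with a treatment label and optional time factor.

    ``table`` needs columns ``value`` and ``group`` (plus ``time`` for
    two-way designs); ``control_group`` must be one of the group labels.
    """

    table: pd.DataFrame
    control_group: str

    def __post_init__(self) -> None:
        if not {"value", "group"}.issubset(self.table.columns):
            raise ValueError("table needs columns 'value' and 'group'")
        groups = self.table["group"].unique()
        if len(groups) < 2:
            raise ValueError("need >= 2 groups")
        if self.control_group not in groups:
            raise ValueError(f"control group {self.control_group!r} not present")

    @property
    def has_time(self) -> bool:
        return "time" in self.table.columns

    def group_arrays(self) -> tuple[list[str], list[np.ndarray], np.ndarray]:
        """(treatment labels, treatment value arrays, control values)."""
        control = self.table.loc[
            self.table["group"] == self.control_group, "value"
        ].to_numpy(dtype=float)
        labels, arrays = [], []
        for g, sub in self.table.groupby("group", sort=False):
            if g == self.control_group:
                continue
            labels.append(g)
            arrays.append(sub["value"].to_numpy(dtype=float))
        return labels, arrays, control


@dataclass(frozen=True)
class TransformReport:
    transformed: bool
    trigger: str | None            # "normality", "homogeneity" or None
    shapiro_p: dict = field(default_factory=dict)
    levene_p: float = float("nan")


def check_and_transform(
    data: GroupedData, alpha: float = 0.05
) -> tuple[GroupedData, TransformReport]:
    """Apply log(y) iff the ANOVA assumptions fail on the raw scale.

    Normality is tested once, by Shapiro-Wilk on the pooled within-group
    centered residuals (the quantity ANOVA actually assumes normal — and a
    single test keeps the null trigger rate near alpha rather than
    inflating it with the number of groups); homogeneity by median-centered
    Levene. If either rejects at ``alpha`` the values are log-transformed
    (natural log); non-positive values then raise with the offending rows
    listed. Per-group Shapiro p-values are included in the report as
    diagnostics only.
    """
    shapiro_p: dict = {}
    trigger = None
    arrays = [sub["value"].to_numpy(dtype=float)
              for _, sub in data.table.groupby("group", sort=False)]
    for (g, sub) in data.table.groupby("group", sort=False):
        v = sub["value"].to_numpy(dtype=float)
        if v.size >= 3 and np.ptp(v) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                shapiro_p[g] = float(stats.shapiro(v).pvalue)
    residuals = np.concatenate([a - a.mean() for a in arrays])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        resid_normal_p = float(stats.shapiro(residuals).pvalue)
    shapiro_p["residuals"] = resid_normal_p
    levene_p = float(stats.levene(*arrays, center="median").pvalue)
    if resid_normal_p < alpha:
        trigger = "normality"
    elif levene_p < alpha:
        trigger = "homogeneity"
    report = TransformReport(trigger is not None, trigger, shapiro_p, levene_p)
    if trigger is None:
        return data, report
    bad = data.table[data.table["value"] <= 0]
    if not bad.empty:
        raise ValueError(
            f"log transform required but {len(bad)} rows are non-positive: "
            f"indices {bad.index.tolist()[:10]}"
        )
    transformed = data.table.copy()
    transformed["value"] = np.log(transformed["value"])
    return GroupedData(transformed, data.control_group), report


@dataclass(frozen=True)
class DunnettResult:
    omnibus_f: float
    omnibus_p: float
    groups: list
    p_adjusted: np.ndarray
    statistic: np.ndarray


def anova_dunnett_arrays(
    groups: list[np.ndarray], control: np.ndarray, labels: list | None = None
) -> DunnettResult:
    """Omnibus F then Dunnett many-to-one comparisons, on raw arrays."""
    if any(len(g) < 2 for g in groups) or len(control) < 2:
        raise ValueError("every group (incl. control) needs >= 2 replicates")
    f, p = stats.f_oneway(control, *groups)
    res = stats.dunnett(*groups, control=control)
    return DunnettResult(
        omnibus_f=float(f),
        omnibus_p=float(p),
        groups=labels if labels is not None else list(range(len(groups))),
        p_adjusted=np.atleast_1d(res.pvalue),
        statistic=np.atleast_1d(res.statistic),
    )


def anova_dunnett(data: GroupedData, alpha: float = 0.05) -> pd.DataFrame:
    """Dunnett comparisons of every treatment against the control group.

    Controls the family-wise error rate at ``alpha`` across the many-to-one
    family via the multivariate-t distribution of the Dunnett statistics.
    """
    labels, arrays, control = data.group_arrays()
    res = anova_dunnett_arrays(arrays, control, labels=labels)
    return pd.DataFrame({
        "group": labels,
        "statistic": res.statistic,
        "p_adjusted": res.p_adjusted,
        "significant": res.p_adjusted < alpha,
        "omnibus_f": res.omnibus_f,
        "omnibus_p": res.omnibus_p,
    })


@dataclass(frozen=True)
class TukeyResult:
    omnibus_f: float
    omnibus_p: float
    table: pd.DataFrame


def anova_tukey(data: GroupedData, alpha: float = 0.05) -> TukeyResult:
    """Omnibus F then Tukey HSD all-pairs comparisons."""
    labels = list(data.table["group"].unique())
    arrays = [data.table.loc[data.table["group"] == g, "value"].to_numpy(dtype=float)
              for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 replicates")
    f, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({
                "group_a": labels[i],
                "group_b": labels[j],
                "p_adjusted": float(res.pvalue[i, j]),
                "significant": bool(res.pvalue[i, j] < alpha),
            })
    return TukeyResult(float(f), float(p), pd.DataFrame(rows))


@dataclass(frozen=True)
class TwoWayDunnettResult:
    anova_table: pd.DataFrame
    comparisons: pd.DataFrame          # time, group, p_adjusted, significant
    first_significant_time: dict       # group -> time or None
    degraded_to_oneway: bool = False


def two_way_anova_dunnett(
    data: GroupedData, alpha: float = 0.05
) -> TwoWayDunnettResult:
    """Time × treatment ANOVA with Dunnett comparisons to control per time.

    The omnibus table comes from an OLS fit with both factors and their
    interaction. Post-hoc, every treatment is compared to the control at
    every time point; p-values are Dunnett-adjusted within each time slice
    and Šidák-adjusted across time slices, so the family-wise error rate
    over the whole time × treatment family is held at ``alpha``. Each
    group's first-significant-time is the earliest time surviving both
    adjustments. A single-time design degrades to the one-way analysis with
    a warning.
    """
    if not data.has_time:
        raise ValueError("two-way design needs a 'time' column")
    times = np.sort(data.table["time"].unique())
    groups = list(data.table["group"].unique())
    missing = [
        (t, g) for t in times for g in groups
        if data.table[(data.table["time"] == t) & (data.table["group"] == g)].empty
    ]
    if missing:
        raise ValueError(f"missing time x group cells: {missing}")

    if len(times) == 1:
        warnings.warn("single time point: degrading to one-way ANOVA", stacklevel=2)
        one = anova_dunnett(GroupedData(data.table, data.control_group), alpha)
        comp = one.assign(time=times[0])[["time", "group", "p_adjusted", "significant"]]
        first = {
            g: (float(times[0]) if bool(comp.loc[comp["group"] == g, "significant"].iloc[0]) else None)
            for g in comp["group"]
        }
        table = pd.DataFrame({
            "F": [one["omnibus_f"].iloc[0]], "PR(>F)": [one["omnibus_p"].iloc[0]],
        }, index=["C(group)"])
        return TwoWayDunnettResult(table, comp, first, degraded_to_oneway=True)

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(group) * C(time)", data=data.table).fit()
    anova_table = sm.stats.anova_lm(model, typ=2)

    n_times = len(times)
    rows = []
    for t in times:
        sub = data.table[data.table["time"] == t]
        sliced = GroupedData(sub.drop(columns="time"), data.control_group)
        labels, arrays, control = sliced.group_arrays()
        res = stats.dunnett(*arrays, control=control)
        p_within = np.atleast_1d(res.pvalue)
        # Sidak across the time slices
        p_total = 1.0 - (1.0 - p_within) ** n_times
        for g, pw, pt in zip(labels, p_within, p_total):
            rows.append({
                "time": t, "group": g,
                "p_dunnett": float(pw),
                "p_adjusted": float(np.clip(pt, 0.0, 1.0)),
                "significant": bool(pt < alpha),
            })
    comparisons = pd.DataFrame(rows)
    first: dict = {}
    for g in comparisons["group"].unique():
        sig = comparisons[(comparisons["group"] == g) & comparisons["significant"]]
        first[g] = float(sig["time"].min()) if not sig.empty else None
    return TwoWayDunnettResult(anova_table, comparisons, first)
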