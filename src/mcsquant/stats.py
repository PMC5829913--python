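"""Statistical reporting layer for per-cell measure tables.

Per-cell imaging measures are rarely Gaussian, so the primary comparison
route is nonparametric: D'Agostino–Pearson K² normality screening, a
tie-corrected Kruskal–Wallis omnibus test, and Dunn's multiple-comparison
z tests on pooled ranks with a Bonferroni-style adjustment over the
declared contrast family (all pairs, or each group against a control —
matching the behaviour of Prism's "Dunn's multiple comparison test").

For time-course designs (condition between cells, time within cells) a
balanced split-plot two-way ANOVA on natural-log-transformed values is
provided, with Tukey HSD contrasts between conditions and an optional
Greenhouse–Geisser correction of the within-cell tests.

Cells are treated as independent replicates; an experiment identifier is
carried through for sensitivity analyses but not modelled hierarchically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupedMeasures:
    """Tidy per-cell values: columns value, group, cell (+ experiment, time)."""

    data: pd.DataFrame
    measure: str = "measure"

    def __post_init__(self) -> None:
        required = {"value", "group", "cell"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"GroupedMeasures is missing columns {sorted(missing)}")
        if self.data.empty:
            raise ValueError("GroupedMeasures has no rows")

    @classmethod
    def from_arrays(
        cls,
        values_by_group: dict[str, np.ndarray],
        measure: str = "measure",
    ) -> "GroupedMeasures":
        rows = []
        cell = 0
        for group, vals in values_by_group.items():
            for v in np.asarray(vals, dtype=float):
                rows.append({"value": v, "group": group, "cell": cell})
                cell += 1
        return cls(pd.DataFrame(rows), measure=measure)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))

    def values(self, group: str) -> np.ndarray:
        return self.data.loc[self.data["group"] == group, "value"].to_numpy(float)


@dataclass(frozen=True)
class ComparisonReport:
    """Omnibus + pairwise results with per-group summaries."""

    measure: str
    omnibus_test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame
    summary: pd.DataFrame
    anova_table: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"measure: {self.measure}",
            f"{self.omnibus_test}: statistic = {self.statistic:.4g}, p = {self.p_value:.4g}",
            "",
            "group summaries:",
            self.summary.to_string(index=False),
            "",
            "pairwise comparisons:",
            self.pairwise.to_string(index=False),
        ]
        if self.anova_table is not None:
            lines += ["", "ANOVA table:", self.anova_table.to_string(index=False)]
        return "\n".join(lines)


MIN_NORMALITY_N = 8  # validity floor of the K² omnibus test


def check_normality(grouped: GroupedMeasures, min_n: int = MIN_NORMALITY_N) -> pd.DataFrame:
    """D'Agostino–Pearson K² per group; undersized groups are declared missing."""
    rows = []
    for g in grouped.groups:
        vals = grouped.values(g)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_n:
            rows.append(
                {"group": g, "n": len(vals), "k2": math.nan, "p": math.nan,
                 "reason": f"undersized (n < {min_n})"}
            )
            continue
        k2, p = sps.normaltest(vals)
        rows.append({"group": g, "n": len(vals), "k2": float(k2), "p": float(p), "reason": ""})
    return pd.DataFrame(rows)


def summarize(grouped: GroupedMeasures, whiskers: tuple[float, float] = (5.0, 95.0)) -> pd.DataFrame:
    """Median, quartiles, percentile whiskers and mean ± s.e. per group.

    Quantiles use linear interpolation between order statistics.
    """
    lo, hi = whiskers
    rows = []
    for g in grouped.groups:
        vals = grouped.values(g)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            continue
        sem = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "median": float(np.percentile(vals, 50)),
                "q1": float(np.percentile(vals, 25)),
                "q3": float(np.percentile(vals, 75)),
                f"p{lo:g}": float(np.percentile(vals, lo)),
                f"p{hi:g}": float(np.percentile(vals, hi)),
                "mean": float(vals.mean()),
                "sem": sem,
            }
        )
    return pd.DataFrame(rows)


def _dunn_pairwise(
    groups: list[str],
    values: dict[str, np.ndarray],
    contrasts: list[tuple[str, str]],
) -> pd.DataFrame:
    pooled = np.concatenate([values[g] for g in groups])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    mean_rank: dict[str, float] = {}
    i = 0
    for g in groups:
        n_g = len(values[g])
        mean_rank[g] = float(ranks[i : i + n_g].mean())
        i += n_g
    # tie correction: sum(t^3 - t) over tie groups
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))
    m = len(contrasts)
    rows = []
    for g1, g2 in contrasts:
        se2 = var_base * (1.0 / len(values[g1]) + 1.0 / len(values[g2]))
        if se2 <= 0:
            z = 0.0
        else:
            z = (mean_rank[g1] - mean_rank[g2]) / math.sqrt(se2)
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"group1": g1, "group2": g2, "z": z, "p_unadjusted": p,
             "p_adjusted": min(1.0, m * p)}
        )
    return pd.DataFrame(rows)


def kruskal_dunn(
    grouped: GroupedMeasures,
    control: str | None = None,
    whiskers: tuple[float, float] = (5.0, 95.0),
) -> ComparisonReport:
    """Kruskal–Wallis omnibus test with Dunn's post-hoc comparisons.

    ``control`` restricts the contrast family to each group versus the
    control (the Prism-style "compared to Ctrl" family); otherwise all
    pairs are compared. Fully tied data are handled through the tie
    correction (H = 0, p = 1), not as a failure.
    """
    groups = grouped.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    values = {g: grouped.values(g) for g in groups}
    for g, v in values.items():
        if len(v) == 0:
            raise ValueError(f"group {g!r} is empty")
    pooled = np.concatenate(list(values.values()))
    if np.all(pooled == pooled[0]):
        h_stat, p = 0.0, 1.0
    else:
        h_stat, p = sps.kruskal(*values.values())
    if control is not None:
        if control not in groups:
            raise ValueError(f"control group {control!r} not among groups {groups}")
        contrasts = [(g, control) for g in groups if g != control]
    else:
        contrasts = list(itertools.combinations(groups, 2))
    pairwise = _dunn_pairwise(groups, values, contrasts)
    return ComparisonReport(
        measure=grouped.measure,
        omnibus_test="Kruskal-Wallis",
        statistic=float(h_stat),
        p_value=float(p),
        pairwise=pairwise,
        summary=summarize(grouped, whiskers),
        extra={"contrast_family": "vs-control" if control else "all-pairs"},
    )


def _gg_epsilon(resid_matrix: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the within-cell covariance matrix."""
    s = np.cov(resid_matrix, rowvar=False, ddof=1)
    b = s.shape[0]
    mean_diag = np.trace(s) / b
    grand = s.mean()
    row_means = s.mean(axis=1)
    num = (b * (mean_diag - grand)) ** 2
    den = (b - 1) * (np.sum(s**2) - 2 * b * np.sum(row_means**2) + b**2 * grand**2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (b - 1))))


def rm_anova_log(
    grouped: GroupedMeasures,
    gg_correction: bool = False,
    log_transform: bool = True,
) -> ComparisonReport:
    """Split-plot two-way ANOVA (condition × time, cell as subject) on ln values.

    Requires strictly positive values (for the log transform) and a
    balanced design: every cell measured at every time point and equal cell
    counts per condition. Pairwise condition contrasts use Tukey's HSD on
    per-cell time-averaged means against the between-cell error term.
    """
    df = grouped.data
    if "time" not in df.columns:
        raise ValueError("rm_anova_log needs a 'time' column (repeated factor)")
    if log_transform:
        bad = df.loc[df["value"] <= 0, "cell"].unique()
        if len(bad):
            raise ValueError(
                f"log transform requires strictly positive values; offending cells: {list(bad)}"
            )
    times = sorted(df["time"].unique())
    groups = list(dict.fromkeys(df["group"]))
    a, b = len(groups), len(times)
    if a < 2 or b < 2:
        raise ValueError("need >= 2 conditions and >= 2 time points")
    # y[g] is an (n, b) matrix of ln values, cells x times
    mats = []
    n_per = None
    for g in groups:
        sub = df[df["group"] == g].pivot_table(index="cell", columns="time", values="value")
        if sub.isna().any().any() or list(sub.columns) != times:
            raise ValueError(f"condition {g!r} has an unbalanced time axis")
        mats.append(np.log(sub.to_numpy()) if log_transform else sub.to_numpy())
        if n_per is None:
            n_per = len(sub)
        elif len(sub) != n_per:
            raise ValueError("unequal cell counts per condition (balanced design required)")
    n = int(n_per)
    if n < 2:
        raise ValueError("need >= 2 cells per condition")
    y = np.stack(mats)  # (a, n, b)
    grand = y.mean()
    g_means = y.mean(axis=(1, 2))
    t_means = y.mean(axis=(0, 1))
    gt_means = y.mean(axis=1)  # (a, b)
    subj_means = y.mean(axis=2)  # (a, n)

    ss_total = float(((y - grand) ** 2).sum())
    ss_cond = n * b * float(((g_means - grand) ** 2).sum())
    ss_between_subj = b * float(((subj_means - grand) ** 2).sum())
    ss_subj_within = ss_between_subj - ss_cond
    ss_time = a * n * float(((t_means - grand) ** 2).sum())
    ss_inter = n * float(
        ((gt_means - g_means[:, None] - t_means[None, :] + grand) ** 2).sum()
    )
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_inter

    df_cond, df_subj = a - 1, a * (n - 1)
    df_time, df_inter = b - 1, (a - 1) * (b - 1)
    df_err = a * (n - 1) * (b - 1)
    ms = {
        "condition": ss_cond / df_cond,
        "subjects": ss_subj_within / df_subj,
        "time": ss_time / df_time,
        "interaction": ss_inter / df_inter,
        "error": ss_err_within / df_err,
    }
    eps = 1.0
    if gg_correction:
        # residual within-cell matrix after removing condition x time means
        resid = (y - gt_means[:, None, :]).reshape(a * n, b)
        eps = _gg_epsilon(resid)

    def _f_row(effect: str, ss: float, df1: int, ms_num: float, ms_den: float, df2: int, corr: float = 1.0):
        f_val = ms_num / ms_den if ms_den > 0 else math.nan
        p_val = float(sps.f.sf(f_val, df1 * corr, df2 * corr)) if np.isfinite(f_val) else math.nan
        return {"effect": effect, "ss": ss, "df1": df1, "df2": df2, "F": f_val, "p": p_val}

    table = pd.DataFrame(
        [
            _f_row("condition", ss_cond, df_cond, ms["condition"], ms["subjects"], df_subj),
            _f_row("time", ss_time, df_time, ms["time"], ms["error"], df_err, eps),
            _f_row("condition:time", ss_inter, df_inter, ms["interaction"], ms["error"], df_err, eps),
        ]
    )

    # Tukey HSD between conditions on cell-level means (between-cell error term)
    se = math.sqrt(ms["subjects"] / (n * b))
    rows = []
    for g1, g2 in itertools.combinations(range(a), 2):
        diff = g_means[g1] - g_means[g2]
        q = abs(diff) / se if se > 0 else 0.0
        p_val = float(sps.studentized_range.sf(q, a, df_subj)) if se > 0 else 1.0
        rows.append(
            {"group1": groups[g1], "group2": groups[g2],
             "estimate_ln": float(diff), "q": q, "p_adjusted": min(1.0, p_val)}
        )
    pairwise = pd.DataFrame(rows)

    condition_means = {g: float(m) for g, m in zip(groups, g_means)}
    return ComparisonReport(
        measure=grouped.measure,
        omnibus_test="split-plot two-way ANOVA (ln scale)" if log_transform
        else "split-plot two-way ANOVA",
        statistic=float(table.loc[0, "F"]),
        p_value=float(table.loc[0, "p"]),
        pairwise=pairwise,
        summary=summarize(grouped),
        anova_table=table,
        extra={"condition_means_ln" if log_transform else "condition_means": condition_means,
               "gg_epsilon": eps},
    )
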