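"""Group-level statistics and report tables.

Pooled-variance two-tailed t-tests with Shapiro-Wilk normality checks,
Pearson chi-square on proportions (no continuity correction), type-II
two-way ANOVA, and the plain-text/CSV/JSON report tables that mirror the
pipeline's panel summaries (group mean +/- SEM, test, statistic, p).
No multiple-testing correction is applied; the number of tests run is
reported.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSample",
    "TTestResult",
    "ChiSquareResult",
    "AnovaResult",
    "two_sample_t",
    "chi_square_proportions",
    "two_way_anova",
    "group_table",
    "report",
]


@dataclass
class GroupSample:
    """Per-animal scalar values for one experimental group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in group {self.label!r}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        return float(self.values.std(ddof=1) / np.sqrt(self.n)) if self.n > 1 \
            else float("nan")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    normal_a: bool
    normal_b: bool
    shapiro_p_a: float
    shapiro_p_b: float
    equal_var: bool


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    factor: str
    F: float
    df1: int
    df2: int
    p: float


def two_sample_t(
    a: GroupSample, b: GroupSample, equal_var: bool = True,
    shapiro_alpha: float = 0.05,
) -> TTestResult:
    """Two-tailed two-sample t-test (pooled variance by default).

    Shapiro-Wilk normality is evaluated per group at ``shapiro_alpha`` and
    reported, not enforced.  With pooled variance df = nA + nB - 2.
    """
    if a.n < 3 or b.n < 3:
        raise ValueError("each group needs at least 3 values")
    t, p = sps.ttest_ind(a.values, b.values, equal_var=equal_var)
    if equal_var:
        df = a.n + b.n - 2
    else:  # Welch-Satterthwaite
        va, vb = a.values.var(ddof=1) / a.n, b.values.var(ddof=1) / b.n
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    swa = sps.shapiro(a.values)
    swb = sps.shapiro(b.values)
    return TTestResult(
        t=float(t), df=float(df), p=float(p),
        normal_a=bool(swa.pvalue > shapiro_alpha),
        normal_b=bool(swb.pvalue > shapiro_alpha),
        shapiro_p_a=float(swa.pvalue), shapiro_p_b=float(swb.pvalue),
        equal_var=equal_var,
    )


def chi_square_proportions(
    count_a: int, total_a: int, count_b: int, total_b: int
) -> ChiSquareResult:
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must satisfy 0 <= count <= total")
    table = np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi-square table has a zero margin")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p))


def two_way_anova(
    data: pd.DataFrame,
    response: str = "value",
    group_col: str = "group",
    condition_col: str = "condition",
    interaction: bool = True,
) -> dict[str, AnovaResult]:
    """Two-way ANOVA with type-II sums of squares.

    ``data`` holds one response value per animal x condition.  Returns the F,
    (df1, df2) and p per factor (and interaction), keyed by factor name; df2
    is the residual degrees of freedom.  The group main effect is the
    headline statistic for group x time-course comparisons.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data.rename(
        columns={response: "_y", group_col: "_g", condition_col: "_c"}
    )
    rhs = "C(_g) * C(_c)" if interaction else "C(_g) + C(_c)"
    try:
        model = smf.ols(f"_y ~ {rhs}", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
    except Exception as exc:  # singular design and friends
        raise ValueError(f"ANOVA design could not be fit: {exc}") from exc
    if not np.isfinite(model.mse_resid):
        raise ValueError("singular ANOVA design (no residual degrees of freedom)")
    df2 = int(table.loc["Residual", "df"])
    out: dict[str, AnovaResult] = {}
    names = {"C(_g)": group_col, "C(_c)": condition_col,
             "C(_g):C(_c)": f"{group_col}:{condition_col}"}
    for row, factor in names.items():
        if row not in table.index:
            continue
        out[factor] = AnovaResult(
            factor=factor,
            F=float(table.loc[row, "F"]),
            df1=int(table.loc[row, "df"]),
            df2=df2,
            p=float(table.loc[row, "PR(>F)"]),
        )
    return out


def group_table(samples: Sequence[GroupSample]) -> pd.DataFrame:
    """Mean +/- SEM summary, one row per group."""
    return pd.DataFrame(
        {
            "group": [s.label for s in samples],
            "n": [s.n for s in samples],
            "mean": [s.mean for s in samples],
            "sem": [s.sem for s in samples],
        }
    )


def report(
    stage_outputs: dict[str, Sequence[GroupSample]],
    out_dir=None,
) -> tuple[str, dict]:
    """Assemble the run's panel-style statistics report.

    ``stage_outputs`` maps a measurement name (e.g. "alternation_percent",
    "total_entries", "bouton_density_pct_ctrl") to its group samples.  Each
    measurement yields a group mean +/- SEM table plus a two-group t-test
    line when exactly two groups with n >= 3 are present.  Missing stages
    are listed as absent and the report continues.  Returns (markdown, JSON
    payload); when ``out_dir`` is given, writes report.md, one CSV per
    table and report.json there.
    """
    lines: list[str] = ["# Run report", ""]
    payload: dict = {"measurements": {}, "n_tests": 0, "absent": []}
    for name in sorted(stage_outputs):
        samples = stage_outputs[name]
        if not samples:
            payload["absent"].append(name)
            lines += [f"## {name}", "", "*absent — no data*", ""]
            continue
        tbl = group_table(samples)
        lines += [f"## {name}", "", tbl.to_markdown(index=False), ""]
        entry: dict = {"groups": tbl.to_dict(orient="records")}
        if len(samples) == 2 and all(s.n >= 3 for s in samples):
            res = two_sample_t(samples[0], samples[1])
            payload["n_tests"] += 1
            entry["t_test"] = asdict(res)
            lines.append(
                f"t-test: t({res.df:g}) = {res.t:.3f}, p = {res.p:.4g} "
                f"(Shapiro-Wilk normal: {res.normal_a}/{res.normal_b})"
            )
            lines.append("")
        payload["measurements"][name] = entry
        if out_dir is not None:
            tbl.to_csv(f"{out_dir}/report_{name}.csv", index=False,
                       float_format="%.9g")
    if payload["absent"]:
        lines += ["## Warnings", ""] + [
            f"- stage output absent: {name}" for name in payload["absent"]
        ] + [""]
    lines.append(f"Tests run (uncorrected): {payload['n_tests']}")
    md = "\n".join(lines)
    if out_dir is not None:
        with open(f"{out_dir}/report.md", "w") as fh:
            fh.write(md)
        with open(f"{out_dir}/report.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    return md, payload
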