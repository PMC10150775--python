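"""Rate tables, group comparisons, and ICC(1,k) test-retest reliability.

The reliability endpoint of the study is the weekly interictal HFO rate
(events/min): each post-injection week is one "test", so weeks 1-4 give
k = 4 repeated measurements per animal.  Reliability is the one-way
random-effects intraclass correlation for k-measurement averages,

    ICC(1,k) = (MSB - MSW) / MSB = 1 - 1/F,      F = MSB / MSW,

with MSB/MSW the between/within-subject mean squares of the one-way ANOVA
on the n x k rating matrix, df = (n-1, n(k-1)).  The 95% confidence bounds
follow the standard one-way random-effects F interval

    LB = 1 - 1/(F / F_{0.975; n-1, n(k-1)}),
    UB = 1 - 1/(F * F_{0.975; n(k-1), n-1}).

Interpretation bands: poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent.
Group comparisons use one-way ANOVA and two-sample t-tests (pooled by
default, Welch optional) with Bonferroni correction, reporting group means
with standard errors of the mean (SEM = SD / sqrt(n)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "IccResult",
    "ComparisonResult",
    "build_rate_table",
    "icc_1k",
    "interpret_icc",
    "compare_rates",
    "sem",
    "bonferroni",
    "rate_matrix",
]

_ICC_BANDS = [(0.75, "excellent"), (0.60, "good"), (0.40, "fair")]


def interpret_icc(icc: float) -> str:
    """Reliability band label: poor / fair / good / excellent.

    Boundary values (0.40, 0.60, 0.75) land in the higher band.
    """
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    for lo, label in _ICC_BANDS:
        if icc >= lo:
            return label
    return "poor"


@dataclass
class IccResult:
    """ICC(1,k) point estimate with F-interval confidence bounds.

    Negative estimates are reported as computed (labelled "poor"), not
    truncated at zero.
    """

    icc: float
    lb: float
    ub: float
    F: float
    df1: int
    df2: int
    p: float
    label: str
    n: int
    k: int

    def summary(self) -> str:
        p = "p < 0.001" if self.p < 0.001 else f"p = {self.p:.3f}"
        return (
            f"ICC(1,k) = {self.icc:.2f} [LB = {self.lb:.2f}, UB = {self.ub:.2f}, "
            f"F({self.df1}, {self.df2}) = {self.F:.2f}, {p}] "
            f"-> {self.label} reliability (n = {self.n} subjects, k = {self.k} tests)"
        )

    def to_dict(self) -> dict:
        return {
            "icc": self.icc,
            "lb": self.lb,
            "ub": self.ub,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "label": self.label,
            "n": self.n,
            "k": self.k,
        }


def icc_1k(ratings: np.ndarray, confidence: float = 0.95) -> IccResult:
    """One-way random-effects ICC for k-measurement averages.

    Parameters
    ----------
    ratings : array, shape (n_subjects, k_measurements)
        Rows with any missing value are dropped (listwise), with a warning.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x measurements matrix")
    keep = ~np.isnan(ratings).any(axis=1)
    if not keep.all():
        warnings.warn(f"dropping {(~keep).sum()} subject(s) with missing measurements")
        ratings = ratings[keep]
    n, k = ratings.shape
    if n < 2 or k < 2:
        raise ValueError("ICC(1,k) requires at least 2 subjects and 2 measurements")

    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    ssb = k * float(np.sum((row_means - grand) ** 2))
    ssw = float(np.sum((ratings - row_means[:, None]) ** 2))
    df1, df2 = n - 1, n * (k - 1)
    msb, msw = ssb / df1, ssw / df2
    if msb == 0 and msw == 0:
        raise ZeroDivisionError("undefined ICC: no variance between or within subjects")
    if msw == 0:
        icc, F, p, lb, ub = 1.0, np.inf, 0.0, 1.0, 1.0
    else:
        F = msb / msw
        icc = (msb - msw) / msb
        p = float(sstats.f.sf(F, df1, df2))
        alpha = 1.0 - confidence
        f_up = sstats.f.ppf(1 - alpha / 2, df1, df2)
        f_lo = sstats.f.ppf(1 - alpha / 2, df2, df1)
        lb = 1.0 - 1.0 / (F / f_up)
        ub = 1.0 - 1.0 / (F * f_lo)
    return IccResult(
        icc=float(icc),
        lb=float(lb),
        ub=float(ub),
        F=float(F),
        df1=df1,
        df2=df2,
        p=float(p),
        label=interpret_icc(float(icc)),
        n=n,
        k=k,
    )


def sem(values) -> float:
    """Standard error of the mean, SD/sqrt(n) (ddof=1)."""
    values = np.asarray(values, dtype=float)
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

def build_rate_table(session_counts: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Weekly per-channel event rates from per-session counts.

    Parameters
    ----------
    session_counts : DataFrame
        One row per session x channel with columns
        ``animal, week, channel, region, n_events, minutes`` (analyzable
        minutes, i.e. excluding masked time).
    manifest : DataFrame
        Columns ``animal, group`` mapping each animal to E+/E-.

    Returns one record per animal x week x channel with the pooled weekly
    rate ``sum(events) / sum(minutes)``.  A session whose animal is absent
    from the manifest raises.
    """
    required = {"animal", "week", "channel", "region", "n_events", "minutes"}
    if not required <= set(session_counts.columns):
        raise ValueError(f"session_counts needs columns {sorted(required)}")
    unknown = set(session_counts["animal"]) - set(manifest["animal"])
    if unknown:
        raise KeyError(f"sessions reference animals missing from the manifest: {sorted(unknown)}")
    grouped = (
        session_counts.groupby(["animal", "week", "channel", "region"], as_index=False)
        .agg(n_events=("n_events", "sum"), minutes=("minutes", "sum"))
    )
    grouped["rate_per_min"] = grouped["n_events"] / grouped["minutes"]
    out = grouped.merge(manifest[["animal", "group"]], on="animal", how="left")
    return out[
        ["animal", "group", "week", "channel", "region", "rate_per_min", "n_events", "minutes"]
    ].sort_values(["animal", "week", "channel"], kind="stable").reset_index(drop=True)


def rate_matrix(
    table: pd.DataFrame,
    weeks=(1, 2, 3, 4),
    region: str = "hippocampus",
    subject: str = "animal",
) -> tuple[np.ndarray, list]:
    """Subjects x weeks rating matrix for the ICC, averaging channels within a region.

    Subjects (animals by default) missing any requested week are excluded
    (listwise, as the one-way ANOVA requires a complete matrix).
    """
    sel = table[table["region"] == region] if region else table
    wide = (
        sel.groupby([subject, "week"])["rate_per_min"].mean().unstack("week")
    )
    missing = [w for w in weeks if w not in wide.columns]
    if missing:
        raise ValueError(f"weeks {missing} absent from the rate table")
    wide = wide[list(weeks)].dropna(axis=0, how="any")
    return wide.to_numpy(), wide.index.tolist()


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """ANOVA + pairwise t-tests with Bonferroni adjustment and group summaries."""

    design: str
    anova_F: float
    anova_p: float
    tests: pd.DataFrame  # contrast, t, p_raw, p_adj, n1, n2
    group_stats: pd.DataFrame  # level, n, mean, sem

    def summary(self) -> str:
        lines = [
            f"{self.design} comparison: ANOVA F = {self.anova_F:.2f}, p = {self.anova_p:.4g}",
            self.group_stats.to_string(index=False),
            self.tests.to_string(index=False),
        ]
        return "\n".join(lines)


def _two_sample_t(a, b, equal_var=True):
    res = sstats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def compare_rates(
    table: pd.DataFrame,
    design: str = "between",
    value: str = "rate_per_min",
    equal_var: bool = True,
    bonferroni_correct: bool = True,
) -> ComparisonResult:
    """Group comparisons of event rates.

    design="between": levels are groups (E+ vs E-); one-way ANOVA across
    groups plus all pairwise two-sample t-tests.
    design="within": levels are weeks; each post-injection week is tested
    against the baseline week (week 0) with two-sample t-tests across
    animals, plus an ANOVA across all weeks.

    Levels with fewer than 2 observations are dropped with a warning.
    t-tests are pooled-variance by default (``equal_var=False`` for Welch);
    Bonferroni adjusts within the reported comparison family.
    """
    if design not in ("between", "within"):
        raise ValueError("design must be 'between' or 'within'")
    level_col = "group" if design == "between" else "week"
    groups = {}
    for level, sub in table.groupby(level_col):
        vals = sub[value].to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(f"level {level!r} has < 2 observations; dropped")
            continue
        groups[level] = vals
    if len(groups) < 2:
        raise ValueError("need at least two levels with >= 2 observations")

    levels = sorted(groups)
    F, p_anova = sstats.f_oneway(*[groups[g] for g in levels])

    if design == "between":
        contrasts = list(combinations(levels, 2))
    else:
        base = 0 if 0 in groups else levels[0]
        contrasts = [(base, w) for w in levels if w != base]
    m = len(contrasts)
    rows = []
    for a, b in contrasts:
        t, p = _two_sample_t(groups[a], groups[b], equal_var=equal_var)
        rows.append(
            {
                "contrast": f"{a} vs {b}",
                "t": t,
                "p_raw": p,
                "p_adj": bonferroni(p, m) if bonferroni_correct else p,
                "n1": len(groups[a]),
                "n2": len(groups[b]),
            }
        )
    stats_rows = [
        {"level": g, "n": len(groups[g]), "mean": float(np.mean(groups[g])), "sem": sem(groups[g])}
        for g in levels
    ]
    return ComparisonResult(
        design=design,
        anova_F=float(F),
        anova_p=float(p_anova),
        tests=pd.DataFrame(rows, columns=["contrast", "t", "p_raw", "p_adj", "n1", "n2"]),
        group_stats=pd.DataFrame(stats_rows, columns=["level", "n", "mean", "sem"]),
    )
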