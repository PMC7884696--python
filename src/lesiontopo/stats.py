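"""Small-cohort statistical procedures.

One-sample and paired t-tests (accepting either raw vectors or printed
(mean, SD, n) summaries), Pearson correlation with its t-based p-value,
Sidak's closed-form multiple-comparison adjustment, Benjamini-Hochberg
step-up FDR, and a two-way (group x timepoint) repeated-measures ANOVA with
Sidak post-hoc comparisons. Everything is a pure function: fixed input,
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "one_sample_t",
    "paired_t",
    "pearson_r",
    "sidak_adjust",
    "bh_fdr",
    "rm_anova_sidak",
]


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    estimate: float  # mean difference for t-tests, r for correlations
    n: int
    method: str
    degenerate: bool = False
    notes: dict = field(default_factory=dict)


def one_sample_t(
    values=None,
    mu0: float = 0.0,
    *,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
) -> TestResult:
    """Two-sided one-sample t-test against ``mu0``.

    Pass a raw vector, or a printed summary via ``mean``, ``sd``, ``n`` —
    summary entry makes published mean ± SD tables first-class inputs.
    Zero sample SD yields a degenerate-variance flag instead of a p-value
    of zero (with t = 0, p = 1 when the mean equals ``mu0`` exactly).
    """
    if values is not None:
        x = np.asarray(values, dtype=float)
        x = x[~np.isnan(x)]
        n = x.size
        if n < 2:
            raise ValueError("need n >= 2 observations")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
    else:
        if mean is None or sd is None or n is None:
            raise ValueError("provide raw values or all of mean, sd, n")
        if n < 2:
            raise ValueError("need n >= 2")
        if sd < 0:
            raise ValueError("sd must be >= 0")
    df = n - 1
    diff = mean - mu0
    if sd == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, 0.0, n, "one-sample t", degenerate=True)
        return TestResult(
            np.inf if diff > 0 else -np.inf, df, np.nan, diff, n,
            "one-sample t", degenerate=True,
            notes={"reason": "zero variance with nonzero effect"},
        )
    t = diff / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), float(diff), int(n), "one-sample t")


def paired_t(x, y) -> TestResult:
    """Two-sided paired t-test: one-sample t on (x - y) against zero.

    NaN pairs are dropped and their count reported in ``notes``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    ok = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~ok).sum())
    d = x[ok] - y[ok]
    if d.size < 2:
        raise ValueError("need at least 2 complete pairs")
    res = one_sample_t(d, 0.0)
    res.method = "paired t"
    if dropped:
        res.notes["n_pairs_dropped"] = dropped
    return res


def pearson_r(x, y) -> TestResult:
    """Pearson correlation with a two-sided p-value from
    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        return TestResult(
            np.nan, n - 2, np.nan, np.nan, n, "pearson r", degenerate=True,
            notes={"reason": "zero variance"},
        )
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        return TestResult(np.inf * np.sign(r), df, 0.0, r, n, "pearson r")
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), r, int(n), "pearson r")


def sidak_adjust(p: float | np.ndarray, k: int) -> float | np.ndarray:
    """Sidak's closed form for k comparisons: p_adj = 1 - (1 - p)^k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    p_arr = np.asarray(p, dtype=float)
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = 1.0 - (1.0 - p_arr) ** k
    return float(out) if np.isscalar(p) else out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, set adj_(i) = min_{j >= i} p_(j) * m / j capped at 1,
    and restore the original order. NaNs pass through untouched and do not
    count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = q.size
    if m == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[ok] = restored
    return out


# --------------------------------------------------------------------------
# repeated-measures ANOVA with Sidak post hoc
# --------------------------------------------------------------------------


def _require_balanced(df: pd.DataFrame) -> None:
    cells = df.pivot_table(
        index="subject_id", columns="timepoint_day", values="value", aggfunc="count"
    )
    missing = [
        (str(s), float(t))
        for s in cells.index
        for t in cells.columns
        if pd.isna(cells.loc[s, t]) or cells.loc[s, t] == 0
    ]
    if missing:
        raise ValueError(f"unbalanced design; missing subject x timepoint cells: {missing}")


def rm_anova_sidak(
    outcomes: pd.DataFrame,
    parameter: str,
    limb: str | None = None,
    baseline_timepoint: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way repeated-measures ANOVA (between: group, within: timepoint)
    with Sidak-adjusted pairwise comparisons.

    Post-hoc families: between groups at each timepoint (pooled-variance
    two-sample t, Sidak over the number of timepoints) and each group's
    timepoints against its baseline (paired t, Sidak over the number of
    post-baseline timepoints). Returns ``(anova_table, pairwise_table)``.
    The omnibus fit is delegated to pingouin's mixed/rm ANOVA.
    """
    import pingouin as pg  # deferred: slow import

    df = outcomes.loc[outcomes["parameter"] == parameter].copy()
    if limb is not None:
        df = df.loc[df["limb"] == limb]
    if df.empty:
        raise ValueError(f"no rows for parameter {parameter!r} (limb {limb!r})")
    _require_balanced(df)

    groups = sorted(df["group"].unique())
    timepoints = sorted(df["timepoint_day"].unique())
    if len(timepoints) < 2:
        raise ValueError("need at least 2 timepoints")
    if baseline_timepoint is None:
        baseline_timepoint = timepoints[0]

    if df["value"].nunique() == 1:
        anova = pd.DataFrame(
            {"Source": ["group", "timepoint_day", "Interaction"],
             "F": [np.nan] * 3, "p_unc": [np.nan] * 3, "degenerate": [True] * 3}
        )
    elif len(groups) >= 2:
        anova = pg.mixed_anova(
            data=df, dv="value", within="timepoint_day",
            subject="subject_id", between="group", correction=False,
        )
    else:
        anova = pg.rm_anova(
            data=df, dv="value", within="timepoint_day", subject="subject_id"
        )
    anova = anova.rename(columns={"p-unc": "p_unc"})

    rows = []
    # between-group comparisons at each timepoint
    if len(groups) == 2:
        k = len(timepoints)
        for t in timepoints:
            a = df.loc[(df["group"] == groups[0]) & (df["timepoint_day"] == t), "value"]
            b = df.loc[(df["group"] == groups[1]) & (df["timepoint_day"] == t), "value"]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
                stat, p = 0.0, 1.0
            else:
                stat, p = sps.ttest_ind(a, b, equal_var=True)
            rows.append(
                ("between_groups", f"{groups[0]} vs {groups[1]}", t,
                 float(stat), float(p), float(sidak_adjust(min(float(p), 1.0), k)))
            )
    # within-group comparisons vs baseline
    for g in groups:
        sub = df.loc[df["group"] == g].pivot_table(
            index="subject_id", columns="timepoint_day", values="value"
        )
        post = [t for t in timepoints if t != baseline_timepoint]
        k = len(post)
        for t in post:
            x = sub[t].to_numpy(float)
            y = sub[baseline_timepoint].to_numpy(float)
            d = x - y
            if np.all(d == d[0]):
                stat, p = (0.0, 1.0) if d[0] == 0 else (np.nan, np.nan)
            else:
                res = paired_t(x, y)
                stat, p = res.statistic, res.p_value
            p_adj = float(sidak_adjust(p, k)) if np.isfinite(p) else np.nan
            rows.append(
                ("vs_baseline", g, t, float(stat), float(p), p_adj)
            )
    pairwise = pd.DataFrame(
        rows,
        columns=["family", "comparison", "timepoint_day", "statistic", "p_raw", "p_sidak"],
    )
    return anova, pairwise
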