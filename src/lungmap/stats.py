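"""Cohort statistics: paired/independent comparisons with a Levene variance
gate, correlation screens, group summary tables, and two-sample power.

The comparison rules mirror common clinical-imaging practice: within-cohort
pre/post contrasts use paired t-tests; between-cohort contrasts use
two-tailed independent t-tests, pooling variances only when Levene's test
(classical, mean-centred) does not reject equality at p > 0.05 and falling
back to Welch's test otherwise.  Raw p-values are reported (no multiplicity
correction, matching the source analyses); an optional Benjamini-Hochberg
adjustment is available as a clearly separate extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "paired_comparison",
    "independent_comparison",
    "correlation_screen",
    "adjust_benjamini_hochberg",
    "required_sample_size",
    "build_summary_tables",
]

ALPHA_DEFAULT = 0.05
LEVENE_GATE_P = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, two-sided p, per-group n, the method
    actually used (records the variance-gate outcome), and the point
    estimate (mean difference or correlation coefficient)."""

    statistic: float
    p_value: float
    n: tuple[int, ...]
    method: str
    estimate: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def paired_comparison(values_pre, values_post) -> TestResult:
    """Paired two-sided t-test on matched pre/post measurements.

    Degenerate difference vectors are handled explicitly: all differences
    zero gives statistic 0, p = 1; identical nonzero differences (zero
    variance) are flagged and reported at the machine floor rather than an
    undefined statistic.
    """
    pre = np.asarray(values_pre, dtype=float)
    post = np.asarray(values_post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    if pre.size < 3:
        raise ValueError("need at least 3 matched pairs")
    diff = post - pre
    est = float(diff.mean())
    if diff.std(ddof=1) == 0:
        if est == 0:
            return TestResult(0.0, 1.0, (pre.size,), "paired-t", 0.0,
                              {"degenerate": "all differences zero"})
        return TestResult(
            np.inf if est > 0 else -np.inf,
            float(np.finfo(float).tiny),
            (pre.size,),
            "paired-t",
            est,
            {"degenerate": "zero-variance nonzero differences"},
        )
    t, p = sps.ttest_rel(post, pre)
    return TestResult(float(t), float(p), (pre.size,), "paired-t", est)


def independent_comparison(group_a, group_b, levene_gate_p: float = LEVENE_GATE_P) -> TestResult:
    """Two-tailed independent t-test with a Levene variance gate.

    Levene's test (mean-centred) runs first; if it does not reject equal
    variances (p > gate), the pooled-variance t-test is used, otherwise
    Welch's unequal-variance t-test.  The method label records which path
    was taken.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    lev_stat, lev_p = sps.levene(a, b, center="mean")
    equal_var = bool(lev_p > levene_gate_p)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return TestResult(
        float(t),
        float(p),
        (a.size, b.size),
        "independent-t" if equal_var else "welch-t",
        float(a.mean() - b.mean()),
        {"levene_statistic": float(lev_stat), "levene_p": float(lev_p)},
    )


def correlation_screen(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    method: str = "spearman",
) -> list[TestResult]:
    """Correlation of each (x, y) column pair with pairwise-complete
    deletion; per-test n records how many rows survived.

    Constant columns have no defined correlation and are flagged (NaN
    coefficient) rather than silently dropped.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    corr_fn = sps.spearmanr if method == "spearman" else sps.pearsonr
    results: list[TestResult] = []
    for x_col, y_col in pairs:
        sub = table[[x_col, y_col]].dropna()
        n = len(sub)
        extra = {"x": x_col, "y": y_col, "n_dropped": len(table) - n}
        if n < 4:
            raise ValueError(
                f"pair ({x_col}, {y_col}) has only {n} complete rows (< 4)"
            )
        x, y = sub[x_col].to_numpy(float), sub[y_col].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            extra["flag"] = "constant column: correlation undefined"
            results.append(TestResult(np.nan, np.nan, (n,), method, np.nan, extra))
            continue
        r, p = corr_fn(x, y)
        results.append(TestResult(float(r), float(p), (n,), method, float(r), extra))
    return results


def adjust_benjamini_hochberg(results: list[TestResult]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a batch of results
    (an extension beyond the raw-p reporting; NaNs pass through)."""
    p = np.array([r.p_value for r in results], dtype=float)
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return adj


def _two_sample_power(n: int, d: float, alpha: float) -> float:
    """Exact power of the two-sided two-sample t-test with n per group,
    effect size d, via the noncentral t distribution."""
    df = 2 * n - 2
    nc = d * np.sqrt(n / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def required_sample_size(
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.80,
    method: str = "exact",
) -> int:
    """Smallest per-group n giving the two-sided two-sample t-test at level
    ``alpha`` at least the target power for standardised effect size
    (Cohen's d) ``effect_size``.

    ``method='exact'`` uses the noncentral-t power function with a monotone
    doubling-then-bisection search; ``method='normal'`` uses the classical
    closed-form normal approximation n = 2 (z_{a/2} + z_b)^2 / d^2.  Tiny
    effect sizes demand enormous samples — at d around 0.01 the requirement
    runs into the hundreds of thousands per group.
    """
    if effect_size <= 0:
        raise ValueError("effect size d = 0 needs an infinite sample; d must be > 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not alpha < power < 1:
        raise ValueError("power must lie in (alpha, 1)")
    if method == "normal":
        z = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(power)
        return int(np.ceil(2.0 * (z / effect_size) ** 2))
    if method != "exact":
        raise ValueError("method must be 'exact' or 'normal'")
    lo, hi = 2, 2
    while _two_sample_power(hi, effect_size, alpha) < power:
        lo, hi = hi, hi * 2
        if hi > 10**9:
            raise ValueError("required sample size exceeds 1e9 per group")
    while lo < hi:
        mid = (lo + hi) // 2
        if _two_sample_power(mid, effect_size, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def _fmt(mean: float, sd: float) -> str:
    return f"{mean:.2f} ({sd:.2f})"


def build_summary_tables(
    table: pd.DataFrame,
    metrics: list[str] | None = None,
    subject_col: str = "subject",
    group_col: str = "group",
    timepoint_col: str = "timepoint",
) -> pd.DataFrame:
    """Cohort comparison report: per-metric means (SD) for controls, the
    exposed group pre and post, with the three contrasts — control vs pre
    and control vs post (independent, Levene-gated) and pre vs post (paired,
    matched by subject).

    Expects a tidy table with one row per subject per timepoint; controls
    carry timepoint 'single', the exposed group 'pre' and 'post'.
    """
    required = {subject_col, group_col, timepoint_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if metrics is None:
        skip = required | {"sex", "nicotine_type"}
        metrics = [c for c in table.columns
                   if c not in skip and pd.api.types.is_numeric_dtype(table[c])]

    controls = table[table[timepoint_col] == "single"]
    pre = table[table[timepoint_col] == "pre"].sort_values(subject_col)
    post = table[table[timepoint_col] == "post"].sort_values(subject_col)
    if controls.empty or pre.empty or post.empty:
        raise ValueError("summary needs non-empty control, pre and post groups")
    if not pre[subject_col].tolist() == post[subject_col].tolist():
        raise ValueError("pre and post rows are not matched by subject")

    rows = []
    for m in metrics:
        c = controls[m].dropna().to_numpy(float)
        a = pre[m].to_numpy(float)
        b = post[m].to_numpy(float)
        paired_ok = np.isfinite(a) & np.isfinite(b)
        row = {
            "metric": m,
            "control_mean": c.mean() if c.size else np.nan,
            "control_sd": c.std(ddof=1) if c.size > 1 else np.nan,
            "pre_mean": np.nanmean(a),
            "pre_sd": np.nanstd(a, ddof=1),
            "post_mean": np.nanmean(b),
            "post_sd": np.nanstd(b, ddof=1),
        }
        row["control"] = _fmt(row["control_mean"], row["control_sd"])
        row["pre"] = _fmt(row["pre_mean"], row["pre_sd"])
        row["post"] = _fmt(row["post_mean"], row["post_sd"])
        try:
            r1 = independent_comparison(c, a[np.isfinite(a)])
            row["p_control_vs_pre"] = r1.p_value
            row["method_control_vs_pre"] = r1.method
        except ValueError:
            row["p_control_vs_pre"] = np.nan
        try:
            r2 = independent_comparison(c, b[np.isfinite(b)])
            row["p_control_vs_post"] = r2.p_value
            row["method_control_vs_post"] = r2.method
        except ValueError:
            row["p_control_vs_post"] = np.nan
        try:
            r3 = paired_comparison(a[paired_ok], b[paired_ok])
            row["p_pre_vs_post"] = r3.p_value
        except ValueError:
            row["p_pre_vs_post"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
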