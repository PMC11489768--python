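"""Normality-gated statistical battery.

Every group comparison is gated by a Shapiro-Wilk normality test on the
pooled residuals: when the residuals look Gaussian (p >= 0.05) a
parametric test is used (Welch two-sample t / one-sample t vs zero);
otherwise the nonparametric counterpart (Wilcoxon rank-sum with
continuity correction / Wilcoxon signed-rank). Omnibus comparisons of
k > 2 groups use a Kruskal-Wallis test followed by pairwise rank-sum
tests with Holm correction. All tests are two-sided.

The Wilcoxon rank-sum p-value is exact (full enumeration of label
assignments, midranks under ties) for small samples, and otherwise uses
the normal approximation with continuity correction. The reported W
statistic follows the rank-sum-minus-minimum convention of the first
sample (the Mann-Whitney U of sample 1), matching R's wilcox.test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "adjust_pvalues",
    "rank_sum_test",
    "normality_gated_compare",
    "mixed_anova",
]

GATE_ALPHA = 0.05
#: exact rank-sum enumeration is used up to this combined sample size
EXACT_RANKSUM_MAX_N = 14


@dataclass
class TestResult:
    """One statistical test in the battery's reporting format."""

    test_name: str
    statistic_symbol: str  # W, t, F or chi-squared
    statistic: float
    p: float
    group_sizes: tuple[int, ...]
    p_adjusted: float | None = None
    adjust_method: str | None = None
    two_sided: bool = True
    shapiro_w: float | None = None
    shapiro_p: float | None = None
    label: str = ""
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "test": self.test_name,
            "factor": self.label,
            "statistic": self.statistic_symbol,
            "value": self.statistic,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
        }


def adjust_pvalues(p: list[float] | np.ndarray, method: str = "holm") -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg ("bh") step-up adjustment.

    Order-preserving against the input indexing; adjusted values are
    clipped at 1 and never below the raw p.
    """
    p = np.asarray(p, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("expected a non-empty 1-D list of p-values")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"holm": "holm", "bh": "fdr_bh"}
    if method not in key:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key[method])[1]


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of label
    assignments; ties handled with midranks."""
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1, n = len(x), len(pooled)
    obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    dev = abs(obs - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
            count += 1
    return count / total


def rank_sum_test(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for combined samples up to 14 observations
    (midranks under ties); larger samples use the normal approximation
    with continuity correction and tie-corrected variance.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    ranks = _midranks(np.concatenate([x, y]))
    w = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0  # Mann-Whitney U of x
    if n1 + n2 <= EXACT_RANKSUM_MAX_N:
        p = _exact_ranksum_p(x, y)
        method = "exact enumeration"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        method = "normal approximation with continuity correction"
    return TestResult(
        test_name="Wilcoxon rank sum test",
        statistic_symbol="W",
        statistic=float(w),
        p=float(min(p, 1.0)),
        group_sizes=(n1, n2),
        extra={"method": method, "U": float(w)},
    )


def _shapiro_gate(groups: list[np.ndarray]) -> tuple[float, float, bool]:
    """Shapiro-Wilk on pooled within-group-centered residuals.

    Returns (W, p, normal) where normal means the parametric branch is
    taken (p >= GATE_ALPHA).
    """
    residuals = np.concatenate([g - g.mean() for g in groups])
    if np.ptp(residuals) == 0:
        # degenerate: all residuals identical; Shapiro undefined, treat
        # as non-normal so the rank test (robust to ties) is used
        return np.nan, 0.0, False
    w, p = sps.shapiro(residuals)
    return float(w), float(p), p >= GATE_ALPHA


def normality_gated_compare(
    groups: list,
    design: str = "two_sample",
    labels: list[str] | None = None,
) -> list[TestResult]:
    """The battery's gated comparison engine.

    - ``two_sample``: Shapiro gate, then Welch t or Wilcoxon rank-sum.
    - ``one_sample_vs_zero``: each sample against 0; gate, then
      one-sample t or Wilcoxon signed-rank.
    - ``k_sample``: Kruskal-Wallis omnibus, then pairwise rank-sum tests
      with Holm correction.

    Returns the list of results (the gate's W and p are attached to each).
    """
    arrays = [np.asarray(g, float) for g in groups]
    if any(len(a) < 3 for a in arrays):
        raise ValueError("each sample needs n >= 3")
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]

    if design == "two_sample":
        if len(arrays) != 2:
            raise ValueError("two_sample design needs exactly 2 groups")
        w, p_gate, normal = _shapiro_gate(arrays)
        if normal:
            t, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=False)
            res = TestResult(
                test_name="Welch Two Sample t-test",
                statistic_symbol="t",
                statistic=float(t),
                p=float(p),
                group_sizes=(len(arrays[0]), len(arrays[1])),
                label=f"{labels[0]} vs {labels[1]}",
            )
        else:
            res = rank_sum_test(arrays[0], arrays[1])
            res.test_name = "Wilcoxon rank sum test with continuity correction"
            res.label = f"{labels[0]} vs {labels[1]}"
        res.shapiro_w, res.shapiro_p = w, p_gate
        return [res]

    if design == "one_sample_vs_zero":
        out = []
        for a, lab in zip(arrays, labels):
            w, p_gate, normal = _shapiro_gate([a])
            if normal:
                t, p = sps.ttest_1samp(a, 0.0)
                res = TestResult(
                    test_name="One Sample t test",
                    statistic_symbol="t",
                    statistic=float(t),
                    p=float(p),
                    group_sizes=(len(a),),
                    label=f"{lab} difference from 0",
                )
            else:
                if np.all(a == 0):
                    res = TestResult(
                        test_name="Wilcoxon signed rank test",
                        statistic_symbol="V",
                        statistic=0.0,
                        p=1.0,
                        group_sizes=(len(a),),
                        label=f"{lab} difference from 0",
                    )
                else:
                    v, p = sps.wilcoxon(a)
                    res = TestResult(
                        test_name="Wilcoxon signed rank test",
                        statistic_symbol="V",
                        statistic=float(v),
                        p=float(p),
                        group_sizes=(len(a),),
                        label=f"{lab} difference from 0",
                    )
            res.shapiro_w, res.shapiro_p = w, p_gate
            out.append(res)
        return out

    if design == "k_sample":
        if len(arrays) < 3:
            raise ValueError("k_sample design needs at least 3 groups")
        h, p = sps.kruskal(*arrays)
        omnibus = TestResult(
            test_name="Kruskal-Wallis rank sum test",
            statistic_symbol="chi-squared",
            statistic=float(h),
            p=float(p),
            group_sizes=tuple(len(a) for a in arrays),
            label="all groups",
        )
        pairwise = []
        for (i, a), (j, b) in itertools.combinations(enumerate(arrays), 2):
            res = rank_sum_test(a, b)
            res.test_name = "Wilcoxon rank sum test with continuity correction"
            res.label = f"{labels[i]} vs {labels[j]}"
            pairwise.append(res)
        adj = adjust_pvalues([r.p for r in pairwise], method="holm")
        for r, pa in zip(pairwise, adj):
            r.p_adjusted = float(pa)
            r.adjust_method = "holm"
        return [omnibus, *pairwise]

    raise ValueError(f"unknown design {design!r}")


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str,
) -> list[TestResult]:
    """Two-way mixed (split-plot) ANOVA.

    One between-subject factor (treatment group) and one within-subject
    factor (e.g. test-solution concentration), each subject measured at
    every within level. Returns F and p for the between main effect
    (against the subjects-within-groups error), the within main effect
    and the interaction (both against the subject-by-within residual).
    Uncorrected p-values; group sizes may be unequal, but every subject
    must be complete over the within levels (missing cells rejected).
    Degenerate zero-variance effects report F = 0, p = 1; a nonzero
    effect over a zero error term reports F = inf, p = 0.
    """
    counts = data.groupby(subject)[within].nunique()
    n_levels = data[within].nunique()
    if (counts != n_levels).any() or data.groupby([subject, within]).size().max() > 1:
        raise ValueError("each subject needs exactly one observation per within level")

    wide = data.pivot_table(index=subject, columns=within, values=dv)
    group_of = data.drop_duplicates(subject).set_index(subject)[between]
    y = wide.to_numpy(float)
    groups = group_of.reindex(wide.index).to_numpy()
    glabels = np.unique(groups)
    a, b = len(glabels), n_levels
    n_subj = len(wide)

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    group_mean = {g: subj_mean[groups == g].mean() for g in glabels}
    within_mean = y.mean(axis=0)
    n_g = {g: int((groups == g).sum()) for g in glabels}

    ss_between = b * sum(n_g[g] * (group_mean[g] - grand) ** 2 for g in glabels)
    ss_subj = b * sum(
        (subj_mean[s] - group_mean[groups[s]]) ** 2 for s in range(n_subj)
    )
    ss_within = n_subj * np.sum((within_mean - grand) ** 2)
    cell_mean = {g: y[groups == g].mean(axis=0) for g in glabels}
    ss_inter = sum(
        n_g[g] * np.sum((cell_mean[g] - group_mean[g] - within_mean + grand) ** 2)
        for g in glabels
    )
    ss_err = sum(
        np.sum(
            (y[s] - subj_mean[s] - cell_mean[groups[s]] + group_mean[groups[s]]) ** 2
        )
        for s in range(n_subj)
    )

    df_between, df_subj = a - 1, n_subj - a
    df_within = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = (n_subj - a) * (b - 1)

    def f_and_p(ss_num: float, df_num: int, ss_den: float, df_den: int, scale: float):
        tol = 1e-12 * max(scale, 1.0)
        if ss_num <= tol:
            return 0.0, 1.0
        if ss_den <= tol:
            return np.inf, 0.0
        f = (ss_num / df_num) / (ss_den / df_den)
        return float(f), float(sps.f.sf(f, df_num, df_den))

    scale = float(np.sum((y - grand) ** 2))
    rows = [
        (f"{between} (between subj)", ss_between, df_between, ss_subj, df_subj),
        (f"{within} (within subjects)", ss_within, df_within, ss_err, df_err),
        ("Interaction", ss_inter, df_inter, ss_err, df_err),
    ]
    out = []
    for label, ss_n, df_n, ss_d, df_d in rows:
        f, p = f_and_p(ss_n, df_n, ss_d, df_d, scale)
        out.append(
            TestResult(
                test_name="Two-way mixed ANOVA",
                statistic_symbol="F",
                statistic=f,
                p=p,
                group_sizes=(n_subj, n_levels),
                label=label,
                extra={"SS": ss_n, "DF1": df_n, "DF2": df_d},
            )
        )
    return out
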