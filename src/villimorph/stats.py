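"""Trial statistics: normality-routed comparisons, CIs and correlations.

The analysis plan this module implements, per HIV stratum and measured
variable, on an intention-to-treat basis:

* Shapiro–Wilk decides the route: normally distributed variables go to a
  two-tailed (pooled) two-sample t-test with a Student-t 95% CI of the
  mean difference; non-normal variables go to Kruskal–Wallis plus a
  Hodges–Lehmann median-difference estimate with a Mann–Whitney-inversion
  95% CI.
* Paired pre/post data use the paired t-test and Wilcoxon signed rank.
* Spearman correlation matrices over the five morphometric measures with
  conventional significance flags (* p<0.05, ** p<0.01).
* Fisher's exact test for 2×2 baseline tables; percent differences and
  villous:crypt ratios for reporting.
* When both a pre- and a post-vaccination dataset exist, the more
  conservative one (larger p on the primary variable, villous height) is
  selected en bloc.

No multiplicity adjustment is applied by default (a Holm option exists).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohortsim import MEASURES

__all__ = [
    "ComparisonResult",
    "CorrelationTable",
    "shapiro_wilk",
    "two_sample_t",
    "two_sample_t_from_summary",
    "kruskal_wallis",
    "median_difference",
    "paired_tests",
    "spearman_matrix",
    "fisher_exact_2x2",
    "percent_difference",
    "vc_ratio",
    "route_and_compare",
    "select_conservative",
    "holm_adjust",
]


@dataclass
class ComparisonResult:
    """One group comparison: estimate, 95% CI, test statistic and p-value.

    ``estimate`` is a mean difference (t route) or Hodges–Lehmann median
    difference (rank route), in the variable's units.
    """

    variable: str
    stratum: str
    test_name: str
    estimate: float
    ci95: tuple[float, float] | None
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.ci95 is not None and self.test_name.endswith("t test"):
            lo, hi = self.ci95
            if not lo <= self.estimate <= hi:
                raise ValueError("mean-difference CI must bracket the estimate")

    def key(self) -> tuple[str, str]:
        return (self.variable, self.stratum)


def _flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationTable:
    """Spearman ρ among the five measures with significance flags."""

    variables: tuple[str, ...]
    rho: np.ndarray
    p_values: np.ndarray
    n: int

    def flags(self) -> np.ndarray:
        out = np.empty(self.rho.shape, dtype=object)
        for i in range(len(self.variables)):
            for j in range(len(self.variables)):
                out[i, j] = "" if i == j else _flag(self.p_values[i, j])
        return out

    def to_text(self) -> str:
        """Lower-triangular rendering in the conventional table layout."""
        flags = self.flags()
        lines = ["\t" + "\t".join(self.variables)]
        for i, vi in enumerate(self.variables):
            cells = []
            for j in range(i + 1):
                r = self.rho[i, j]
                cell = "1.000" if i == j else f"{r:.3f}{flags[i, j]}"
                cells.append(cell)
            lines.append(vi + "\t" + "\t".join(cells))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# single tests
# ---------------------------------------------------------------------------

def shapiro_wilk(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro–Wilk W, p, and the normality routing flag at ``alpha``."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 3:
        raise ValueError(f"Shapiro–Wilk needs n >= 3, got {len(x)}")
    if len(x) > 5000:
        raise ValueError(f"Shapiro–Wilk supports n <= 5000, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p >= alpha)


def two_sample_t(
    a,
    b,
    variable: str = "",
    stratum: str = "",
    welch: bool = False,
    conf_level: float = 0.95,
) -> ComparisonResult:
    """Two-tailed two-sample t-test with CI of the mean difference.

    Pooled-variance Student's t by default (``welch=True`` switches to
    Welch–Satterthwaite degrees of freedom).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs n >= 2, got {n1} and {n2}")
    return two_sample_t_from_summary(
        a.mean(), a.std(ddof=1), n1, b.mean(), b.std(ddof=1), n2,
        variable=variable, stratum=stratum, welch=welch, conf_level=conf_level,
    )


def two_sample_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variable: str = "",
    stratum: str = "",
    welch: bool = False,
    conf_level: float = 0.95,
) -> ComparisonResult:
    """t-test from group summaries (mean, SD, n) — e.g. published tables."""
    if n1 < 2 or n2 < 2:
        raise ValueError(f"each group needs n >= 2, got {n1} and {n2}")
    diff = mean1 - mean2
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        se = math.sqrt(v1 + v2)
        if se == 0:
            raise ValueError("zero variance in both groups; t undefined")
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        name = "Welch t test"
    else:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        if sp2 == 0:
            raise ValueError("zero pooled variance; t undefined")
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        name = "2-tailed t test"
    t = diff / se
    p = 2 * sps.t.sf(abs(t), df)
    tq = sps.t.ppf(0.5 + conf_level / 2, df)
    return ComparisonResult(
        variable=variable,
        stratum=stratum,
        test_name=name,
        estimate=diff,
        ci95=(diff - tq * se, diff + tq * se),
        statistic=float(t),
        p_value=float(min(1.0, p)) if p > 0 else np.nextafter(0, 1),
        n_per_group=(n1, n2),
    )


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis rank test with tie correction; chi-square p, k-1 df.

    All values identical across all groups gives (H=0, p=1) rather than
    an error.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    arrays = [g[~np.isnan(g)] for g in arrays]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in arrays):
        raise ValueError("each group needs at least one observation")
    if sum(len(g) for g in arrays) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _mann_whitney_u_cdf(n: int, m: int) -> np.ndarray:
    """Exact null CDF of the Mann–Whitney U statistic (no ties).

    Classic convolution: U = number of (a, b) pairs with a > b; each of
    the m "b" items contributes 0..n.  Returns the CDF over u = 0..n·m.
    """
    counts = np.array([1.0])
    for _ in range(m):
        new = np.zeros(len(counts) + n)
        for shift in range(n + 1):
            new[shift : shift + len(counts)] += counts
        counts = new
    return np.cumsum(counts) / counts.sum()


def median_difference(
    a, b, conf_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Hodges–Lehmann shift estimate a−b with a Mann–Whitney-inversion CI.

    The estimate is the median of all n·m pairwise differences; the CI
    takes order statistics of those differences at the exact Mann–Whitney
    critical rank (normal approximation beyond n·m = 10000).  Degenerate
    sample sizes fall back to the full range of pairwise differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n, m = len(a), len(b)
    if n < 1 or m < 1:
        raise ValueError(f"each group needs n >= 1, got {n} and {m}")
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    estimate = float(np.median(diffs))
    alpha = 1 - conf_level
    if n * m <= 10_000:
        cdf = _mann_whitney_u_cdf(n, m)
        ks = np.nonzero(cdf <= alpha / 2)[0]
        k = int(ks.max()) if len(ks) else -1
    else:
        mu = n * m / 2
        sigma = math.sqrt(n * m * (n + m + 1) / 12)
        k = int(math.floor(mu + sps.norm.ppf(alpha / 2) * sigma - 0.5))
    if k < 0:
        lo, hi = float(diffs[0]), float(diffs[-1])
    else:
        lo, hi = float(diffs[k + 1 - 1]), float(diffs[n * m - k - 1])
    return estimate, (lo, hi)


def paired_tests(
    pre,
    post,
    variable: str = "",
    stratum: str = "",
    zero_method: str = "wilcox",
) -> tuple[ComparisonResult, ComparisonResult]:
    """Paired t-test and Wilcoxon signed-rank on pre/post vectors.

    Zero differences are dropped for the Wilcoxon by default
    (``zero_method="pratt"`` keeps them in the ranking).  All-zero
    differences report p = 1 for both tests rather than erroring.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    keep = ~(np.isnan(pre) | np.isnan(post))
    pre, post = pre[keep], post[keep]
    if len(pre) < 2:
        raise ValueError(f"paired tests need n >= 2 pairs, got {len(pre)}")
    d = post - pre
    n = len(d)
    if np.ptp(d) == 0 and d[0] == 0:
        t_res = ComparisonResult(
            variable, stratum, "paired t test", 0.0, (0.0, 0.0), 0.0, 1.0, (n, n)
        )
        w_res = ComparisonResult(
            variable, stratum, "Wilcoxon signed rank", 0.0, None, 0.0, 1.0, (n, n)
        )
        return t_res, w_res
    if np.ptp(d) == 0:  # constant nonzero difference: t undefined (0 variance)
        raise ValueError("zero variance of paired differences; paired t undefined")
    t_stat, t_p = sps.ttest_rel(post, pre)
    se = d.std(ddof=1) / math.sqrt(n)
    tq = sps.t.ppf(0.975, n - 1)
    t_res = ComparisonResult(
        variable, stratum, "paired t test",
        float(d.mean()), (float(d.mean() - tq * se), float(d.mean() + tq * se)),
        float(t_stat), float(t_p), (n, n),
    )
    nz = d[d != 0]
    if len(nz) == 0:
        w_res = ComparisonResult(
            variable, stratum, "Wilcoxon signed rank", 0.0, None, 0.0, 1.0, (n, n)
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # small-n exact/approx notices
            w_stat, w_p = sps.wilcoxon(post, pre, zero_method=zero_method)
        w_res = ComparisonResult(
            variable, stratum, "Wilcoxon signed rank",
            float(np.median(d)), None, float(w_stat), float(w_p), (n, n),
        )
    return t_res, w_res


def spearman_matrix(
    records: pd.DataFrame,
    stratum: str = "all",
    variables: tuple[str, ...] = MEASURES,
) -> CorrelationTable:
    """Pairwise Spearman ρ over the measured variables with flags.

    Requires at least 4 complete records.  A constant variable gets NaN ρ
    for its pairs (flagged undefined rather than erroring).
    """
    df = records.loc[:, list(variables)].dropna()
    n = len(df)
    if n < 4:
        raise ValueError(f"need >= 4 complete records, got {n}")
    k = len(variables)
    rho = np.eye(k)
    pvals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = df.iloc[:, i], df.iloc[:, j]
            if xi.nunique() == 1 or xj.nunique() == 1:
                r, p = float("nan"), float("nan")
            else:
                r, p = sps.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    return CorrelationTable(variables=tuple(variables), rho=rho, p_values=pvals, n=n)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2×2 table (hypergeometric sum)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"table must be 2x2, got shape {t.shape}")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be nonnegative integers")
        t = t.astype(int)
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def percent_difference(treated: float, control: float) -> float:
    """(treated − control) / control × 100, to one decimal place."""
    if control == 0:
        raise ValueError("control value must be nonzero")
    return round((treated - control) / control * 100.0, 1)


def vc_ratio(vh_values, cd_values, groups=None):
    """Per-patient villous:crypt ratios, optionally compared between arms.

    Patients with CD = 0 are excluded with a warning.  With ``groups``
    (a label per patient, two levels), also returns the two-sample t
    comparison of the ratios.
    """
    vh = np.asarray(vh_values, dtype=float)
    cd = np.asarray(cd_values, dtype=float)
    if vh.shape != cd.shape:
        raise ValueError("VH and CD must be paired per patient")
    ok = cd > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} patient(s) with zero crypt depth",
            stacklevel=2,
        )
    ratios = vh[ok] / cd[ok]
    if groups is None:
        return ratios
    g = np.asarray(groups)[ok]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    cmp = two_sample_t(ratios[g == levels[0]], ratios[g == levels[1]],
                       variable="VC_ratio")
    return ratios, cmp


# ---------------------------------------------------------------------------
# routed cohort analysis
# ---------------------------------------------------------------------------

def route_and_compare(
    data: pd.DataFrame,
    timepoint: str = "pre",
    variables: tuple[str, ...] = MEASURES,
    alpha_normality: float = 0.05,
    welch: bool = False,
    holm: bool = False,
    arms: tuple[str, str] = ("MM", "placebo"),
) -> list[ComparisonResult]:
    """Intention-to-treat comparisons per HIV stratum and variable.

    All randomised participants with adequate sections are analysed in
    their assigned arm.  Per variable, a Shapiro–Wilk test on the
    arm-centred residuals pooled within the stratum (centring removes the
    group shift, pooling gives the normality screen usable power at trial
    sizes) routes to the pooled t-test (normal) or to Kruskal–Wallis with
    a Hodges–Lehmann median difference (non-normal).  Strata with < 2
    adequate participants in either arm are skipped with a notice.
    ``holm=True`` applies a Holm step-down adjustment across the returned
    p-values (off by default).
    """
    if "arm" not in data.columns:
        raise ValueError("data has no 'arm' column: unblind the cohort first")
    df = data[(data["timepoint"] == timepoint) & data["adequate"]]
    results: list[ComparisonResult] = []
    for stratum in ("negative", "positive"):
        sub = df[df["hiv"] == stratum]
        ga = sub[sub["arm"] == arms[0]]
        gb = sub[sub["arm"] == arms[1]]
        if len(ga) < 2 or len(gb) < 2:
            warnings.warn(
                f"HIV {stratum}: fewer than 2 adequate participants per arm "
                f"({len(ga)} vs {len(gb)}); comparisons skipped",
                stacklevel=2,
            )
            continue
        for var in variables:
            a = ga[var].to_numpy(dtype=float)
            b = gb[var].to_numpy(dtype=float)
            residuals = np.concatenate([a - np.nanmean(a), b - np.nanmean(b)])
            normal = shapiro_wilk(residuals, alpha_normality)[2]
            if normal:
                res = two_sample_t(a, b, variable=var, stratum=stratum, welch=welch)
            else:
                h, p = kruskal_wallis([a, b])
                est, ci = median_difference(a, b)
                res = ComparisonResult(
                    variable=var,
                    stratum=stratum,
                    test_name="Kruskal-Wallis",
                    estimate=est,
                    ci95=ci,
                    statistic=h,
                    p_value=p,
                    n_per_group=(len(a), len(b)),
                )
            results.append(res)
    if holm:
        holm_adjust(results)
    return results


def holm_adjust(results: list[ComparisonResult]) -> None:
    """Holm step-down adjustment of p-values, in place."""
    order = np.argsort([r.p_value for r in results])
    m = len(results)
    running = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * results[idx].p_value)
        running = max(running, adj)
        results[idx].p_value = running


def select_conservative(
    results_pre: list[ComparisonResult],
    results_post: list[ComparisonResult],
    primary_variable: str = "VH",
    primary_stratum: str = "negative",
) -> tuple[list[ComparisonResult], str]:
    """Choose the more conservative of two complete result sets.

    The pre- and post-vaccination datasets must cover identical
    comparisons; the set whose primary-variable effect has the larger
    p-value is selected *en bloc* (no per-variable cherry-picking).
    Ties select the pre-vaccination set.
    """
    keys_pre = {r.key() for r in results_pre}
    keys_post = {r.key() for r in results_post}
    if keys_pre != keys_post:
        raise ValueError(
            f"result sets cover different comparisons: "
            f"{sorted(keys_pre ^ keys_post)}"
        )

    def primary_p(results: list[ComparisonResult]) -> float:
        for r in results:
            if r.key() == (primary_variable, primary_stratum):
                return r.p_value
        raise ValueError(
            f"primary comparison ({primary_variable}, {primary_stratum}) missing"
        )

    if primary_p(results_post) > primary_p(results_pre):
        return results_post, "post"
    return results_pre, "pre"
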