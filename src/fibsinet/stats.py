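"""Group-level and paired statistical tests used across the pipeline.

The battery covers: Fisher's exact test on 2x2 proportion tables;
heteroscedasticity-robust omnibus comparisons (Welch's ANOVA and the
Brown–Forsythe ANOVA) with Games–Howell post-hoc pairs; Kruskal–Wallis
with Dunn's post-hoc (Bonferroni-adjusted); Mann–Whitney; and paired
designs (paired t, Wilcoxon signed rank, and a two-way repeated-measures
/ mixed ANOVA with Sidak-adjusted planned contrasts). A D'Agostino–
Pearson normality check is provided as an advisory only — it never
switches tests automatically.

Simple univariate tests delegate to scipy.stats; Welch/Brown–Forsythe
ANOVA, Games–Howell and Dunn are computed from their closed forms here
(the studentized-range distribution comes from scipy), and the mixed
ANOVA table is fit with pingouin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "ComparisonResult",
    "fisher_exact_2x2",
    "omnibus_compare",
    "paired_compare",
    "mann_whitney",
    "normality_advisory",
]


@dataclass
class ContingencyTable2x2:
    """Counts with rows = condition, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in vals):
            raise ValueError("counts must be non-negative integers")
        if sum(vals) == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class ComparisonResult:
    """Uniform container for a test result plus optional post-hoc table."""

    test: str
    statistic: float
    df: tuple | float | None
    p: float
    posthoc: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


def fisher_exact_2x2(table) -> ComparisonResult:
    """Fisher's exact test on a 2x2 table.

    Two-sided p by the point-probability rule (sum of all tables with the
    observed margins whose hypergeometric probability does not exceed the
    observed table's); one-sided p-values and the odds ratio are attached
    in ``extra``.
    """
    if isinstance(table, ContingencyTable2x2):
        arr = table.as_array()
    else:
        arr = np.asarray(table, dtype=int)
        ContingencyTable2x2(*arr.ravel().tolist())  # validates
    odds, p_two = sps.fisher_exact(arr, alternative="two-sided")
    _, p_less = sps.fisher_exact(arr, alternative="less")
    _, p_greater = sps.fisher_exact(arr, alternative="greater")
    return ComparisonResult(
        test="fisher_exact",
        statistic=float(odds),
        df=None,
        p=float(p_two),
        extra={"odds_ratio": float(odds), "p_less": float(p_less),
               "p_greater": float(p_greater)},
    )


def _group_stats(groups):
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n = np.array([len(g) for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    return groups, n, m, v


def welch_anova_stat(groups):
    """Welch's heteroscedastic one-way ANOVA (W statistic, df pair, p)."""
    groups, n, m, v = _group_stats(groups)
    flags = []
    if np.any(v == 0):
        flags.append("zero_variance_group")
        v = np.maximum(v, 1e-12)
    w = n / v
    mw = (w * m).sum() / w.sum()
    k = len(groups)
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = (3.0 / (k * k - 1.0)) * ((1.0 - w / w.sum()) ** 2 / (n - 1)).sum()
    W = num / (1.0 + 2.0 * lam * (k - 2) / 3.0)
    df2 = 1.0 / lam
    p = sps.f.sf(W, k - 1, df2)
    return float(W), (k - 1.0, float(df2)), float(p), flags


def brown_forsythe_anova_stat(groups):
    """Brown–Forsythe ANOVA on means (F* with variance-weighted denominator)."""
    groups, n, m, v = _group_stats(groups)
    N = n.sum()
    grand = np.concatenate(groups).mean()
    num = (n * (m - grand) ** 2).sum()
    c = (1.0 - n / N) * v
    den = c.sum()
    F = num / den
    # Satterthwaite denominator df
    df2 = den**2 / ((c**2 / (n - 1)).sum())
    k = len(groups)
    p = sps.f.sf(F, k - 1, df2)
    return float(F), (k - 1.0, float(df2)), float(p), []


def games_howell_posthoc(groups, names=None) -> pd.DataFrame:
    """Games–Howell all-pairs comparisons for unequal variances.

    Uses Welch–Satterthwaite degrees of freedom per pair and the
    studentized-range distribution (q = |t|·sqrt(2)) for the adjusted
    p-value.
    """
    groups, n, m, v = _group_stats(groups)
    k = len(groups)
    names = names or [f"g{i}" for i in range(k)]
    rows = []
    for i, j in combinations(range(k), 2):
        se2 = v[i] / n[i] + v[j] / n[j]
        se2 = max(se2, 1e-300)
        t = (m[i] - m[j]) / np.sqrt(se2)
        df = se2**2 / ((v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1))
        q = abs(t) * np.sqrt(2.0)
        p = sps.studentized_range.sf(q, k, df)
        rows.append({"A": names[i], "B": names[j], "statistic": float(t),
                     "df": float(df), "p_adjusted": float(np.clip(p, 0, 1))})
    return pd.DataFrame(rows)


def dunn_posthoc(groups, names=None, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based all-pairs test after Kruskal–Wallis.

    Z statistics from pooled mean ranks with a tie correction;
    Bonferroni adjustment over the number of pairs (the conventional
    choice when the correction is not stated).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    names = names or [f"g{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (N - 1))
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = np.array([rg.mean() for rg in rank_groups])
    n = np.array([len(g) for g in groups], dtype=float)
    m_pairs = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt((N * (N + 1) / 12.0 - tie) * (1.0 / n[i] + 1.0 / n[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(p_raw * m_pairs, 1.0) if adjust == "bonferroni" else p_raw
        rows.append({"A": names[i], "B": names[j], "statistic": float(z),
                     "p_raw": float(p_raw), "p_adjusted": float(p_adj)})
    return pd.DataFrame(rows)


def omnibus_compare(groups, family: str, names=None,
                    posthoc: bool = True) -> ComparisonResult:
    """Omnibus k-group comparison with the matching post-hoc battery.

    ``family`` is one of ``welch_anova``, ``brown_forsythe`` (each with
    Games–Howell pairs) or ``kruskal_wallis`` (with Bonferroni-adjusted
    Dunn pairs). Zero-variance groups are flagged and continued with an
    epsilon guard rather than raising.
    """
    if family == "welch_anova":
        stat, df, p, flags = welch_anova_stat(groups)
        ph = games_howell_posthoc(groups, names) if posthoc else None
    elif family == "brown_forsythe":
        stat, df, p, flags = brown_forsythe_anova_stat(groups)
        ph = games_howell_posthoc(groups, names) if posthoc else None
    elif family == "kruskal_wallis":
        stat, p = sps.kruskal(*groups)
        df, flags = float(len(groups) - 1), []
        ph = dunn_posthoc(groups, names) if posthoc else None
    else:
        raise ValueError(f"unknown family {family!r}")
    ns = [len(g) for g in groups]
    if family != "kruskal_wallis" and min(ns) <= 50:
        flags = flags + ["small_n_games_howell"]
    return ComparisonResult(test=family, statistic=float(stat), df=df,
                            p=float(p), posthoc=ph, flags=flags)


def mann_whitney(a, b) -> ComparisonResult:
    """Two-sided Mann–Whitney U rank test."""
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult(test="mann_whitney", statistic=float(u), df=None, p=float(p))


def _sidak(p: float, m: int) -> float:
    return float(1.0 - (1.0 - p) ** m)


def paired_compare(pre, post, method: str = "paired_t", group=None) -> ComparisonResult:
    """Paired pre/post comparison.

    ``paired_t`` and ``wilcoxon_signed_rank`` act on matched vectors
    (all-zero differences return p = 1 with a flag, by convention).
    ``rm_anova_2way_sidak`` additionally needs ``group`` — a
    between-subjects factor (e.g. the increase/decrease fold-change
    grouping); it fits a two-way repeated-measures (mixed) ANOVA and
    runs Sidak-adjusted paired contrasts (pre vs post within each
    group), mirroring the planned-contrast layout of the drug
    experiments.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) != len(post) or len(pre) < 2:
        raise ValueError("need >= 2 complete pairs")
    diffs = post - pre
    if method == "paired_t":
        if np.allclose(diffs, 0):
            return ComparisonResult("paired_t", 0.0, float(len(pre) - 1), 1.0,
                                    flags=["all_zero_differences"])
        t, p = sps.ttest_rel(post, pre)
        return ComparisonResult("paired_t", float(t), float(len(pre) - 1), float(p))
    if method == "wilcoxon_signed_rank":
        if np.allclose(diffs, 0):
            return ComparisonResult("wilcoxon_signed_rank", 0.0, None, 1.0,
                                    flags=["all_zero_differences"])
        w, p = sps.wilcoxon(post, pre)
        return ComparisonResult("wilcoxon_signed_rank", float(w), None, float(p))
    if method == "rm_anova_2way_sidak":
        if group is None:
            raise ValueError("rm_anova_2way_sidak requires a group factor")
        return _mixed_anova_sidak(pre, post, np.asarray(group))
    raise ValueError(f"unknown method {method!r}")


def _mixed_anova_sidak(pre, post, group) -> ComparisonResult:
    import pingouin as pg

    n = len(pre)
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "treatment": np.repeat(["pre", "post"], n),
            "group": np.tile(group, 2),
            "value": np.concatenate([pre, post]),
        }
    )
    aov = pg.mixed_anova(data=df, dv="value", within="treatment",
                         subject="subject", between="group")
    inter = aov[aov["Source"] == "Interaction"].iloc[0]
    levels = list(pd.unique(group))
    m = len(levels)
    rows = []
    for lev in levels:
        mask = group == lev
        if mask.sum() >= 2 and not np.allclose(post[mask] - pre[mask], 0):
            t, p_raw = sps.ttest_rel(post[mask], pre[mask])
        else:
            t, p_raw = 0.0, 1.0
        rows.append({"A": f"pre:{lev}", "B": f"post:{lev}", "statistic": float(t),
                     "p_raw": float(p_raw), "p_adjusted": _sidak(float(p_raw), m)})
    posthoc = pd.DataFrame(rows)
    return ComparisonResult(
        test="rm_anova_2way_sidak",
        statistic=float(inter["F"]),
        df=(float(inter["DF1"]), float(inter["DF2"])),
        p=float(inter["p_unc"]),
        posthoc=posthoc,
        extra={"anova_table": aov},
    )


def normality_advisory(x, alpha: float = 0.05) -> dict:
    """D'Agostino–Pearson omnibus normality check (advisory only)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        return {"p": np.nan, "normal": None, "note": "n < 8: test unreliable"}
    stat, p = sps.normaltest(x)
    return {"statistic": float(stat), "p": float(p), "normal": bool(p >= alpha)}
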