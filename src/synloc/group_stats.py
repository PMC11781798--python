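"""Group-comparison statistics decision tree and the behavioral learning index.

The comparison workflow mirrors common practice in fly behavioral
neuroscience: every group is first tested for normality (Shapiro-Wilk)
and the groups jointly for homoscedasticity (Bartlett by default).  If no
assumption is violated, parametric tests are used — Student's t-test for
two groups, one-way ANOVA with Dunnett's or Bonferroni-corrected pairwise
t-tests otherwise, or a two-way ANOVA for factorial designs.  Any
violation routes the whole comparison to nonparametric tests:
Mann-Whitney U for two groups, Kruskal-Wallis with Dunn's post hoc
pairwise test otherwise.  Every branch taken is recorded in the result's
decision path, so the choice of test is itself reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .volume_io import GroupTable

__all__ = [
    "GroupComparisonResult",
    "BehavioralCounts",
    "LearningIndexResult",
    "stats_decision_tree",
    "two_way_interaction",
    "dunn_posthoc",
    "learning_index",
    "reciprocal_average",
    "significance_symbol",
]


@dataclass
class GroupComparisonResult:
    """Outcome of a group comparison plus the path that led to it."""

    test_used: str
    statistic: float
    p_value: float
    decision_path: list[tuple[str, str]]
    adjusted: str = "none"
    posthoc: pd.DataFrame | None = None
    anova_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.decision_path:
            raise ValueError("decision_path must be non-empty")
        if not (np.isfinite(self.p_value) and 0 <= self.p_value <= 1):
            raise ValueError(f"p_value must be finite in [0, 1], got {self.p_value}")

    @property
    def symbol(self) -> str:
        return significance_symbol(self.p_value)


@dataclass
class BehavioralCounts:
    """Per-second T-maze arm counts over a test session."""

    n_cs_plus: np.ndarray
    n_cs_minus: np.ndarray
    session_length: int | None = None

    def __post_init__(self) -> None:
        self.n_cs_plus = np.asarray(self.n_cs_plus)
        self.n_cs_minus = np.asarray(self.n_cs_minus)
        if self.n_cs_plus.shape != self.n_cs_minus.shape or self.n_cs_plus.ndim != 1:
            raise ValueError("count arrays must be 1D and of equal length")
        for name, arr in (("n_cs_plus", self.n_cs_plus), ("n_cs_minus", self.n_cs_minus)):
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise ValueError(f"{name} must be non-negative integers")
        self.n_cs_plus = self.n_cs_plus.astype(int)
        self.n_cs_minus = self.n_cs_minus.astype(int)
        if self.session_length is None:
            self.session_length = len(self.n_cs_plus)


@dataclass
class LearningIndexResult:
    """Windowed learning index; seconds with no fly in either arm are
    excluded and flagged rather than propagating 0/0."""

    value: float
    n_seconds_used: int
    excluded_seconds: list[int] = field(default_factory=list)


def significance_symbol(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def _fmt_p(p: float) -> str:
    return f"p={p:.4g}"


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrs):
        if len(g) < 3:
            raise ValueError(f"group {i} has n={len(g)} < 3; normality untestable")
        if np.ptp(g) == 0:
            raise ValueError(f"group {i} is constant; variance degenerate")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrs


def _assumption_checks(
    arrs: list[np.ndarray],
    alpha: float,
    homoscedasticity: Literal["bartlett", "spearman"],
    path: list[tuple[str, str]],
) -> bool:
    """Run Shapiro-Wilk per group then a homoscedasticity test; record and
    return whether the parametric branch applies."""
    normal = True
    for i, g in enumerate(arrs):
        p = stats.shapiro(g).pvalue
        ok = p > alpha
        normal &= ok
        path.append((f"shapiro_wilk[group{i}]", f"{'pass' if ok else 'fail'} {_fmt_p(p)}"))
    if homoscedasticity == "bartlett":
        p_var = stats.bartlett(*arrs).pvalue
    elif homoscedasticity == "spearman":
        # rank correlation of absolute residuals against fitted group means
        fitted = np.concatenate([np.full(len(g), g.mean()) for g in arrs])
        resid = np.concatenate([g - g.mean() for g in arrs])
        p_var = stats.spearmanr(np.abs(resid), fitted).pvalue
    else:
        raise ValueError(f"unknown homoscedasticity test {homoscedasticity!r}")
    ok_var = p_var > alpha
    path.append(
        (f"homoscedasticity[{homoscedasticity}]", f"{'pass' if ok_var else 'fail'} {_fmt_p(p_var)}")
    )
    return normal and ok_var


def dunn_posthoc(
    groups: Sequence[np.ndarray],
    p_adjust: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's rank-based pairwise post hoc test after Kruskal-Wallis.

    Uses tie-corrected pooled-rank variance; two-sided z tests per pair
    with the chosen multiple-comparison adjustment.
    """
    arrs = [np.asarray(g, float).ravel() for g in groups]
    pooled = np.concatenate(arrs)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in arrs:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            se = np.sqrt(var_unit * (1 / sizes[i] + 1 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_i": i, "group_j": j, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method=p_adjust)[1]
    return df


def _bonferroni_t_posthoc(arrs: list[np.ndarray]) -> pd.DataFrame:
    rows = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            t, p = stats.ttest_ind(arrs[i], arrs[j], equal_var=True)
            rows.append({"group_i": i, "group_j": j, "t": t, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p_raw"], method="bonferroni")[1]
    return df


def stats_decision_tree(
    groups: Sequence[np.ndarray] | GroupTable,
    design: Literal["two_group", "one_way", "two_way"] = "two_group",
    alpha: float = 0.05,
    homoscedasticity: Literal["bartlett", "spearman"] = "bartlett",
    post_hoc: Literal["auto", "none", "dunnett", "bonferroni_t", "dunn"] = "auto",
    control_index: int = 0,
    **two_way_kwargs,
) -> GroupComparisonResult:
    """Run the assumption-gated group comparison and record every branch.

    For ``two_group``/``one_way`` designs, ``groups`` is a list of 1D
    sample arrays (each n >= 3).  For ``two_way``, pass a
    :class:`GroupTable` (checks run per factor cell, then the factorial
    ANOVA; a violated assumption routes to the ANOVA on rank-transformed
    responses).  Post hoc defaults: Bonferroni-corrected t-tests on the
    parametric branch (``dunnett`` compares all groups against
    ``control_index`` instead), Dunn's test on the nonparametric branch.
    """
    path: list[tuple[str, str]] = []

    if design == "two_way":
        if not isinstance(groups, GroupTable):
            raise TypeError("design='two_way' requires a GroupTable")
        return _two_way_tree(groups, alpha, homoscedasticity, path, **two_way_kwargs)

    arrs = _check_groups(groups)
    if design == "two_group" and len(arrs) != 2:
        raise ValueError(f"design='two_group' requires exactly 2 groups, got {len(arrs)}")

    parametric = _assumption_checks(arrs, alpha, homoscedasticity, path)
    posthoc_df = None
    adjusted = "none"

    if parametric:
        path.append(("branch", "parametric"))
        if design == "two_group":
            res = stats.ttest_ind(arrs[0], arrs[1], equal_var=True)
            test_used, statistic, p_value = "student_t", res.statistic, res.pvalue
        else:
            res = stats.f_oneway(*arrs)
            test_used, statistic, p_value = "one_way_anova", res.statistic, res.pvalue
            if post_hoc in ("auto", "bonferroni_t"):
                posthoc_df = _bonferroni_t_posthoc(arrs)
                adjusted = "bonferroni"
            elif post_hoc == "dunnett":
                treat = [a for k, a in enumerate(arrs) if k != control_index]
                dres = stats.dunnett(*treat, control=arrs[control_index])
                posthoc_df = pd.DataFrame(
                    {
                        "group": [k for k in range(len(arrs)) if k != control_index],
                        "statistic": dres.statistic,
                        "p_adj": dres.pvalue,
                    }
                )
                adjusted = "dunnett"
    else:
        path.append(("branch", "nonparametric"))
        if design == "two_group":
            res = stats.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided")
            test_used, statistic, p_value = "mann_whitney_u", res.statistic, res.pvalue
        else:
            res = stats.kruskal(*arrs)
            test_used, statistic, p_value = "kruskal_wallis", res.statistic, res.pvalue
            if post_hoc in ("auto", "dunn"):
                posthoc_df = dunn_posthoc(arrs)
                adjusted = "dunn_bonferroni"

    path.append((test_used, _fmt_p(p_value)))
    return GroupComparisonResult(
        test_used=test_used,
        statistic=float(statistic),
        p_value=float(p_value),
        decision_path=path,
        adjusted=adjusted,
        posthoc=posthoc_df,
    )


def _two_way_tree(
    table: GroupTable,
    alpha: float,
    homoscedasticity: str,
    path: list[tuple[str, str]],
    factor_a: str = "genotype",
    factor_b: str | None = None,
    response: str = "measurement",
) -> GroupComparisonResult:
    factor_b = factor_b or table.condition_column
    cells = [g.values for _, g in table.data.groupby([factor_a, factor_b])[response]]
    arrs = _check_groups(cells)
    parametric = _assumption_checks(arrs, alpha, homoscedasticity, path)
    if parametric:
        path.append(("branch", "parametric"))
        result = two_way_interaction(table, factor_a, factor_b, response)
    else:
        # no exact nonparametric factorial analogue; rank-transform the
        # response and run the same factorial ANOVA (documented choice)
        path.append(("branch", "nonparametric (rank-transformed ANOVA)"))
        ranked = table.data.copy()
        ranked[response] = stats.rankdata(ranked[response])
        result = two_way_interaction(
            GroupTable(ranked, table.condition_column), factor_a, factor_b, response
        )
    result.decision_path = path + result.decision_path
    return result


def two_way_interaction(
    table: GroupTable,
    factor_a: str = "genotype",
    factor_b: str | None = None,
    response: str = "measurement",
) -> GroupComparisonResult:
    """Two-way ANOVA (type-II sums of squares); the headline statistic is
    the A x B interaction F and p, with main effects in the record.

    Designed for factorial questions like "does receptor level change
    with starvation time differently across genotypes".
    """
    factor_b = factor_b or table.condition_column
    df = table.data
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels, has {df[f].nunique()}")
    counts = df.groupby([factor_a, factor_b], observed=True)[response].count()
    full = pd.MultiIndex.from_product([df[factor_a].unique(), df[factor_b].unique()])
    counts = counts.reindex(full, fill_value=0)
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(f"cell(s) with < 2 observations: {thin.index.tolist()}")

    data = df.rename(columns={factor_a: "A", factor_b: "B", response: "y"})
    model = smf.ols("y ~ C(A) * C(B)", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    inter = anova.loc["C(A):C(B)"]
    path = [
        ("two_way_anova[A]", _fmt_p(anova.loc["C(A)", "PR(>F)"])),
        ("two_way_anova[B]", _fmt_p(anova.loc["C(B)", "PR(>F)"])),
        ("two_way_anova[interaction]", _fmt_p(inter["PR(>F)"])),
    ]
    return GroupComparisonResult(
        test_used="two_way_anova_interaction",
        statistic=float(inter["F"]),
        p_value=float(inter["PR(>F)"]),
        decision_path=path,
        anova_table=anova,
    )


def learning_index(
    counts: BehavioralCounts,
    window_seconds: int = 60,
    sign: Literal["aversive", "appetitive"] = "aversive",
) -> LearningIndexResult:
    """Windowed T-maze learning index.

    Per second, LI_t = (#CS- - #CS+) / (#CS+ + #CS-) (aversive
    convention; learned avoidance of the punished odor is positive), then
    averaged over the last ``window_seconds`` of the session.
    ``sign="appetitive"`` flips the convention so that learned approach
    of the rewarded odor scores positive.  Seconds with no fly in either
    arm are excluded and flagged.
    """
    n = len(counts.n_cs_plus)
    if not 0 < window_seconds <= n:
        raise ValueError(f"window of {window_seconds}s does not fit a {n}s session")
    plus = counts.n_cs_plus[n - window_seconds :].astype(float)
    minus = counts.n_cs_minus[n - window_seconds :].astype(float)
    total = plus + minus
    included = total > 0
    excluded = [int(i) for i in np.nonzero(~included)[0] + (n - window_seconds)]
    if not included.any():
        raise ValueError("every second in the averaging window has zero flies")
    li_sec = (minus[included] - plus[included]) / total[included]
    if sign == "appetitive":
        li_sec = -li_sec
    elif sign != "aversive":
        raise ValueError(f"unknown sign convention {sign!r}")
    return LearningIndexResult(
        value=float(li_sec.mean()),
        n_seconds_used=int(included.sum()),
        excluded_seconds=excluded,
    )


def reciprocal_average(li_a: float, li_b: float) -> float:
    """Average the indices of a reciprocally trained pair of groups into
    one data point (cancels odor-identity bias)."""
    if not (np.isfinite(li_a) and np.isfinite(li_b)):
        raise ValueError("both learning indices must be finite")
    return float((li_a + li_b) / 2.0)
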