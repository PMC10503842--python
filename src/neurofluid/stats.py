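"""Cohort-level rank-based statistics for the neurofluid study design.

Group comparisons use the Wilcoxon rank-sum test (exact enumeration when the
combined sample is small, otherwise the tie-corrected normal approximation
with continuity correction), categorical contrasts use Pearson's chi-squared,
associations use Spearman rank-order correlation, and covariate dependence is
assessed with separate simple OLS regressions (cohort, age, sex), mirroring
how small observational imaging cohorts are typically analyzed.  Significance
is two-sided p < 0.05 throughout with no multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "GroupComparisonResult",
    "CorrelationResult",
    "wilcoxon_rank_sum",
    "spearman_corr",
    "chi_squared_2x2",
    "linear_regression",
    "cohort_analysis",
    "CohortResults",
]

ALPHA = 0.05

#: combined sample size at or below which the Wilcoxon p is exact
EXACT_WILCOXON_MAX_N = 12


@dataclass
class GroupComparisonResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    group_means: tuple[float, float] = (np.nan, np.nan)
    group_sds: tuple[float, float] = (np.nan, np.nan)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class CorrelationResult:
    variables: tuple[str, str]
    rho: float
    p_value: float
    n: int
    defined: bool = True

    @property
    def significant(self) -> bool:
        return self.defined and self.p_value < ALPHA


def _rank_sum_exact_p(ranks: np.ndarray, n_x: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum W by enumerating all assignments.

    Enumerates every C(n, n_x) choice of which midranks belong to x; ties are
    handled naturally because the midranks themselves are permuted.  The
    two-sided p is 2 * min(P(W <= w), P(W >= w)), capped at 1.
    """
    n = ranks.size
    total = comb(n, n_x)
    lo = hi = 0
    eps = 1e-9
    for idx in combinations(range(n), n_x):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            lo += 1
        if w >= w_obs - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_rank_sum(x, y, variable: str = "") -> GroupComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    For combined samples of at most ``EXACT_WILCOXON_MAX_N`` observations the
    p-value is computed by exact enumeration of all rank assignments;
    otherwise by the normal approximation with tie-corrected variance and a
    0.5 continuity correction.  The statistic reported is the rank sum of x.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs >= 2 observations")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = float(ranks[:n_x].sum())

    if n <= EXACT_WILCOXON_MAX_N:
        p = _rank_sum_exact_p(ranks, n_x, w)
    else:
        mean_w = n_x * (n + 1) / 2.0
        _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
        var_w = n_x * n_y / 12.0 * ((n + 1) - tie_term)
        if var_w <= 0:  # all observations identical
            p = 1.0
        else:
            # continuity correction shrinks |W - E[W]| by 0.5
            z = (w - mean_w - 0.5 * np.sign(w - mean_w)) / np.sqrt(var_w)
            p = float(2.0 * sps.norm.sf(abs(z)))
            p = min(1.0, p)
    return GroupComparisonResult(
        variable=variable,
        test="wilcoxon_rank_sum",
        statistic=w,
        p_value=p,
        group_means=(float(x.mean()), float(y.mean())),
        group_sds=(float(x.std(ddof=1)), float(y.std(ddof=1))),
    )


def spearman_corr(x, y, variables: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Spearman rank-order correlation (Pearson of midranks, t-approximation p).

    Constant input leaves rho undefined; the result is flagged rather than
    raising.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise ValueError("samples must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(
            variables=variables, rho=np.nan, p_value=np.nan, n=x.size, defined=False
        )
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(
        variables=variables, rho=float(rho), p_value=float(p), n=x.size
    )


def chi_squared_2x2(table, variable: str = "") -> GroupComparisonResult:
    """Pearson chi-squared on a 2x2 count table, no continuity correction, 1 df."""
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    stat, p, _, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be > 0")
    return GroupComparisonResult(
        variable=variable, test="chi_squared", statistic=float(stat), p_value=float(p)
    )


def linear_regression(
    response, covariates: pd.DataFrame, joint: bool = False
) -> pd.DataFrame:
    """OLS of the response on cohort/age/sex covariates with t-based p-values.

    By default each covariate is fit in its own simple regression (with
    intercept); ``joint=True`` fits them together instead.  Returns a table
    with one row per covariate: coefficient, standard error, t, p.
    """
    y = np.asarray(response, dtype=np.float64)
    X = covariates.copy()
    for col in X.columns:
        if X[col].dtype == object or str(X[col].dtype) == "category":
            codes, _ = pd.factorize(X[col])
            X[col] = codes.astype(float)  # binary indicator for e.g. sex
    X = X.astype(float)
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > number of covariates + 1")

    rows = []
    if joint:
        design = sm.add_constant(X)
        if np.linalg.matrix_rank(design.values) < design.shape[1]:
            raise ValueError("rank-deficient design")
        fit = sm.OLS(y, design).fit()
        for col in X.columns:
            rows.append(
                {
                    "covariate": col,
                    "coef": fit.params[col],
                    "stderr": fit.bse[col],
                    "t": fit.tvalues[col],
                    "p_value": fit.pvalues[col],
                    "model": "joint",
                }
            )
    else:
        for col in X.columns:
            design = sm.add_constant(X[[col]])
            if np.linalg.matrix_rank(design.values) < design.shape[1]:
                raise ValueError(f"rank-deficient design for covariate {col}")
            fit = sm.OLS(y, design).fit()
            rows.append(
                {
                    "covariate": col,
                    "coef": fit.params[col],
                    "stderr": fit.bse[col],
                    "t": fit.tvalues[col],
                    "p_value": fit.pvalues[col],
                    "model": "simple",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CohortResults:
    """Bundle of the full cohort analysis; every member serializes to TSV."""

    descriptives: pd.DataFrame
    comparisons: list[GroupComparisonResult] = field(default_factory=list)
    correlations: list[CorrelationResult] = field(default_factory=list)
    regressions: pd.DataFrame | None = None

    def comparisons_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "variable": c.variable,
                    "test": c.test,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "mean_healthy": c.group_means[0],
                    "mean_pd": c.group_means[1],
                    "sd_healthy": c.group_sds[0],
                    "sd_pd": c.group_sds[1],
                    "significant": c.significant,
                }
                for c in self.comparisons
            ]
        )

    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "var_x": c.variables[0],
                    "var_y": c.variables[1],
                    "rho": c.rho,
                    "p_value": c.p_value,
                    "n": c.n,
                    "defined": c.defined,
                    "significant": c.significant,
                }
                for c in self.correlations
            ]
        )


CONTINUOUS_ROI_COLUMNS = [
    "wm_d",
    "gm_d",
    "ventricle_d",
    "suprasellar_d",
    "cp_perfusion",
]


def cohort_analysis(table: pd.DataFrame) -> CohortResults:
    """Run the full cohort-level analysis on a per-subject table.

    Emits group descriptives (mean +- SD per variable), Wilcoxon rank-sum
    comparisons for age and every continuous ROI variable, a chi-squared test
    for sex, Spearman correlations of suprasellar decay vs choroid plexus
    perfusion within each group and pooled, exploratory Spearman of UPDRS and
    MoCA vs suprasellar decay in the PD group, and simple regressions of
    suprasellar decay on cohort, age and sex.
    """
    required = {"group", "age", "sex", "suprasellar_d", "cp_perfusion"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    groups = set(table["group"])
    if not {"healthy", "PD"} <= groups:
        raise ValueError("both 'healthy' and 'PD' groups are required")
    healthy = table[table["group"] == "healthy"]
    pd_grp = table[table["group"] == "PD"]

    desc_rows = []
    for col in ["age"] + [c for c in CONTINUOUS_ROI_COLUMNS if c in table] + [
        c for c in ("updrs", "moca") if c in table
    ]:
        desc_rows.append(
            {
                "variable": col,
                "mean_healthy": healthy[col].mean(),
                "sd_healthy": healthy[col].std(ddof=1),
                "mean_pd": pd_grp[col].mean(),
                "sd_pd": pd_grp[col].std(ddof=1),
            }
        )
    descriptives = pd.DataFrame(desc_rows)

    comparisons = [wilcoxon_rank_sum(healthy["age"], pd_grp["age"], variable="age")]
    for col in CONTINUOUS_ROI_COLUMNS:
        if col in table:
            comparisons.append(
                wilcoxon_rank_sum(healthy[col], pd_grp[col], variable=col)
            )
    sex_table = [
        [(healthy["sex"] == "F").sum(), (healthy["sex"] == "M").sum()],
        [(pd_grp["sex"] == "F").sum(), (pd_grp["sex"] == "M").sum()],
    ]
    comparisons.append(chi_squared_2x2(sex_table, variable="sex"))

    correlations = [
        spearman_corr(
            healthy["cp_perfusion"],
            healthy["suprasellar_d"],
            variables=("cp_perfusion", "suprasellar_d[healthy]"),
        ),
        spearman_corr(
            pd_grp["cp_perfusion"],
            pd_grp["suprasellar_d"],
            variables=("cp_perfusion", "suprasellar_d[PD]"),
        ),
        spearman_corr(
            table["cp_perfusion"],
            table["suprasellar_d"],
            variables=("cp_perfusion", "suprasellar_d[all]"),
        ),
    ]
    if "updrs" in table:
        correlations.append(
            spearman_corr(
                pd_grp["updrs"],
                pd_grp["suprasellar_d"],
                variables=("updrs", "suprasellar_d[PD]"),
            )
        )
    if "moca" in table:
        correlations.append(
            spearman_corr(
                pd_grp["moca"],
                pd_grp["suprasellar_d"],
                variables=("moca", "suprasellar_d[PD]"),
            )
        )

    covs = pd.DataFrame(
        {
            "cohort": (table["group"] == "PD").astype(float),
            "age": table["age"].astype(float),
            "sex": table["sex"],
        }
    )
    regressions = linear_regression(table["suprasellar_d"], covs)

    return CohortResults(
        descriptives=descriptives,
        comparisons=comparisons,
        correlations=correlations,
        regressions=regressions,
    )
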