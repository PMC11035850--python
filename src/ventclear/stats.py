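"""Cohort-level statistics for fitted clearance constants.

Covers the analyses run on the per-subject rate constants: two-group
contrasts (Welch t and Wilcoxon rank-sum), Fisher's exact test for
categorical covariates, the interaction regression of clearance on blood
delivery (k_clearance ~ group + k1_blood + group x k1_blood, with estimated
marginal means per group at the pooled mean of k1_blood), and Spearman rank
correlation of clearance against the DTI-ALPS covariate.

Group coding is control = 0, TBI = 1 throughout, so the group coefficient is
the TBI offset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "group_compare",
    "group_compare_from_stats",
    "fisher_exact",
    "interaction_regression",
    "rank_correlation",
    "full_report",
]

GROUP_CODES = {"control": 0, "TBI": 1}


def group_compare(values: np.ndarray, groups: np.ndarray) -> dict:
    """Welch t-test and Wilcoxon rank-sum between the two groups.

    The rank-sum p is exact when the pooled sample has no ties and both
    groups are small; otherwise the normal approximation is used.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    out = {
        "groups": labels,
        "means": {labels[0]: float(a.mean()), labels[1]: float(b.mean())},
        "sds": {labels[0]: float(a.std(ddof=1)), labels[1]: float(b.std(ddof=1))},
        "flags": [],
    }
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        out["flags"].append("t_undefined_constant_groups")
        out["t_p"] = 1.0 if a.mean() == b.mean() else np.nan
    else:
        out["t_p"] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    pooled = np.concatenate([a, b])
    exact_ok = len(np.unique(pooled)) == len(pooled) and max(len(a), len(b)) <= 25
    method = "exact" if exact_ok else "asymptotic"
    out["wilcoxon_p"] = float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )
    out["wilcoxon_method"] = method
    return out


def group_compare_from_stats(mean1: float, sd1: float, n1: int,
                             mean2: float, sd2: float, n2: int) -> dict:
    """Welch t-test from group summary statistics (means, SDs, n)."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return {"t": float(res.statistic), "t_p": float(res.pvalue)}


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher exact p (hypergeometric tables as or less probable).

    A zero margin makes every table with those margins identical, so p = 1
    by convention.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 integer table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


@dataclass
class RegressionResult:
    """OLS of k_clearance on group, k1_blood and their interaction."""

    coefficients: dict[str, float]
    se: dict[str, float]
    p_values: dict[str, float]
    r_squared: float
    adj_r_squared: float
    f_stat: float
    model_p: float
    emm: dict[str, dict[str, float]]           # per group: value, se at pooled mean k1_blood
    per_group_pearson: dict[str, dict[str, float]]  # per group: r, p
    n: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "se": self.se,
            "p_values": self.p_values,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "f_stat": self.f_stat,
            "model_p": self.model_p,
            "emm": self.emm,
            "per_group_pearson": self.per_group_pearson,
            "n": self.n,
            "flags": self.flags,
        }


def interaction_regression(
    cohort: pd.DataFrame,
    include_age: bool = False,
    exclude_max_control: bool = False,
) -> RegressionResult:
    """k_clearance ~ group + k1_blood + group:k1_blood by OLS.

    Estimated marginal means (EMMs) are the model predictions per group at
    the pooled mean of k1_blood, with delta-method standard errors.
    ``exclude_max_control`` re-runs the model without the control subject
    with the highest k_clearance (sensitivity analysis).
    """
    df = cohort.copy()
    required = {"group", "k1_blood", "k_clearance"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must contain {sorted(required)}")
    df = df.dropna(subset=["k1_blood", "k_clearance"])
    if exclude_max_control:
        ctrl = df[df["group"] == "control"]
        if len(ctrl):
            df = df.drop(index=ctrl["k_clearance"].idxmax())
    if df["group"].nunique() != 2:
        raise ValueError("both groups must be present")
    if len(df) < 5:
        raise ValueError("need n >= 5 for the interaction regression")
    flags: list[str] = []
    g = df["group"].map(GROUP_CODES).to_numpy(dtype=float)
    x = df["k1_blood"].to_numpy(dtype=float)
    y = df["k_clearance"].to_numpy(dtype=float)

    names = ["intercept", "group", "k1_blood", "group_x_k1_blood"]
    X = np.column_stack([np.ones_like(x), g, x, g * x])
    if include_age:
        X = np.column_stack([X, df["age_years"].to_numpy(dtype=float)])
        names = names + ["age_years"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        flags.append("rank_deficient_interaction_dropped")
        keep = [i for i, nm in enumerate(names) if nm != "group_x_k1_blood"]
        X = X[:, keep]
        names = [names[i] for i in keep]
    model = sm.OLS(y, X).fit()

    coeffs = dict(zip(names, map(float, model.params)))
    ses = dict(zip(names, map(float, model.bse)))
    pvals = dict(zip(names, map(float, model.pvalues)))

    xbar = float(x.mean())
    emm: dict[str, dict[str, float]] = {}
    cov = np.asarray(model.cov_params())
    for label, code in GROUP_CODES.items():
        row = {"intercept": 1.0, "group": float(code), "k1_blood": xbar,
               "group_x_k1_blood": float(code) * xbar, "age_years": float(df["age_years"].mean()) if include_age else 0.0}
        x0 = np.array([row[nm] for nm in names])
        emm[label] = {
            "value": float(x0 @ model.params),
            "se": float(np.sqrt(x0 @ cov @ x0)),
        }

    pearson: dict[str, dict[str, float]] = {}
    for label in GROUP_CODES:
        sub = df[df["group"] == label]
        if len(sub) >= 3 and sub["k1_blood"].std() > 0 and sub["k_clearance"].std() > 0:
            r, p = sps.pearsonr(sub["k1_blood"], sub["k_clearance"])
            pearson[label] = {"r": float(r), "p": float(p)}
        else:
            pearson[label] = {"r": np.nan, "p": np.nan}
            flags.append(f"pearson_undefined_{label}")

    return RegressionResult(
        coefficients=coeffs,
        se=ses,
        p_values=pvals,
        r_squared=float(model.rsquared),
        adj_r_squared=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        model_p=float(model.f_pvalue),
        emm=emm,
        per_group_pearson=pearson,
        n=len(df),
        flags=flags,
    )


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p for Spearman rho (all n! relabelings of y)."""
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    n = len(xr)
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (yc[perms] @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def rank_correlation(x: np.ndarray, y: np.ndarray) -> dict:
    """Spearman rho with mid-rank ties; exact permutation p for n < 10.

    Pairs with a missing value in either vector are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4 complete pairs")
    out: dict = {"n": n, "flags": []}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        out["flags"].append("constant_vector")
        out["rho"], out["p"] = np.nan, np.nan
        return out
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    out["rho"] = rho
    if n < 10:
        out["p"] = _spearman_exact_p(xr, yr, rho)
        out["p_method"] = "exact_permutation"
    else:
        out["p"] = float(sps.spearmanr(x, y).pvalue)
        out["p_method"] = "t_approximation"
    return out


def full_report(cohort: pd.DataFrame, include_age: bool = False,
                exclude_max_control: bool = False) -> dict:
    """All cohort statistics keyed by analysis name (JSON-serializable)."""
    report: dict = {}
    for var in ("k_clearance", "k1_blood", "age_years"):
        if var in cohort.columns:
            sub = cohort.dropna(subset=[var])
            report[f"group_compare_{var}"] = group_compare(
                sub[var].to_numpy(), sub["group"].to_numpy()
            )
    if "sex" in cohort.columns:
        table = np.array([
            [int(((cohort["group"] == g) & (cohort["sex"] == s)).sum()) for s in ("M", "F")]
            for g in ("TBI", "control")
        ])
        report["fisher_sex"] = {"table": table.tolist(), "p": fisher_exact(table)}
    report["interaction_regression"] = interaction_regression(
        cohort, include_age=include_age, exclude_max_control=exclude_max_control
    ).to_dict()
    if "alps_index" in cohort.columns and cohort["alps_index"].notna().sum() >= 4:
        report["alps_rank_correlation"] = rank_correlation(
            cohort["k_clearance"].to_numpy(), cohort["alps_index"].to_numpy()
        )
    return report
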