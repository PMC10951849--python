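"""Behavioural and questionnaire statistics.

Mixed (split-plot) two-way ANOVA — one between-participant factor
(group) crossed with one within-participant factor (condition, 2
levels) — with Bonferroni-corrected simple-effects analyses run only
when the interaction is significant (main effects are reported
otherwise).  A multiple linear regression predicts per-participant
theta contrasts from ERQ Reappraisal, ERQ Suppression and the
reappraisal-minus-maintenance rating difference, with Bonferroni
adjustment over the three predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DataError

__all__ = ["AnovaResult", "RegressionResult", "mixed_anova_2x2", "theta_regression"]


@dataclass
class AnovaResult:
    """Split-plot ANOVA effects and (conditional) simple effects."""

    effects: dict            # name -> {"F", "df", "p"}
    simple_effects: list = field(default_factory=list)
    alpha: float = 0.05
    n_excluded: int = 0

    @property
    def interaction_significant(self) -> bool:
        return self.effects["interaction"]["p"] < self.alpha

    def to_dict(self) -> dict:
        return {
            "effects": {k: {kk: (list(vv) if isinstance(vv, tuple) else float(vv))
                            for kk, vv in v.items()}
                        for k, v in self.effects.items()},
            "simple_effects": self.simple_effects,
            "n_excluded": self.n_excluded,
        }


@dataclass
class RegressionResult:
    f_value: float
    df: tuple[int, int]
    r_squared: float
    coefficients: dict       # name -> {"coef", "t", "p", "p_adjusted"}
    p_value: float

    def to_dict(self) -> dict:
        return {
            "F": float(self.f_value), "df": list(self.df),
            "R2": float(self.r_squared), "p": float(self.p_value),
            "coefficients": {k: {kk: float(vv) for kk, vv in v.items()}
                             for k, v in self.coefficients.items()},
        }


def mixed_anova_2x2(
    table: pd.DataFrame,
    value_cols: tuple[str, str],
    group_col: str = "group",
    alpha: float = 0.05,
) -> AnovaResult:
    """Split-plot ANOVA of two within-participant condition columns by a
    two-level grouping column.

    Participants with a missing condition value are excluded with a
    warning.  When the group × condition interaction is significant,
    Bonferroni-corrected within-group paired comparisons (simple
    effects of condition) are reported.
    """
    c1, c2 = value_cols
    df_in = table[[group_col, c1, c2]].copy()
    complete = df_in[[c1, c2]].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} participant(s) with missing "
                      "condition values")
    df_in = df_in[complete]
    groups = sorted(df_in[group_col].unique())
    if len(groups) != 2:
        raise DataError(f"need exactly 2 groups, got {groups}")
    y = df_in[[c1, c2]].to_numpy(float)          # (n, 2)
    g = df_in[group_col].to_numpy()
    n_per = {gr: int((g == gr).sum()) for gr in groups}
    if min(n_per.values()) < 2:
        raise DataError("need at least 2 participants per group")
    n = len(df_in)

    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    cell_mean = np.array([[y[g == gr, j].mean() for j in (0, 1)] for gr in groups])
    group_mean = cell_mean.mean(axis=1)

    # between-participant stratum
    ss_group = sum(2 * n_per[gr] * (group_mean[i] - grand) ** 2
                   for i, gr in enumerate(groups))
    ss_subj_within = sum(
        float((2 * (subj_mean[g == gr] - group_mean[i]) ** 2).sum())
        for i, gr in enumerate(groups))
    # within-participant stratum
    ss_cond = sum(n * (cond_mean[j] - grand) ** 2 for j in (0, 1))
    ss_inter = sum(n_per[gr] * (cell_mean[i, j] - group_mean[i]
                                - cond_mean[j] + grand) ** 2
                   for i, gr in enumerate(groups) for j in (0, 1))
    ss_total = ((y - grand) ** 2).sum()
    ss_resid = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter

    df_group, df_cond, df_inter = 1, 1, 1
    df_subj = n - 2
    df_resid = n - 2

    def eff(ss, dfn, ss_err, dfe):
        ms, mse = ss / dfn, ss_err / dfe
        F = 0.0 if ss <= 1e-300 and mse <= 1e-300 else \
            (np.inf if mse == 0 and ms > 0 else ms / mse if mse > 0 else 0.0)
        p = 1.0 if not np.isfinite(F) and F != np.inf else float(stats.f.sf(F, dfn, dfe))
        if F == np.inf:
            p = 0.0
        return {"F": float(F), "df": (dfn, dfe), "p": p}

    effects = {
        "group": eff(ss_group, df_group, ss_subj_within, df_subj),
        "condition": eff(ss_cond, df_cond, ss_resid, df_resid),
        "interaction": eff(ss_inter, df_inter, ss_resid, df_resid),
    }

    result = AnovaResult(effects, alpha=alpha, n_excluded=n_excluded)
    if result.interaction_significant:
        k = len(groups)  # one paired contrast per group
        for i, gr in enumerate(groups):
            sub = y[g == gr]
            t, p = stats.ttest_rel(sub[:, 0], sub[:, 1])
            result.simple_effects.append({
                "group": gr, "contrast": f"{c1} - {c2}",
                "t": float(t), "df": int(len(sub) - 1),
                "p": float(p), "p_adjusted": float(min(1.0, k * p)),
            })
    return result


def theta_regression(
    theta: np.ndarray,
    erq_reappraisal: np.ndarray,
    erq_suppression: np.ndarray,
    rating_diff: np.ndarray,
    alpha: float = 0.05,
) -> RegressionResult:
    """OLS of the cluster-mean theta contrast on the two ERQ facets and
    the rating difference; two-sided per-predictor t tests with
    Bonferroni adjustment over the 3 predictors.  Complete cases only."""
    import statsmodels.api as sm

    X = np.column_stack([erq_reappraisal, erq_suppression, rating_diff]).astype(float)
    y = np.asarray(theta, float)
    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    if len(y) < 5:
        raise DataError("too few complete cases for regression")
    design = sm.add_constant(X)
    if np.linalg.cond(design) > 1e8:
        raise DataError("collinear design matrix (condition number > 1e8)")
    fit = sm.OLS(y, design).fit()
    names = ["intercept", "erq_reappraisal", "erq_suppression", "rating_diff"]
    coefs = {}
    for i, name in enumerate(names):
        entry = {
            "coef": float(fit.params[i]),
            "t": float(fit.tvalues[i]),
            "p": float(fit.pvalues[i]),
        }
        if name != "intercept":
            entry["p_adjusted"] = float(min(1.0, 3 * fit.pvalues[i]))
        coefs[name] = entry
    return RegressionResult(
        f_value=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        r_squared=float(fit.rsquared),
        coefficients=coefs,
        p_value=float(fit.f_pvalue),
    )
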