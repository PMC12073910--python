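"""Age-trajectory statistics for fitted diffusion parameters.

For every (region, metabolite, model, parameter) cell of a cohort table
the suite runs, after removing estimates that converged onto their fitting
lower bound (considered unreliable):

* ordinary least-squares regression of the estimate on age, with 95 %
  confidence and prediction bands on a dense age grid;
* a two-regressor OLS, y ~ b0 + b1*age + b2*(fGM/fWM), separating the
  age effect from voxel tissue composition;
* an independent two-sample t-test between younger (age < 50) and older
  (age >= 50) subjects, Bonferroni-corrected across the 6-cell family
  (2 regions x 3 metabolites) of each diffusion metric.

OLS inference goes through statsmodels; t-tests through scipy. The raw
per-coefficient p-values of the regressions are reported uncorrected;
only the t-test family is Bonferroni-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "LinearTrajectory",
    "CovariateFit",
    "GroupComparison",
    "TrajectoryResult",
    "exclude_at_bound",
    "linear_trajectory",
    "covariate_regression",
    "group_ttest",
    "bonferroni_threshold",
    "run_trajectory_suite",
]

AGE_CUTOFF = 50.0
N_BAND_POINTS = 100


@dataclass
class LinearTrajectory:
    """Univariate OLS of an estimate on age, with 95 % bands."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_p: float
    age_grid: np.ndarray
    conf_low: np.ndarray
    conf_high: np.ndarray
    pred_low: np.ndarray
    pred_high: np.ndarray
    n: int


@dataclass
class CovariateFit:
    """OLS with age and fGM/fWM regressors; per-coefficient inference."""

    beta0: float
    beta_age: float
    beta_fgmfwm: float
    p_age: float
    p_fgmfwm: float
    n: int
    condition_number: float


@dataclass
class GroupComparison:
    """Younger (< 50 y) vs older (>= 50 y) two-sample t-test."""

    t: float
    df: float
    p: float
    young_mean: float
    young_sd: float
    old_mean: float
    old_sd: float
    n_young: int
    n_old: int


@dataclass
class TrajectoryResult:
    """All statistics for one (region, metabolite, model, parameter) cell."""

    linear: LinearTrajectory | None
    covariate: CovariateFit | None
    group: GroupComparison | None
    n_used: int
    n_excluded: int
    analyzable: bool
    reason: str = ""


def exclude_at_bound(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop unreliable rows before trajectory analysis.

    Removes rows flagged ``at_lower_bound`` (the estimate collapsed onto
    the fitting lower bound), rows with non-finite estimates, and rows
    from invalid fits. Returns the filtered table and an exclusion log
    with one row per removal (subject, parameter, reason).
    """
    reasons = pd.Series("", index=table.index, dtype=object)
    bad_nan = ~np.isfinite(table["estimate"].to_numpy(dtype=float))
    reasons[bad_nan] = "nan_estimate"
    if "valid" in table.columns:
        bad_valid = ~table["valid"].astype(bool) & ~bad_nan
        reasons[bad_valid] = "invalid_fit"
    at_lb = table["at_lower_bound"].astype(bool) & (reasons == "")
    reasons[at_lb] = "at_lower_bound"
    drop = reasons != ""
    log = table.loc[drop, ["subject_id", "region", "metabolite", "model",
                           "parameter"]].copy()
    log["reason"] = reasons[drop].to_numpy()
    return table.loc[~drop].copy(), log.reset_index(drop=True)


def linear_trajectory(values, ages) -> LinearTrajectory:
    """OLS of parameter estimates on age with confidence/prediction bands.

    Bands are 95 % pointwise intervals on ``N_BAND_POINTS`` ages spanning
    the observed range; the prediction band (new observation) contains
    the confidence band (regression mean) everywhere.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if y.size < 3:
        raise ValueError("need n >= 3 for the age regression")
    scale = max(float(np.abs(y).max()), 1.0)
    if float(np.ptp(y)) <= 1e-12 * scale:
        # exactly constant response: no evidence of any slope
        grid = np.linspace(x.min(), x.max(), N_BAND_POINTS)
        mean = np.full(N_BAND_POINTS, float(y.mean()))
        return LinearTrajectory(0.0, float(y.mean()), 0.0, 0.0, 1.0,
                                grid, mean.copy(), mean.copy(),
                                mean.copy(), mean.copy(), int(y.size))
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), N_BAND_POINTS)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    slope_p = float(fit.pvalues[1])
    if not np.isfinite(slope_p):
        # zero residual variance: an exact line is infinitely significant,
        # an exactly constant y carries no evidence of a slope at all
        scale = max(np.abs(y).max(), 1.0)
        slope_p = 0.0 if abs(fit.params[1]) > 1e-12 * scale else 1.0
    return LinearTrajectory(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        slope_p=slope_p,
        age_grid=grid,
        conf_low=pred["mean_ci_lower"].to_numpy(),
        conf_high=pred["mean_ci_upper"].to_numpy(),
        pred_low=pred["obs_ci_lower"].to_numpy(),
        pred_high=pred["obs_ci_upper"].to_numpy(),
        n=int(y.size),
    )


def covariate_regression(values, ages, fgmfwm,
                         max_condition: float = 1e10) -> CovariateFit:
    """OLS of estimates on age and the GM/WM fraction ratio."""
    y = np.asarray(values, dtype=float)
    x1 = np.asarray(ages, dtype=float)
    x2 = np.asarray(fgmfwm, dtype=float)
    if y.size < 4:
        raise ValueError("need n >= 4 for the two-regressor model")
    X = sm.add_constant(np.column_stack([x1, x2]), has_constant="add")
    cond = float(np.linalg.cond(X))
    if cond > max_condition:
        raise np.linalg.LinAlgError(
            f"collinear design (condition number {cond:.3g})"
        )
    fit = sm.OLS(y, X).fit()
    return CovariateFit(
        beta0=float(fit.params[0]),
        beta_age=float(fit.params[1]),
        beta_fgmfwm=float(fit.params[2]),
        p_age=float(fit.pvalues[1]),
        p_fgmfwm=float(fit.pvalues[2]),
        n=int(y.size),
        condition_number=cond,
    )


def group_ttest(values, ages, cutoff: float = AGE_CUTOFF,
                welch: bool = True) -> GroupComparison:
    """Two-sample t-test between age < cutoff and age >= cutoff.

    Default is Welch's unequal-variance test; set ``welch=False`` for
    Student's pooled-variance variant. Subjects aged exactly at the
    cutoff belong to the older group.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    young = y[a < cutoff]
    old = y[a >= cutoff]
    if young.size == 0 or old.size == 0:
        raise ValueError("both age groups must be non-empty")
    res = sps.ttest_ind(young, old, equal_var=not welch)
    return GroupComparison(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        young_mean=float(young.mean()),
        young_sd=float(young.std(ddof=1)) if young.size > 1 else 0.0,
        old_mean=float(old.mean()),
        old_sd=float(old.std(ddof=1)) if old.size > 1 else 0.0,
        n_young=int(young.size),
        n_old=int(old.size),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m; flags use strict p < threshold."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return alpha / m


def analyze_cell(values, ages, fgmfwm, n_excluded: int = 0,
                 welch: bool = True) -> TrajectoryResult:
    """Run all three analyses on one cell, degrading gracefully."""
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    lin = cov = grp = None
    reasons = []
    try:
        lin = linear_trajectory(values, ages)
    except ValueError as exc:
        reasons.append(f"linear: {exc}")
    try:
        cov = covariate_regression(values, ages, fgmfwm)
    except (ValueError, np.linalg.LinAlgError) as exc:
        reasons.append(f"covariate: {exc}")
    try:
        grp = group_ttest(values, ages, welch=welch)
    except ValueError as exc:
        reasons.append(f"ttest: {exc}")
    return TrajectoryResult(lin, cov, grp, int(values.size), int(n_excluded),
                            analyzable=lin is not None,
                            reason="; ".join(reasons))


def run_trajectory_suite(table: pd.DataFrame,
                         fractions: pd.DataFrame,
                         alpha: float = 0.05,
                         welch: bool = True) -> pd.DataFrame:
    """Full statistics grid over a cohort table.

    Parameters
    ----------
    table : DataFrame
        Tidy cohort table (one row per subject/region/metabolite/model/
        parameter estimate) with at_lower_bound and valid flags.
    fractions : DataFrame
        Per (subject_id, region) tissue composition with an ``fgm_fwm``
        column.
    alpha : float
        Family-wise level for the t-test family; the per-test threshold
        is alpha / (n_regions * n_metabolites) within each
        (model, parameter) metric, matching a 2x3 design -> 0.05/6.

    Returns one row per (region, metabolite, model, parameter) cell.
    """
    filtered, log = exclude_at_bound(table)
    merged = filtered.merge(fractions[["subject_id", "region", "fgm_fwm"]],
                            on=["subject_id", "region"], how="left")
    excl_counts = (log.groupby(["region", "metabolite", "model", "parameter"])
                   .size() if len(log) else pd.Series(dtype=int))

    rows = []
    keys = ["region", "metabolite", "model", "parameter"]
    for (region, metab, model, param), cell in sorted(
            merged.groupby(keys), key=lambda kv: kv[0]):
        n_exc = int(excl_counts.get((region, metab, model, param), 0))
        res = analyze_cell(cell["estimate"].to_numpy(),
                           cell["age"].to_numpy(),
                           cell["fgm_fwm"].to_numpy(),
                           n_excluded=n_exc, welch=welch)
        row = dict(region=region, metabolite=metab, model=model,
                   parameter=param, n_used=res.n_used,
                   n_excluded=res.n_excluded, analyzable=res.analyzable)
        if res.linear is not None:
            row.update(slope=res.linear.slope, intercept=res.linear.intercept,
                       slope_se=res.linear.slope_se,
                       slope_p=res.linear.slope_p)
        if res.covariate is not None:
            row.update(beta_age=res.covariate.beta_age,
                       beta_fgmfwm=res.covariate.beta_fgmfwm,
                       p_age=res.covariate.p_age,
                       p_fgmfwm=res.covariate.p_fgmfwm)
        if res.group is not None:
            row.update(t_stat=res.group.t, t_df=res.group.df, t_p=res.group.p,
                       young_mean=res.group.young_mean,
                       young_sd=res.group.young_sd,
                       old_mean=res.group.old_mean,
                       old_sd=res.group.old_sd)
        rows.append(row)
    grid = pd.DataFrame(rows)
    if grid.empty:
        return grid
    # Bonferroni family: regions x metabolites within each (model, parameter)
    m_tests = grid["region"].nunique() * grid["metabolite"].nunique()
    thresh = bonferroni_threshold(alpha, m_tests)
    grid["t_threshold"] = thresh
    grid["t_significant"] = (grid.get("t_p", pd.Series(np.nan,
                                                       index=grid.index))
                             < thresh)
    return grid.sort_values(keys).reset_index(drop=True)
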