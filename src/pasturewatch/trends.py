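"""Mixed-effects spline trends of behavior over the grazing cycle.

For each behavioral variable, a linear mixed model describes the course
over cycle days 1-6: the fixed effect of day enters as a natural cubic
spline with 5 degrees of freedom (boundary knots at days 1 and 6, four
internal knots at days 2-5 — a saturated basis on six day levels, so the
fixed-effect predictions are adjusted day means), with a random intercept
per cow and a random day slope per paddock, estimated by REML.

Variables whose estimated trajectory over the last four cycle days does
not move consistently in one direction (or moves by less than the
estimation uncertainty) are flagged as low-relevance predictors and
dropped from the reduced predictor set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .errors import SchemaError
from .variables import BEHAVIOR_VARS

__all__ = ["TrendFit", "RelevanceFlag", "fit_day_spline", "flag_relevance", "plot_trends"]

#: Paddocks excluded from trend analysis by default (heavy rain on the
#: first paddock soiled the herbage and distorted grazing behavior).
DEFAULT_PADDOCK_EXCLUSIONS: tuple[int, ...] = (1,)

SPLINE_DF = 5


@dataclass
class TrendFit:
    """Estimated day-wise means of one variable with 95% confidence bounds."""

    variable: str
    days: np.ndarray  # evaluated cycle days (1..6)
    estimates: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    spline_df: int = SPLINE_DF
    internal_knots: tuple[float, ...] = (2, 3, 4, 5)
    boundary_knots: tuple[float, float] = (1, 6)
    random_effects: str = "intercept~cow + slope~paddock"
    excluded_paddocks: tuple[int, ...] = DEFAULT_PADDOCK_EXCLUSIONS
    converged: bool = True
    fit_type: str = "mixed_crossed"  # or "mixed_cow_intercept" / "ols"
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not (np.all(self.ci_lower <= self.estimates + 1e-9)
                and np.all(self.estimates <= self.ci_upper + 1e-9)):
            raise ValueError("confidence bounds must bracket the estimates")


@dataclass(frozen=True)
class RelevanceFlag:
    """Screening outcome for one variable: relevant iff it moves one way."""

    variable: str
    relevant: bool
    direction: str  # "increase", "decrease", or "none"
    rule: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.relevant != (self.direction != "none"):
            raise ValueError("relevant must be True exactly when a direction is set")


def _spline_formula(max_day: int) -> str:
    internal = list(range(2, max_day))
    return (
        f"0 + cr(day, knots={internal}, lower_bound=1, upper_bound={max_day})"
    )


def _basis(days: np.ndarray, max_day: int) -> np.ndarray:
    return np.asarray(
        patsy.dmatrix(_spline_formula(max_day), {"day": days}, return_type="matrix")
    )


def fit_day_spline(
    features: pd.DataFrame,
    variable: str,
    exclusions: tuple[int, ...] = DEFAULT_PADDOCK_EXCLUSIONS,
) -> TrendFit:
    """Fit the day-trend mixed model for one behavioral variable.

    ``features`` needs columns ``cow_id``, ``paddock_id``, ``day`` and the
    variable itself.  Rows from excluded paddocks are dropped before
    fitting.  On non-convergence the model falls back to a random-intercept
    -only fit and, failing that, to OLS on the spline basis; the
    ``fit_type`` and ``converged`` fields record what happened.
    """
    needed = {"cow_id", "paddock_id", "day", variable}
    if not needed <= set(features.columns):
        raise SchemaError(f"feature table missing columns: {sorted(needed - set(features.columns))}")
    df = features[~features["paddock_id"].isin(exclusions)].copy()
    if df["cow_id"].nunique() < 2 or df["paddock_id"].nunique() < 2:
        raise ValueError("need at least 2 cows and 2 paddocks after exclusions")
    max_day = int(df["day"].max())
    df["_one"] = 1
    formula = f"{variable} ~ {_spline_formula(max_day)}"
    pred_days = np.arange(1, max_day + 1)
    basis_new = _basis(pred_days, max_day)

    fit_type = "mixed_crossed"
    converged = True
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM.from_formula(
                formula,
                groups="_one",
                vc_formula={
                    "cow": "0 + C(cow_id)",
                    "paddock_slope": "0 + C(paddock_id):day",
                },
                data=df,
            )
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            res = None
        if res is None or not converged:
            fit_type = "mixed_cow_intercept"
            try:
                model = sm.MixedLM.from_formula(formula, groups="cow_id", data=df)
                res = model.fit(reml=True)
                converged = bool(res.converged)
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                res = None
        if res is None or not converged:
            fit_type = "ols"
            y, X = patsy.dmatrices(formula, df, return_type="dataframe")
            res = sm.OLS(np.asarray(y).ravel(), np.asarray(X)).fit()
            converged = True

    k = basis_new.shape[1]
    if fit_type == "ols":
        beta = np.asarray(res.params)[:k]
        cov = np.asarray(res.cov_params())[:k, :k]
    else:
        beta = res.fe_params.to_numpy()[:k]
        cov = np.asarray(res.cov_params())[:k, :k]
    est = basis_new @ beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", basis_new, cov, basis_new), 0.0))
    return TrendFit(
        variable=variable,
        days=pred_days,
        estimates=est,
        ci_lower=est - 1.96 * se,
        ci_upper=est + 1.96 * se,
        internal_knots=tuple(range(2, max_day)),
        boundary_knots=(1, max_day),
        excluded_paddocks=tuple(exclusions),
        converged=converged,
        fit_type=fit_type,
        n_obs=int(len(df)),
    )


def flag_relevance(
    fits: list[TrendFit],
    last_days: int = 4,
    require_ci_separation: bool = True,
) -> list[RelevanceFlag]:
    """Screen variables for a consistent directional change late in the cycle.

    A variable is relevant iff its estimated trajectory over the last
    ``last_days`` cycle days is monotone in one direction and (by default)
    the final day's estimate lies outside the confidence interval of the
    first of those days.  Requires a fit for every behavioral variable.
    """
    have = {f.variable for f in fits}
    missing = set(BEHAVIOR_VARS) - have
    if missing:
        raise ValueError(f"missing trend fits for: {sorted(missing)}")

    flags = []
    rule = dict(last_days=last_days, require_ci_separation=require_ci_separation)
    for fit in fits:
        traj = np.asarray(fit.estimates[-last_days:], dtype=float)
        diffs = np.diff(traj)
        increasing = bool(np.all(diffs > 0))
        decreasing = bool(np.all(diffs < 0))
        direction = "increase" if increasing else "decrease" if decreasing else "none"
        relevant = direction != "none"
        if relevant and require_ci_separation:
            i0 = len(fit.estimates) - last_days
            lo, hi = fit.ci_lower[i0], fit.ci_upper[i0]
            if lo <= traj[-1] <= hi:
                relevant, direction = False, "none"
        flags.append(
            RelevanceFlag(variable=fit.variable, relevant=relevant, direction=direction, rule=rule)
        )
    return flags


def trend_table(fits: list[TrendFit]) -> pd.DataFrame:
    """Long table of day estimates and CI bounds, one row per variable-day."""
    rows = []
    for f in fits:
        for d, est, lo, hi in zip(f.days, f.estimates, f.ci_lower, f.ci_upper):
            rows.append(
                dict(
                    variable=f.variable,
                    day=int(d),
                    estimate=est,
                    ci_lower=lo,
                    ci_upper=hi,
                    fit_type=f.fit_type,
                )
            )
    return pd.DataFrame(rows)


def plot_trends(fits: list[TrendFit], features: pd.DataFrame, path) -> None:
    """Violin plots of the raw data per day with the spline estimate overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(fits)
    ncols = min(4, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows), squeeze=False)
    for ax, fit in zip(axes.ravel(), fits):
        groups = [
            features.loc[features["day"] == d, fit.variable].dropna().to_numpy()
            for d in fit.days
        ]
        if all(len(g) > 1 for g in groups):
            ax.violinplot(groups, positions=fit.days, showmeans=False, showextrema=False)
        ax.plot(fit.days, fit.estimates, "-", color="black")
        ax.plot(fit.days, fit.ci_lower, "--", color="gray")
        ax.plot(fit.days, fit.ci_upper, "--", color="gray")
        ax.set_title(fit.variable)
        ax.set_xlabel("cycle day")
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
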