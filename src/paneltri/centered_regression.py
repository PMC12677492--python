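"""Person-mean centering and the three multilevel regressions (models 4-6).

Person-mean centering subtracts each person's own across-occasion average,
so a centered value of +1 means "one scale point above this person's usual
level at that occasion".  The three regressions probe a putative
increasing effect of X on Y from different angles, each on the stacked
single-lag frame (t -> t+1 for t = 1..T-1) with a person-level random
intercept, fitted by ML:

* model 4 (prospective): y_c(t+1) ~ x_c(t) + y_c(t); expected positive
  under a true increasing effect.
* model 5 (time-reversed): y_c(t) ~ x_c(t) + y_c(t+1); expected negative
  (compensation signature) under a true increasing effect.
* model 6 (crude change): (y(t+1) - y(t)) ~ x_c(t); expected positive.

With ``standardize=True`` (default) all analysis variables are grand-
standardized (each by its own standard deviation over the stacked frame)
before fitting, so coefficients are on the beta scale.  P-values use the
normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel import PanelDataset


@dataclass
class CenteredPanel:
    """Panel plus person-mean-centered scores ``x_c``, ``y_c``."""

    data: pd.DataFrame            # long, with x_c / y_c columns
    single_occasion_ids: list     # persons centered on one observation only

    @property
    def T(self) -> int:
        return int(self.data["occasion"].max())


def person_mean_center(panel: PanelDataset) -> CenteredPanel:
    """Center each person's scores on their own across-occasion mean.

    Persons observed at a single occasion get centered scores of exactly 0
    and are flagged in ``single_occasion_ids``.
    """
    df = panel.data.copy()
    if df.empty:
        raise ValueError("empty panel")
    g = df.groupby("person_id")
    df["x_c"] = df["x"] - g["x"].transform("mean")
    df["y_c"] = df["y"] - g["y"].transform("mean")
    counts = g["occasion"].count()
    singles = counts.index[counts == 1].tolist()
    return CenteredPanel(data=df, single_occasion_ids=singles)


def make_lagged_frame(centered: CenteredPanel) -> pd.DataFrame:
    """Stack adjacent-occasion records: one row per person per lag.

    Columns: person_id, t, x_c_t, y_c_t, x_c_t1, y_c_t1, dy (= y_{t+1} - y_t,
    identical on raw and centered scales).  Rows exist only where both
    occasions are observed.
    """
    df = centered.data
    left = df.rename(columns={"occasion": "t"})
    right = df.rename(columns={"occasion": "t"}).assign(t=lambda d: d["t"] - 1)
    merged = left.merge(right, on=["person_id", "t"], suffixes=("_t", "_t1"))
    out = pd.DataFrame({
        "person_id": merged["person_id"],
        "t": merged["t"],
        "x_c_t": merged["x_c_t"], "y_c_t": merged["y_c_t"],
        "x_c_t1": merged["x_c_t1"], "y_c_t1": merged["y_c_t1"],
        "dy": merged["y_t1"] - merged["y_t"],
        "dx": merged["x_t1"] - merged["x_t"],
    })
    return out.sort_values(["person_id", "t"]).reset_index(drop=True)


def fit_random_intercept(frame: pd.DataFrame, outcome: str, predictors: list[str],
                         standardize: bool = True) -> pd.DataFrame:
    """Random-intercept (person) linear model by ML; coefficient table.

    Returns one row per predictor with estimate, se, ci95 and the normal-
    approximation p-value.  With zero between-person variance the ML
    estimate sits at the boundary and the coefficients coincide with
    pooled OLS.
    """
    work = frame[[outcome, *predictors, "person_id"]].dropna().copy()
    if work["person_id"].nunique() < 2:
        raise ValueError("need at least two distinct persons")
    cols = [outcome, *predictors]
    if standardize:
        for c in cols:
            sd = work[c].std(ddof=1)
            if sd > 0:
                work[c] = work[c] / sd
    X = work[predictors].to_numpy(dtype=float)
    if len(predictors) > 1:
        corr = np.corrcoef(X, rowvar=False)
        iu = np.triu_indices(len(predictors), 1)
        worst = np.nanmax(np.abs(corr[iu]))
        if worst > 0.9999:
            i, j = [(a, b) for a, b in zip(*iu)][int(np.nanargmax(np.abs(corr[iu])))]
            raise ValueError(f"collinear predictors: {predictors[i]!r} and {predictors[j]!r}")
    exog = sm.add_constant(X)
    endog = work[outcome].to_numpy(dtype=float)
    model = sm.MixedLM(endog, exog, groups=work["person_id"].to_numpy())
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
            est = np.asarray(res.fe_params)[1:]
            se = np.asarray(res.bse_fe)[1:]
        except np.linalg.LinAlgError:
            # between-person variance at the 0 boundary: the ML solution
            # coincides with pooled OLS, whose information matrix is regular
            ols = sm.OLS(endog, exog).fit()
            est = np.asarray(ols.params)[1:]
            se = np.asarray(ols.bse)[1:]
    z = np.where(se > 0, est / se, np.nan)
    from scipy import stats
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({
        "predictor": predictors, "estimate": est, "se": se,
        "ci_lo": est - 1.959963984540054 * se,
        "ci_hi": est + 1.959963984540054 * se,
        "z": z, "p_value": p,
    }).set_index("predictor")


def run_model4(centered: CenteredPanel, direction: str = "xy",
               standardize: bool = True) -> pd.DataFrame:
    """Prospective: centered outcome at t+1 on centered predictor and outcome at t."""
    frame = make_lagged_frame(_oriented(centered, direction))
    return fit_random_intercept(frame, "y_c_t1", ["x_c_t", "y_c_t"], standardize)


def run_model5(centered: CenteredPanel, direction: str = "xy",
               standardize: bool = True) -> pd.DataFrame:
    """Time-reversed: centered outcome at t on centered predictor at t and outcome at t+1."""
    frame = make_lagged_frame(_oriented(centered, direction))
    return fit_random_intercept(frame, "y_c_t", ["x_c_t", "y_c_t1"], standardize)


def run_model6(centered: CenteredPanel, direction: str = "xy",
               standardize: bool = True) -> pd.DataFrame:
    """Crude change: outcome difference (t+1 minus t) on centered predictor at t."""
    frame = make_lagged_frame(_oriented(centered, direction))
    return fit_random_intercept(frame, "dy", ["x_c_t"], standardize)


def _oriented(centered: CenteredPanel, direction: str) -> CenteredPanel:
    if direction == "xy":
        return centered
    if direction != "yx":
        raise ValueError("direction must be 'xy' or 'yx'")
    df = centered.data.rename(columns={"x": "y", "y": "x", "x_c": "y_c", "y_c": "x_c"})
    return CenteredPanel(data=df, single_occasion_ids=centered.single_occasion_ids)
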