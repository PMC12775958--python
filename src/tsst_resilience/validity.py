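"""Validity of the resilience index: association with psychological distress.

A multiple linear regression of distress on the mean-centered resilience
index, mean-centered daily-stressor exposure, their product, major life
events, and demographic covariates. A negative index coefficient indicates
a protective (compensatory) association; a daily-stressor x index
interaction would indicate stress buffering. Centering the two interacting
terms removes the collinearity between main effects and product without
changing the interaction coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["DEFAULT_COVARIATES", "validity_regression", "ValidityResult"]

DEFAULT_COVARIATES = (
    "gender",
    "age",
    "education",
    "marital_status",
    "employment_status",
    "income",
    "medical_condition",
)

#: binary covariates are left 0/1 in the standardized pass
BINARY_COVARIATES = frozenset(
    {"gender", "education", "marital_status", "employment_status", "income", "medical_condition"}
)


class ValidityResult:
    """Coefficient table plus fit metadata for the validity regression."""

    def __init__(self, table: pd.DataFrame, n: int, r_squared: float, model):
        self.table = table
        self.n = n
        self.r_squared = r_squared
        self.model = model

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r_squared": self.r_squared,
            "terms": self.table.reset_index().to_dict(orient="records"),
        }


def _fit_ols(y, X):
    model = sm.OLS(y, X).fit()
    df_resid = model.df_resid
    t2 = model.tvalues**2
    partial_eta_sq = t2 / (t2 + df_resid)  # single-df identity SS/(SS+SSE)
    return model, partial_eta_sq


def validity_regression(
    distress,
    index,
    daily_stressors,
    major_life_events,
    demographics: pd.DataFrame | None = None,
    covariates=DEFAULT_COVARIATES,
) -> ValidityResult:
    """OLS of distress on the centered index, centered daily stressors,
    their interaction, major life events and demographic covariates.

    Reports raw and standardized coefficients (continuous variables
    z-scored, binaries left 0/1), 95 % confidence intervals, two-sided
    p-values and partial eta-squared per term.
    """
    y = np.asarray(distress, dtype=float)
    idx = np.asarray(index, dtype=float)
    daily = np.asarray(daily_stressors, dtype=float)
    major = np.asarray(major_life_events, dtype=float)
    n = y.size
    if not (idx.size == daily.size == major.size == n):
        raise ValueError("all inputs must have equal length")

    frame = pd.DataFrame(
        {
            "resilience_index": idx - idx.mean(),
            "daily_stressors": daily - daily.mean(),
        }
    )
    frame["index_x_daily"] = frame["resilience_index"] * frame["daily_stressors"]
    frame["major_life_events"] = major
    used_covs = []
    if demographics is not None:
        for cov in covariates:
            if cov not in demographics.columns:
                raise ValueError(f"demographic covariate {cov!r} missing")
            frame[cov] = np.asarray(demographics[cov], dtype=float)
            used_covs.append(cov)
    if frame.isna().any().any() or not np.all(np.isfinite(y)):
        raise ValueError("complete cases required; impute before fitting")
    if n <= frame.shape[1] + 2:
        raise ValueError("too few observations for the requested model")

    X = sm.add_constant(frame, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the error message
        bad = []
        cols = X.columns.tolist()
        for j in range(1, X.shape[1]):
            sub = X.drop(columns=cols[j]).to_numpy()
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(cols[j])
        raise ValueError(f"perfect collinearity among terms: {bad}")

    model, eta2 = _fit_ols(y, X)
    ci = model.conf_int(alpha=0.05)

    # standardized pass: z-score y and continuous regressors, binaries 0/1
    zy = (y - y.mean()) / y.std(ddof=1)
    zframe = frame.copy()
    for col in zframe.columns:
        if col in BINARY_COVARIATES:
            continue
        sd = zframe[col].std(ddof=1)
        if sd > 0:
            zframe[col] = (zframe[col] - zframe[col].mean()) / sd
    zmodel = sm.OLS(zy, sm.add_constant(zframe, has_constant="add")).fit()

    table = pd.DataFrame(
        {
            "coef": model.params,
            "std_beta": zmodel.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p_value": model.pvalues,
            "partial_eta_sq": eta2,
        }
    )
    table.index.name = "term"
    return ValidityResult(
        table=table, n=n, r_squared=float(model.rsquared), model=model
    )
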