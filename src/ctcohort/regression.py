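"""Hierarchical OLS variance decomposition: predictor vs tissue pH.

For a dependent transcript y, a predictor transcript x and tissue pH, three
ordinary-least-squares fits are run (x alone; pH alone; pH then x) and the
variance accounted for is decomposed as R2(x), R2(pH) and the increment
delta R2 = R2(pH + x) - R2(pH), i.e. what the predictor explains over and
above pH.  Standardized coefficients (beta) come from z-scored variables;
delta R2 significance uses the standard hierarchical F-change test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["RegressionDecomposition", "fit_decomposition"]


class RegressionError(ValueError):
    pass


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass
class RegressionDecomposition:
    dependent: str
    n: int
    r2_predictor_alone: float
    r2_ph_alone: float
    r2_full: float
    delta_r2: float
    f_change: float
    p_change: float
    beta_predictor_alone: float      # single-predictor (simple) model
    beta_ph_alone: float
    beta_predictor_full: float       # from the two-predictor model
    beta_ph_full: float
    beta_p_values: dict = field(default_factory=dict)
    stars: dict = field(default_factory=dict)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise RegressionError("zero-variance variable: standardization undefined")
    return (v - v.mean()) / sd


def fit_decomposition(
    dependent: np.ndarray | pd.Series,
    predictor: np.ndarray | pd.Series,
    ph: np.ndarray | pd.Series,
    dependent_name: str = "dependent",
) -> RegressionDecomposition:
    """Fit the three OLS models and report the R2 decomposition.

    Missing values are removed listwise across the three variables; the
    surviving n is reported.  beta values are emitted from both the simple
    and the two-predictor model, labelled, because published tables do not
    always say which model their pH beta comes from.
    """
    df = pd.DataFrame({
        "y": np.asarray(dependent, float),
        "x": np.asarray(predictor, float),
        "ph": np.asarray(ph, float),
    }).dropna()
    n = len(df)
    if n < 4:
        raise RegressionError(f"need >= 4 complete cases, got {n}")
    if df["y"].std(ddof=1) == 0:
        raise RegressionError("zero-variance dependent")
    corr_xp = np.corrcoef(df["x"], df["ph"])[0, 1]
    if df["x"].std(ddof=1) == 0 or df["ph"].std(ddof=1) == 0 or abs(corr_xp) > 1 - 1e-12:
        raise RegressionError("predictors are constant or perfectly collinear")

    y = _zscore(df["y"].to_numpy())
    x = _zscore(df["x"].to_numpy())
    p = _zscore(df["ph"].to_numpy())

    m_x = sm.OLS(y, sm.add_constant(x)).fit()
    m_p = sm.OLS(y, sm.add_constant(p)).fit()
    m_full = sm.OLS(y, sm.add_constant(np.column_stack([p, x]))).fit()

    r2_x, r2_p, r2_full = m_x.rsquared, m_p.rsquared, m_full.rsquared
    delta = r2_full - r2_p
    df_resid = n - 3
    if df_resid <= 0 or r2_full >= 1 - 1e-14:
        f_change = float("inf") if delta > 0 else 0.0
        p_change = 0.0 if delta > 0 else 1.0
    else:
        f_change = (delta / 1.0) / ((1.0 - r2_full) / df_resid)
        p_change = float(stats.f.sf(f_change, 1, df_resid))

    beta_p = {
        "predictor_alone": float(m_x.pvalues[1]),
        "ph_alone": float(m_p.pvalues[1]),
        "ph_full": float(m_full.pvalues[1]),
        "predictor_full": float(m_full.pvalues[2]),
    }
    return RegressionDecomposition(
        dependent=dependent_name,
        n=n,
        r2_predictor_alone=float(r2_x),
        r2_ph_alone=float(r2_p),
        r2_full=float(r2_full),
        delta_r2=float(delta),
        f_change=float(f_change),
        p_change=p_change,
        beta_predictor_alone=float(m_x.params[1]),
        beta_ph_alone=float(m_p.params[1]),
        beta_ph_full=float(m_full.params[1]),
        beta_predictor_full=float(m_full.params[2]),
        beta_p_values=beta_p,
        stars={"delta_r2": _stars(p_change),
               **{k: _stars(v) for k, v in beta_p.items()}},
    )
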