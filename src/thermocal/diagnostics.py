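"""Goodness-of-fit statistics and residual analysis for calibration models.

Observed values O (reference temperatures) are compared with simulated
values S (model predictions) through the usual battery: coefficient of
determination R^2 (squared Pearson correlation), RMSE, relative error
RE = 100*RMSE/mean(O), and Willmott's similarity index

    SI = 1 - sum (S-O)^2 / sum (|S - MO| + |O - MO|)^2,

where MO is the observed mean.  ``residual_diagnostics`` adds the standard
four-part residual screen: the observed~simulated regression line,
residual normality (Shapiro-Wilk), homoscedasticity (Breusch-Pagan), and
Cook's distance with a 4/n outlier threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import OLSInfluence

from .errors import UndefinedStatisticError


def _pair(observed, simulated) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float).ravel()
    s = np.asarray(simulated, dtype=float).ravel()
    if len(o) != len(s):
        raise ValueError(f"length mismatch: {len(o)} observed vs {len(s)} simulated")
    if len(o) == 0:
        raise ValueError("empty series")
    return o, s


def rmse(observed, simulated) -> float:
    """Root mean square error (same units as the inputs)."""
    o, s = _pair(observed, simulated)
    return float(np.sqrt(np.mean((s - o) ** 2)))


def r_squared(observed, simulated) -> float:
    """Coefficient of determination: squared Pearson correlation of O and S."""
    o, s = _pair(observed, simulated)
    if len(o) < 2:
        raise ValueError("need at least 2 observations")
    do, ds = o - o.mean(), s - s.mean()
    denom = np.sqrt((do**2).sum() * (ds**2).sum())
    if denom == 0:
        raise UndefinedStatisticError("zero variance in observed or simulated series")
    return float(((do * ds).sum() / denom) ** 2)


def relative_error(rmse_value: float, mean_obs: float) -> float:
    """Relative error in percent: 100 * RMSE / mean(observed)."""
    if mean_obs == 0:
        raise ValueError("relative error undefined for zero observed mean")
    return 100.0 * rmse_value / mean_obs


def similarity_index(observed, simulated, literal_form: bool = False) -> float:
    """Willmott-type index of agreement in (-inf, 1]; 1 means exact agreement.

    The default uses absolute deviations from the observed mean in the
    denominator (Willmott's d).  ``literal_form=True`` drops the absolute
    values, summing ((S-MO)+(O-MO))^2 instead; this variant can degenerate
    when deviations cancel and is provided for comparison only.
    """
    o, s = _pair(observed, simulated)
    mo = o.mean()
    if literal_form:
        denom = (((s - mo) + (o - mo)) ** 2).sum()
    else:
        denom = ((np.abs(s - mo) + np.abs(o - mo)) ** 2).sum()
    num = ((s - o) ** 2).sum()
    if denom == 0:
        if num == 0:
            return 1.0
        raise UndefinedStatisticError("similarity index denominator is zero")
    return float(1.0 - num / denom)


@dataclass(frozen=True)
class FitReport:
    """Bundle of the agreement statistics for one observed/simulated pairing."""

    n: int
    mean_obs: float
    mean_sim: float
    r2: float
    rmse: float
    relative_error: float  # percent
    similarity_index: float
    residuals: np.ndarray  # S - O, degrees C

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_obs": self.mean_obs,
            "mean_sim": self.mean_sim,
            "r2": self.r2,
            "rmse": self.rmse,
            "relative_error": self.relative_error,
            "similarity_index": self.similarity_index,
        }


def fit_report(observed, simulated) -> FitReport:
    """Compute all agreement statistics consistently on one pairing.

    The relative error uses this report's own RMSE and observed mean.
    """
    o, s = _pair(observed, simulated)
    if len(o) < 2:
        raise ValueError("need at least 2 observations")
    rm = rmse(o, s)
    return FitReport(
        n=len(o),
        mean_obs=float(o.mean()),
        mean_sim=float(s.mean()),
        r2=r_squared(o, s),
        rmse=rm,
        relative_error=relative_error(rm, float(o.mean())),
        similarity_index=similarity_index(o, s),
        residuals=s - o,
    )


@dataclass(frozen=True)
class ResidualDiagnostics:
    """Four-part residual screen of the observed ~ simulated regression."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    normality_p: float  # Shapiro-Wilk on the regression residuals
    homoscedasticity_p: float  # Breusch-Pagan (squared residuals on S)
    cooks_distances: np.ndarray
    outlier_flags: np.ndarray  # indices with Cook's distance > threshold
    cooks_threshold: float
    normality_test: str = "shapiro-wilk"
    homoscedasticity_test: str = "breusch-pagan"


def residual_diagnostics(observed, simulated) -> ResidualDiagnostics:
    """Regress observed on simulated and screen the residuals.

    Normality: Shapiro-Wilk p-value on the residuals.  Homoscedasticity:
    Breusch-Pagan Lagrange-multiplier p-value from the auxiliary regression
    of squared residuals on the simulated values.  Outliers: Cook's distance
    above 4/n.
    """
    o, s = _pair(observed, simulated)
    n = len(o)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(s) == 0:
        raise UndefinedStatisticError("constant simulated series: regression undefined")
    X = sm.add_constant(s)
    ols = sm.OLS(o, X).fit()
    resid = ols.resid
    _, norm_p = stats.shapiro(resid)
    _, bp_p, _, _ = het_breuschpagan(resid, X)
    cooks = OLSInfluence(ols).cooks_distance[0]
    threshold = 4.0 / n
    flags = np.flatnonzero(cooks > threshold)
    return ResidualDiagnostics(
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        slope_se=float(ols.bse[1]),
        intercept_se=float(ols.bse[0]),
        normality_p=float(norm_p),
        homoscedasticity_p=float(bp_p),
        cooks_distances=np.asarray(cooks, dtype=float),
        outlier_flags=flags,
        cooks_threshold=threshold,
    )
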