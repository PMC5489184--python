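"""Post-fit inference: effect functions with Bayesian intervals and summaries.

Pointwise 90% intervals use the Bayesian interpretation of the smoothing
spline: the posterior covariance of the penalized estimator is
sigma2 * (B'V^-1 B + Lambda)^-1, and each effect function's interval is
estimate +/- 1.645 * posterior SD.  Also houses the study's derived scalars:
the intra-class correlation, the dual R-squared pair, the delay-asymmetry
effect sizes d and d*, and the "successful smile" rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import VAR_COLUMNS

__all__ = [
    "EffectEstimate",
    "EffectSizes",
    "predict_effect",
    "icc",
    "dual_r_squared",
    "effect_sizes",
    "successful",
    "delay_zero_crossing",
    "plot_effect",
]


@dataclass
class EffectEstimate:
    """An effect function evaluated on a grid, with 90% Bayesian bounds."""

    grid: pd.DataFrame
    estimate: np.ndarray
    lower90: np.ndarray
    upper90: np.ndarray
    se: np.ndarray
    term: str = ""

    def to_frame(self) -> pd.DataFrame:
        out = self.grid.copy()
        out["estimate"] = self.estimate
        out["lower90"] = self.lower90
        out["upper90"] = self.upper90
        out["se"] = self.se
        return out


@dataclass
class EffectSizes:
    """Cohen's-d style effect sizes of the delay-asymmetry effect."""

    d: float       # eta_T(200) / sigma
    d_star: float  # [eta_T(75) - eta_T(200)] / sigma
    response: str = ""
    reference: str = "delay0"


def _grid_frame(fit, term: str, grid) -> pd.DataFrame:
    if isinstance(grid, pd.DataFrame):
        return grid.reset_index(drop=True)
    names = fit.model.design.resolve_terms(term)
    vars_ = sorted({v for t in names for v in t.split(":")})
    if len(vars_) != 1:
        raise ValueError(
            f"term {term!r} involves {vars_}; pass a DataFrame grid")
    return pd.DataFrame({VAR_COLUMNS[vars_[0]]: np.asarray(grid).ravel()})


def predict_effect(fit, term: str, grid, include_intercept: bool = False,
                   level: float = 0.90) -> EffectEstimate:
    """Posterior mean and pointwise Bayesian interval of one effect function.

    Parameters
    ----------
    fit : SSANOVAResults
    term : str
        A term name (``"age"``, ``"delay"``, ``"angle:extent"``, ...), a
        ``+``-joined combination, ``"smile"`` (all spatial terms plus the
        intercept is added when ``include_intercept``), or ``"intercept"``.
    grid : array or DataFrame
        Points at which to evaluate; an array is accepted for single-variable
        terms (raw covariate scale, e.g. delay in ms).
    """
    design = fit.model.design
    if term == "intercept":
        gdf = grid if isinstance(grid, pd.DataFrame) else pd.DataFrame(
            index=range(np.size(grid) or 1))
        X = np.zeros((len(gdf), design.n_cols))
        X[:, 0] = 1.0
    else:
        gdf = _grid_frame(fit, term, grid)
        X = design.term_rows(term, gdf, include_intercept=include_intercept)
    est = X @ fit.params
    cov = fit.sigma2 * fit.cov_unscaled
    var = np.einsum("ij,jk,ik->i", X, cov, X)
    se = np.sqrt(np.maximum(var, 0.0))
    z = norm.ppf(0.5 + level / 2.0)
    return EffectEstimate(grid=gdf, estimate=est, lower90=est - z * se,
                          upper90=est + z * se, se=se, term=term)


def icc(theta2: float, sigma2: float) -> float:
    """Intra-class correlation rho = theta2 / (theta2 + sigma2).

    The share of rating variance attributable to stable between-participant
    baseline differences.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if theta2 < 0:
        raise ValueError("theta2 must be non-negative")
    return theta2 / (theta2 + sigma2)


def dual_r_squared(fit, data: pd.DataFrame | None = None) -> tuple[float, float]:
    """(R2, R*2): squared correlation of the response with the fitted values
    excluding / including the participant random effects."""
    if data is None:
        data = fit.model.data
    y = data[fit.spec.response].to_numpy(float)
    fixed = fit.fitted_fixed
    pid = data["participant_id"].to_numpy()
    b = fit.blups.reindex(pid).fillna(0.0).to_numpy()

    def sqcorr(a, v):
        if np.std(v) == 0:
            warnings.warn("zero-variance fitted values; R^2 undefined", UserWarning)
            return np.nan
        return float(np.corrcoef(a, v)[0, 1] ** 2)

    return sqcorr(y, fixed), sqcorr(y, fixed + b)


def effect_sizes(fit, reference: str = "delay0") -> EffectSizes:
    """Delay-asymmetry effect sizes d and d*.

    d = eta_T(200)/sigma and d* = [eta_T(75) - eta_T(200)]/sigma, with the
    cubic delay spline evaluated at 75 ms (between design points).  With
    ``reference="delay0"`` (default) eta_T is referenced so eta_T(0) = 0,
    matching "units below the symmetric (zero-delay) smile"; with
    ``reference="centered"`` the raw centered effect is used.
    """
    if "delay" not in {t.name for t in fit.model.design.terms}:
        raise ValueError("fit has no delay-asymmetry term eta_T")
    if reference not in ("delay0", "centered"):
        raise ValueError("reference must be 'delay0' or 'centered'")
    eff = predict_effect(fit, "delay", np.array([0.0, 75.0, 200.0]))
    e0, e75, e200 = eff.estimate
    if reference == "delay0":
        e75, e200 = e75 - e0, e200 - e0
    sigma = np.sqrt(fit.sigma2)
    return EffectSizes(d=float(e200 / sigma), d_star=float((e75 - e200) / sigma),
                       response=fit.spec.response, reference=reference)


def successful(pred_effective: float, pred_genuine: float,
               pred_pleasant: float) -> bool:
    """A smile is successful iff all three predicted ratings strictly exceed
    the neutral value 0.5 on the coded [0, 1] scale."""
    return bool(pred_effective > 0.5 and pred_genuine > 0.5
                and pred_pleasant > 0.5)


def delay_zero_crossing(fit, step: float = 1.0) -> float:
    """Delay (ms) at which the fitted eta_T, referenced to delay 0, crosses
    from the early positive bump back below zero.

    Returns the linearly interpolated crossing after the curve's maximum;
    NaN if the curve never returns below zero.
    """
    t = np.arange(0.0, 200.0 + step / 2, step)
    eff = predict_effect(fit, "delay", t)
    rel = eff.estimate - eff.estimate[0]
    i0 = int(np.argmax(rel))
    for i in range(max(i0, 1), len(t)):
        if rel[i] <= 0.0:
            if rel[i] == rel[i - 1]:
                return float(t[i])
            frac = rel[i - 1] / (rel[i - 1] - rel[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return float("nan")


def plot_effect(fit, term: str, grid, ax=None, **kwargs):
    """Plot an effect function with its shaded 90% Bayesian band."""
    import matplotlib.pyplot as plt

    eff = predict_effect(fit, term, grid, **kwargs)
    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(eff.estimate))
    if eff.grid.shape[1] == 1 and np.issubdtype(eff.grid.dtypes.iloc[0], np.number):
        x = eff.grid.iloc[:, 0].to_numpy()
        ax.fill_between(x, eff.lower90, eff.upper90, alpha=0.3)
        ax.plot(x, eff.estimate)
    else:
        ax.errorbar(x, eff.estimate,
                    yerr=[eff.estimate - eff.lower90, eff.upper90 - eff.estimate],
                    fmt="o")
    ax.set_xlabel(", ".join(eff.grid.columns))
    ax.set_ylabel(f"effect: {term}")
    return ax
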