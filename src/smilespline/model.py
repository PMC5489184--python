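"""Random-intercept smoothing-spline ANOVA models for smile ratings.

The response of participant *i* to stimulus *j* is modelled as

    y_ij = eta(x_ij) + b_i + eps_ij,   b_i ~ N(0, theta2),  eps ~ N(0, sigma2)

where eta decomposes into covariate main effects (cubic splines for age and
drinks, a shrinkage effect for gender) plus either a spatial smile-effect
function eta_S over the (angle, extent, dental-show) factor cube — itself
decomposed into ordinal main effects and tensor-product interactions — or a
cubic delay-asymmetry effect eta_T.

Estimation is the two-step procedure used with these models in practice:
(1) REML on a working parametric mixed model estimates the participant
random-intercept variance theta2; (2) with the implied correlation structure
fixed, the penalized representer problem is solved on whitened data with one
smoothing parameter per term, chosen by minimizing the GCV criterion
V(lambda) = n RSS(lambda) / (n - tr S_lambda)^2.

Usage follows the statsmodels convention: build :class:`MixedSSANOVA` from a
long-format rating table, call :meth:`~MixedSSANOVA.fit`, inspect the returned
:class:`SSANOVAResults` (and its ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize, minimize_scalar

from .design import ModelDesign, VAR_COLUMNS

__all__ = [
    "ModelSpec",
    "enumerate_smile_models",
    "estimate_random_intercept",
    "MixedSSANOVA",
    "SSANOVAResults",
    "information_criteria",
    "select_model",
]

RESPONSES = ("effective", "genuine", "pleasant")
SMILE_MAINS = ("angle", "extent", "dental")
TWO_WAYS = ("angle:extent", "angle:dental", "extent:dental")
THREE_WAY = "angle:extent:dental"
COVARIATE_TERMS = ("age", "gender", "drinks")


@dataclass(frozen=True)
class ModelSpec:
    """Which terms one candidate rating model contains.

    Every spec carries the three covariate effects (age, gender, drinks).
    Symmetric specs always contain the three spatial main effects and the
    constant; ``interactions`` selects which tensor-product terms join them,
    hierarchically (the three-way requires all three two-ways).  Asymmetric
    specs replace the spatial terms by the single delay effect.
    """

    response: str
    kind: str = "symmetric"  # or "asymmetric"
    interactions: tuple[str, ...] = ()
    label: str = ""

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        if self.kind not in ("symmetric", "asymmetric"):
            raise ValueError("kind must be 'symmetric' or 'asymmetric'")
        inter = tuple(self.interactions)
        if self.kind == "asymmetric" and inter:
            raise ValueError("asymmetric model has no spatial interactions")
        bad = set(inter) - set(TWO_WAYS) - {THREE_WAY}
        if bad:
            raise ValueError(f"unknown interaction terms {sorted(bad)}")
        if THREE_WAY in inter and not set(TWO_WAYS) <= set(inter):
            raise ValueError(
                "hierarchical lattice: the three-way interaction requires all "
                "three two-way interactions")

    @property
    def stimulus_terms(self) -> tuple[str, ...]:
        if self.kind == "asymmetric":
            return ("delay",)
        return SMILE_MAINS + tuple(self.interactions)

    @property
    def terms(self) -> tuple[str, ...]:
        return COVARIATE_TERMS + self.stimulus_terms

    @property
    def n_smile_terms(self) -> int:
        """Number of eta terms in the smile-effect decomposition (incl. eta_0)."""
        return 1 + len(self.stimulus_terms)


def enumerate_smile_models(response: str = "effective") -> list[ModelSpec]:
    """The nine hierarchical candidate decompositions of the smile effect.

    Ordered from the full model (all two-ways plus the three-way) down to the
    purely additive model.
    """
    ae, ad, ed = TWO_WAYS
    combos = [
        (ae, ad, ed, THREE_WAY),
        (ae, ad, ed),
        (ae, ad),
        (ae, ed),
        (ad, ed),
        (ae,),
        (ad,),
        (ed,),
        (),
    ]
    return [
        ModelSpec(response, "symmetric", c, label=str(i + 1))
        for i, c in enumerate(combos)
    ]


# ---------------------------------------------------------------------------
# step 1: REML for the participant variance component
# ---------------------------------------------------------------------------

def _reml_profile(y: np.ndarray, X: np.ndarray, groups: list[np.ndarray]
                  ) -> tuple[float, float]:
    """Exact profiled REML for a Gaussian random-intercept model.

    With V = I + gamma ZZ' the REML criterion profiles out beta and sigma2,
    leaving a one-dimensional problem in gamma = theta2/sigma2, solved by
    bounded scalar minimization on the log scale with an explicit boundary
    check at gamma = 0.
    """
    n, p = X.shape
    XX = X.T @ X
    Xy = X.T @ y
    yy = float(y @ y)
    GS = np.stack([X[i].sum(axis=0) for i in groups])
    gy = np.array([float(y[i].sum()) for i in groups])
    ns = np.array([len(i) for i in groups], dtype=float)

    def crit(gamma: float) -> tuple[float, float]:
        w = gamma / (1.0 + gamma * ns)
        XVX = XX - (GS.T * w) @ GS
        XVy = Xy - GS.T @ (w * gy)
        yVy = yy - float(np.sum(w * gy * gy))
        beta = np.linalg.lstsq(XVX, XVy, rcond=None)[0]
        rss = max(yVy - float(beta @ XVy), 1e-300)
        s2 = rss / (n - p)
        _, ld1 = np.linalg.slogdet(XVX)
        ldV = float(np.sum(np.log1p(gamma * ns)))
        return (n - p) * np.log(s2) + ldV + ld1, s2

    res = minimize_scalar(lambda lg: crit(np.exp(lg))[0],
                          bounds=(-18.0, 6.0), method="bounded",
                          options={"xatol": 1e-10})
    gamma = float(np.exp(res.x))
    f0, s2_0 = crit(0.0)
    f1, s2_1 = crit(gamma)
    if f0 <= f1:
        return 0.0, s2_0
    return gamma * s2_1, s2_1


def estimate_random_intercept(data: pd.DataFrame, spec: ModelSpec
                              ) -> tuple[float, float]:
    """REML estimates (theta2, sigma2) of the variance components.

    Uses a working linear mixed model with participant random intercepts and a
    saturated parametric proxy for the fixed effects: cell-mean dummies for
    the stimuli (27 smiles or 6 delays), linear age and drinks, and a gender
    dummy.  The proxy is rich enough that theta2 is not inflated by
    fixed-effect misfit, and it does not depend on which spline interactions a
    candidate model contains.  The random-intercept structure admits an exact
    one-dimensional profiled REML, solved directly.
    """
    counts = data["participant_id"].value_counts()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        warnings.warn(
            "random-intercept variance unidentifiable: need >= 2 participants "
            "with >= 2 observations each; returning theta2 = 0",
            UserWarning,
        )
        resid = data[spec.response] - data[spec.response].mean()
        return 0.0, float(np.var(resid, ddof=1))

    cell = "smile_index" if spec.kind == "symmetric" else "delay_ms"
    y = data[spec.response].to_numpy(float)
    cols = [np.ones(len(data))]
    if data[cell].nunique() > 1:
        dummies = pd.get_dummies(data[cell], drop_first=True)
        cols.append(dummies.to_numpy(float))
    for c in ("age", "drinks"):
        if data[c].nunique() > 1:
            cols.append(data[c].to_numpy(float)[:, None])
    if data["gender"].nunique() > 1:
        cols.append((data["gender"].to_numpy(object) == "M"
                     ).astype(float)[:, None])
    X = np.column_stack(cols)
    groups = _group_indices(data["participant_id"].to_numpy())
    return _reml_profile(y, X, groups)


# ---------------------------------------------------------------------------
# whitening for the compound-symmetric observation covariance
# ---------------------------------------------------------------------------

def _group_indices(pid: np.ndarray) -> list[np.ndarray]:
    order = pd.Series(pid)
    return [idx.to_numpy() for _, idx in order.groupby(order, sort=False).groups.items()]


def _whiten(B: np.ndarray, y: np.ndarray, groups: list[np.ndarray],
            gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Apply V^{-1/2} blockwise, V_i = I + gamma * J_{n_i}."""
    Bt = B.copy()
    yt = y.copy()
    if gamma > 0:
        for idx in groups:
            ni = len(idx)
            a = (1.0 - 1.0 / np.sqrt(1.0 + gamma * ni)) / ni
            Bt[idx] -= a * Bt[idx].sum(axis=0)
            yt[idx] -= a * yt[idx].sum()
    return Bt, yt


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

class MixedSSANOVA:
    """Mixed-effects SSANOVA model bound to a rating table.

    Parameters
    ----------
    data : DataFrame
        Long-format ratings (one row per participant x stimulus) with the
        canonical columns; symmetric specs need ``angle_level`` etc.,
        asymmetric specs need a non-null ``delay_ms``.
    spec : ModelSpec
    terms : sequence of str, optional
        Override the term list (advanced use; defaults to ``spec.terms``).
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec,
                 terms: tuple[str, ...] | None = None):
        self.spec = spec
        term_names = list(terms if terms is not None else spec.terms)
        needed = [VAR_COLUMNS[v] for t in term_names for v in t.split(":")]
        data = data.reset_index(drop=True)
        if data[spec.response].isna().any():
            raise ValueError(f"response {spec.response!r} contains missing values")
        for c in needed:
            if data[c].isna().any():
                raise ValueError(f"covariate column {c!r} contains missing values")
        self.data = data
        self.y = data[spec.response].to_numpy(float)
        self.n = len(data)
        self.design = ModelDesign(term_names, data)
        self.groups = _group_indices(data["participant_id"].to_numpy())

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       kind: str = "symmetric",
                       interactions: tuple[str, ...] = ()) -> "MixedSSANOVA":
        return cls(data, ModelSpec(response, kind, tuple(interactions)))

    # -- GCV machinery ------------------------------------------------------

    def _gcv_parts(self, gamma: float):
        Bt, yt = _whiten(self.design.matrix, self.y, self.groups, gamma)
        M0 = Bt.T @ Bt
        b0 = Bt.T @ yt
        yy = float(yt @ yt)
        return M0, b0, yy

    def _solve(self, M0, b0, loglam):
        n = self.n
        M = M0.copy()
        for lb, blk in zip(loglam, self.design.penalties):
            # +-40 in log lambda is numerically none/infinite smoothing
            lam = np.exp(np.clip(lb, -40.0, 40.0))
            M[blk.cols, blk.cols] += n * lam * blk.matrix
        try:
            c, low = sla.cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            warnings.warn("near-singular penalized system; ridge-stabilizing",
                          UserWarning)
            jitter = 1e-10 * max(np.trace(M) / M.shape[0], 1.0)
            c, low = sla.cho_factor(M + jitter * np.eye(M.shape[0]), lower=True,
                                    check_finite=False)
        beta = sla.cho_solve((c, low), b0, check_finite=False)
        # one step of iterative refinement: the kernel Gram blocks are
        # ill-conditioned and the raw solve can leave O(1e-4) residuals
        beta += sla.cho_solve((c, low), b0 - M @ beta, check_finite=False)
        trS = float(np.trace(sla.cho_solve((c, low), M0, check_finite=False)))
        return beta, trS, (c, low)

    def _gcv(self, loglam, M0, b0, yy):
        beta, trS, _ = self._solve(M0, b0, loglam)
        rss = max(yy - 2.0 * float(beta @ b0) + float(beta @ (M0 @ beta)), 0.0)
        denom = max(self.n - trS, 1e-6)
        return self.n * rss / denom ** 2

    def gcv_score(self, loglam, gamma: float = 0.0) -> float:
        """GCV criterion V(lambda) at the given log smoothing parameters."""
        M0, b0, yy = self._gcv_parts(gamma)
        return self._gcv(np.atleast_1d(np.asarray(loglam, float)), M0, b0, yy)

    def _optimize_gcv(self, M0, b0, yy, maxfev=None):
        k = len(self.design.penalties)
        obj = lambda x: self._gcv(x, M0, b0, yy)
        # deterministic coordinate-wise coarse-grid pre-scan from log lambda=0:
        # joint Nelder-Mead alone is sensitive to its start when terms differ
        # by orders of magnitude in the right amount of smoothing
        x0 = np.zeros(k)
        grid = np.arange(-12.0, 12.01, 1.5)
        for _ in range(2):
            for j in range(k):
                vals = []
                for g in grid:
                    xt = x0.copy()
                    xt[j] = g
                    vals.append(obj(xt))
                x0[j] = grid[int(np.argmin(vals))]
        if maxfev is None:
            maxfev = min(200 * k, 1500)
        res = minimize(obj, x0, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": 1e-4, "fatol": 1e-8})
        best_x, best_v = res.x, res.fun
        if obj(x0) < best_v:
            best_x, best_v = x0, obj(x0)
        # coordinate-wise Brent refinement: pins each log lambda tightly so
        # that models sharing terms converge to the same shared optima
        x = best_x.copy()
        for _ in range(2):
            for j in range(k):
                r1 = minimize_scalar(
                    lambda g: obj(np.concatenate([x[:j], [g], x[j + 1:]])),
                    bounds=(x[j] - 2.0, x[j] + 2.0), method="bounded",
                    options={"xatol": 1e-6})
                if r1.fun <= obj(x):
                    x[j] = r1.x
        if obj(x) <= best_v:
            best_x, best_v = x, obj(x)
        if not np.isfinite(best_v):
            # brute-force coordinate-descent grid fallback
            x = np.zeros(k)
            grid = np.arange(-15.0, 15.01, 0.5)
            for _ in range(2):
                for j in range(k):
                    vals = []
                    for g in grid:
                        xt = x.copy()
                        xt[j] = g
                        vals.append(obj(xt))
                    x[j] = grid[int(np.argmin(vals))]
            v = obj(x)
            if v < best_v or not np.isfinite(best_v):
                best_x, best_v = x, v
            if not np.isfinite(best_v):
                raise RuntimeError(
                    "GCV optimization failed to produce a finite criterion; "
                    f"last point {best_x}")
        return best_x, best_v

    # -- fitting ------------------------------------------------------------

    def fit(self, theta2: float | None = None, sigma2: float | None = None,
            lambdas: np.ndarray | None = None,
            maxfev: int | None = None) -> "SSANOVAResults":
        """Two-step fit: REML for theta2 (unless given), then GCV for lambda.

        Parameters
        ----------
        theta2, sigma2 : float, optional
            Variance components from a previous REML step; estimated here if
            omitted.  ``theta2=0`` fits an independent-errors model.
        lambdas : array, optional
            Fixed smoothing parameters (natural scale, one per penalized
            term), bypassing GCV — used for oracle comparisons.
        """
        if theta2 is None:
            theta2, sigma2 = estimate_random_intercept(self.data, self.spec)
        if sigma2 is None or sigma2 <= 0:
            sigma2 = max(float(np.var(self.y, ddof=1)), 1e-12)
        gamma = max(theta2, 0.0) / sigma2
        M0, b0, yy = self._gcv_parts(gamma)
        if lambdas is not None:
            loglam = np.log(np.asarray(lambdas, float))
            gcv = self._gcv(loglam, M0, b0, yy)
        else:
            loglam, gcv = self._optimize_gcv(M0, b0, yy, maxfev=maxfev)
        beta, trS, (c, low) = self._solve(M0, b0, loglam)
        rss = max(yy - 2.0 * float(beta @ b0) + float(beta @ (M0 @ beta)), 0.0)
        edf = trS
        sigma2_hat = max(rss / max(self.n - edf, 1.0), 1e-12)
        Minv = sla.cho_solve((c, low), np.eye(M0.shape[0]), check_finite=False)

        fitted_fixed = self.design.matrix @ beta
        resid = self.y - fitted_fixed
        blups = {}
        pid = self.data["participant_id"].to_numpy()
        for idx in self.groups:
            ni = len(idx)
            shrink = gamma * ni / (1.0 + gamma * ni) if gamma > 0 else 0.0
            blups[pid[idx[0]]] = shrink * resid[idx].mean()
        blup_s = pd.Series(blups, name="blup")
        b_vec = blup_s.reindex(pid).to_numpy()

        def sqcorr(a, b):
            if np.std(a) == 0 or np.std(b) == 0:
                warnings.warn("zero-variance fitted values; R^2 undefined",
                              UserWarning)
                return np.nan
            return float(np.corrcoef(a, b)[0, 1] ** 2)

        r2 = sqcorr(self.y, fitted_fixed)
        r2_star = sqcorr(self.y, fitted_fixed + b_vec)

        loglik = _mixed_loglik(resid, self.groups, theta2, sigma2_hat)
        df = edf + 2.0  # + (sigma2, theta2)
        aic = -2.0 * loglik + 2.0 * df
        bic = -2.0 * loglik + np.log(self.n) * df

        return SSANOVAResults(
            model=self, spec=self.spec, params=beta,
            lambdas={blk.name: float(np.exp(np.clip(lb, -40.0, 40.0)))
                     for lb, blk in zip(loglam, self.design.penalties)},
            theta2=float(theta2), sigma2=float(sigma2_hat),
            blups=blup_s, fitted_fixed=fitted_fixed, edf=float(edf),
            gcv=float(gcv) if lambdas is None else float(self._gcv(loglam, M0, b0, yy)),
            loglik=float(loglik), aic=float(aic), bic=float(bic),
            r2=r2, r2_star=r2_star, cov_unscaled=Minv,
        )


def _mixed_loglik(resid: np.ndarray, groups: list[np.ndarray],
                  theta2: float, sigma2: float) -> float:
    """Gaussian marginal log-likelihood with Sigma = sigma2 I + theta2 ZZ'."""
    n = resid.size
    gamma = theta2 / sigma2
    quad = float(resid @ resid)
    logdet = n * np.log(sigma2)
    for idx in groups:
        ni = len(idx)
        s = float(resid[idx].sum())
        quad -= gamma / (1.0 + gamma * ni) * s * s
        logdet += np.log1p(gamma * ni)
    quad /= sigma2
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


@dataclass
class SSANOVAResults:
    """Fitted mixed-effects SSANOVA model.

    Attributes mirror the quantities reported for these models: smoothing
    parameters per term, variance components (theta2, sigma2), participant
    BLUPs, effective degrees of freedom (trace of the smoother matrix),
    AIC/BIC, the dual R-squared pair and the intra-class correlation rho.
    """

    model: MixedSSANOVA
    spec: ModelSpec
    params: np.ndarray
    lambdas: dict[str, float]
    theta2: float
    sigma2: float
    blups: pd.Series
    fitted_fixed: np.ndarray
    edf: float
    gcv: float
    loglik: float
    aic: float
    bic: float
    r2: float
    r2_star: float
    cov_unscaled: np.ndarray = field(repr=False, default=None)

    @property
    def rho(self) -> float:
        """Intra-class correlation theta2 / (theta2 + sigma2)."""
        return self.theta2 / (self.theta2 + self.sigma2)

    @property
    def n(self) -> int:
        return self.model.n

    def predict_effect(self, term: str, grid, include_intercept: bool = False,
                       level: float = 0.90):
        from .effects import predict_effect
        return predict_effect(self, term, grid,
                              include_intercept=include_intercept, level=level)

    def effect_sizes(self, reference: str = "delay0"):
        from .effects import effect_sizes
        return effect_sizes(self, reference=reference)

    def plot_effect(self, term: str, grid, ax=None, **kwargs):
        from .effects import plot_effect
        return plot_effect(self, term, grid, ax=ax, **kwargs)

    def summary(self) -> str:
        spec = self.spec
        lines = [
            "Mixed-effects SSANOVA results",
            "=" * 46,
            f"response:        {spec.response}",
            f"stimulus model:  {spec.kind}"
            + (f" (model {spec.label})" if spec.label else ""),
            f"terms:           {', '.join(spec.terms)}",
            f"n obs:           {self.n}",
            f"n participants:  {len(self.blups)}",
            "-" * 46,
            f"edf (tr S):      {self.edf:10.2f}",
            f"sigma2:          {self.sigma2:10.4f}",
            f"theta2:          {self.theta2:10.4f}",
            f"rho (ICC):       {self.rho:10.4f}",
            f"R2 / R*2:        {self.r2:10.4f} / {self.r2_star:.4f}",
            f"logLik:          {self.loglik:10.2f}",
            f"AIC / BIC:       {self.aic:10.2f} / {self.bic:.2f}",
            "-" * 46,
            "smoothing parameters (GCV):",
        ]
        for name, lam in self.lambdas.items():
            lines.append(f"  {name:<22s} {lam:12.4e}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model scores and selection
# ---------------------------------------------------------------------------

def information_criteria(fit: SSANOVAResults, offset: float = 0.0
                         ) -> tuple[float, float]:
    """(AIC, BIC) of a fit, shifted by ``offset``.

    AIC = -2 loglik + 2 df and BIC = -2 loglik + log(n) df with
    df = edf + 2 variance parameters.  Absolute scores are
    convention-dependent; only differences within one response matter.
    """
    return fit.aic + offset, fit.bic + offset


def select_model(fits: list[SSANOVAResults], criterion: str = "aic"
                 ) -> SSANOVAResults:
    """Return the fit minimizing AIC (ties broken by fewer smile terms).

    Score differences below 0.01 — far beneath any meaningful evidence
    threshold, and the numerical precision of the smoothing-parameter search —
    count as ties, resolved deterministically toward parsimony.  Also records
    on the winner whether BIC agrees (``bic_agrees`` attribute).
    """
    if not fits:
        raise ValueError("no fits to select from")
    responses = {f.spec.response for f in fits}
    if len(responses) > 1:
        raise ValueError("fits compare different responses")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")

    def key(attr):
        return lambda f: (round(getattr(f, attr) * 100) / 100,
                          f.spec.n_smile_terms)

    best = min(fits, key=key(criterion))
    bic_best = min(fits, key=key("bic"))
    best.bic_agrees = bic_best.spec == best.spec
    return best
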