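"""Abundance point estimates and confidence intervals.

Three estimators, all operating on counts within sampled model polygons:

direct extrapolation
    abundance = haulout area x area-weighted mean plot density; the 95% CI
    multiplies empirical 2.5/97.5% quantiles of normal draws
    N(mean density, SD of plot densities) by the haulout area.

linear model
    OLS of plot count on plot area; the haulout abundance is the predicted
    mean response at the full haulout area with a z x SE(mean prediction) CI.
    Predicting at the whole-haulout area is far outside the plot-area range;
    an ExtrapolationWarning is emitted but the prediction is made.

negative-binomial GLM
    counts ~ terrain + offset(log area), log link, dispersion theta
    (Var = mu + mu^2/theta) estimated by alternating IRLS (beta given theta)
    and univariate ML (theta given beta) from theta_init = 0.1.  Predictions
    exponentiate the linear predictor; the CI moves the delta-method variance
    onto the log scale, var(log c) = log(1 + var(c)/c^2), and takes
    c * exp(-/+ 2 sd(log c)) — an asymmetric, strictly positive interval.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import optimize, special

from .counts import PolygonCountSummary
from .geometry import Terrain


class ExtrapolationWarning(UserWarning):
    """Prediction requested far outside the fitted plot-area range."""


@dataclass
class AbundanceEstimate:
    method: str
    site_id: str
    survey_date: "dt.date | None"
    point: float
    ci_lower: float
    ci_upper: float
    n_polygons: "int | None" = None
    lower_floored: bool = False  # negative lower bound clamped to 0

    def __post_init__(self) -> None:
        if not (self.ci_lower <= self.point + 1e-9 and self.point <= self.ci_upper + 1e-9):
            raise ValueError(
                f"CI bounds must bracket the point estimate: "
                f"({self.ci_lower}, {self.point}, {self.ci_upper})"
            )


def direct_extrapolation(
    area: float,
    mean_density: float,
    sd_density: float,
    n_sims: int = 10_000,
    seed: "int | None" = None,
    rng: "np.random.Generator | None" = None,
    site_id: str = "",
    survey_date: "dt.date | None" = None,
    n_polygons: "int | None" = None,
) -> AbundanceEstimate:
    """Extrapolate the survey-level density over the whole haulout area.

    The CI is simulation-based: empirical 2.5% and 97.5% quantiles of
    ``n_sims`` draws from N(mean_density, sd_density), each multiplied by the
    haulout area.  ``sd_density`` is the SD of plot densities (not the SE of
    their mean), so the interval reflects plot-to-plot density variability.
    A negative lower bound is floored at 0 and flagged.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    if sd_density < 0:
        raise ValueError("sd_density must be non-negative")
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    point = area * mean_density
    if sd_density == 0:
        lo = hi = point
    else:
        rng = rng if rng is not None else np.random.default_rng(seed)
        draws = rng.normal(mean_density, sd_density, size=n_sims)
        qlo, qhi = np.quantile(draws, [0.025, 0.975])
        lo, hi = area * qlo, area * qhi
    floored = lo < 0
    return AbundanceEstimate(
        method="direct_extrapolation", site_id=site_id, survey_date=survey_date,
        point=point, ci_lower=max(0.0, lo), ci_upper=hi,
        n_polygons=n_polygons, lower_floored=bool(floored),
    )


# ---------------------------------------------------------------- linear model


@dataclass
class LinearFit:
    """OLS fit of plot count on plot area (with intercept)."""

    intercept: float
    slope: float
    cov: np.ndarray          # 2x2 covariance of (intercept, slope)
    resid_var: float         # residual mean square, df = n - 2
    n: int
    area_min: float
    area_max: float


def fit_linear(counts, areas) -> LinearFit:
    """Ordinary least squares of counts on areas (exact normal equations)."""
    c = np.asarray(counts, dtype=float)
    a = np.asarray(areas, dtype=float)
    if c.size != a.size:
        raise ValueError("counts and areas must have equal length")
    if c.size < 3:
        raise ValueError("need at least 3 polygons to fit the linear model")
    if np.ptp(a) == 0:
        raise ValueError("areas are all equal: slope is not identifiable")
    X = sm.add_constant(a)
    res = sm.OLS(c, X).fit()
    return LinearFit(
        intercept=float(res.params[0]), slope=float(res.params[1]),
        cov=np.asarray(res.cov_params()), resid_var=float(res.mse_resid),
        n=int(c.size), area_min=float(a.min()), area_max=float(a.max()),
    )


def predict_linear(
    fit: LinearFit,
    area: float,
    z: float = 1.96,
    site_id: str = "",
    survey_date: "dt.date | None" = None,
) -> AbundanceEstimate:
    """Predicted abundance at a haulout area with a z x SE(mean response) CI."""
    if fit is None:
        raise ValueError("no linear fit given")
    if area <= 0:
        raise ValueError("area must be positive")
    if area > fit.area_max * 1.5 or area < fit.area_min / 1.5:
        warnings.warn(
            f"predicting at area {area:.1f} m^2, outside the fitted plot-area "
            f"range [{fit.area_min:.1f}, {fit.area_max:.1f}] m^2",
            ExtrapolationWarning, stacklevel=2,
        )
    x = np.array([1.0, area])
    point = float(x @ np.array([fit.intercept, fit.slope]))
    se = float(math.sqrt(max(0.0, x @ fit.cov @ x)))
    lo, hi = point - z * se, point + z * se
    return AbundanceEstimate(
        method="linear_model", site_id=site_id, survey_date=survey_date,
        point=point, ci_lower=max(0.0, lo), ci_upper=hi,
        n_polygons=fit.n, lower_floored=bool(lo < 0),
    )


# ------------------------------------------------------- negative-binomial GLM


@dataclass
class NBModelFit:
    """Fitted NB GLM: counts ~ terrain + offset(log area), log link.

    ``params`` is (intercept,) or (intercept, sandy coefficient); the rocky
    terrain is the reference level.  ``theta`` is the NB dispersion in the
    Var = mu + mu^2/theta parameterization.
    """

    params: np.ndarray
    cov: np.ndarray
    terrain_levels: tuple
    theta: float
    se_theta: "float | None"
    null_deviance: float
    resid_deviance: float
    loglik: float
    n_obs: int
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.params = np.atleast_1d(np.asarray(self.params, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def sandy_coef(self) -> "float | None":
        return float(self.params[1]) if len(self.params) > 1 else None

    @property
    def se_params(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def deviance_explained(self) -> float:
        return deviance_explained(self)

    @classmethod
    def from_coefficients(
        cls,
        intercept: float,
        sandy_coef: "float | None" = None,
        theta: float = 1.0,
        cov: "np.ndarray | None" = None,
    ) -> "NBModelFit":
        """A fit object from externally reported coefficients (e.g. a
        published model), with zero coefficient covariance unless given."""
        k = 1 if sandy_coef is None else 2
        params = [intercept] if sandy_coef is None else [intercept, sandy_coef]
        levels = (Terrain.ROCKY.value,) if sandy_coef is None \
            else (Terrain.ROCKY.value, Terrain.SANDY.value)
        return cls(
            params=np.array(params), cov=np.zeros((k, k)) if cov is None else cov,
            terrain_levels=levels, theta=theta, se_theta=None,
            null_deviance=math.nan, resid_deviance=math.nan,
            loglik=math.nan, n_obs=0,
        )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    # gamma-function form so non-integer responses (multi-observer mean
    # counts) are handled like R's glm.nb does
    return float(np.sum(
        special.gammaln(y + theta) - special.gammaln(theta) - special.gammaln(y + 1)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu) + (y == 0))
    ))


def fit_nb_glm(
    counts,
    areas,
    terrain,
    theta_init: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NBModelFit:
    """Fit counts ~ terrain + offset(log area) with NB errors and log link.

    Alternates an IRLS fit of the coefficients at fixed theta with a
    univariate ML update of theta at fixed coefficients, starting from
    ``theta_init``, until the joint log-likelihood changes by less than
    ``tol``.  If only one terrain level is present an intercept-only model
    is fitted with a warning.
    """
    y = np.asarray(counts, dtype=float)
    a = np.asarray(areas, dtype=float)
    if (a <= 0).any():
        raise ValueError("all areas must be positive")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    terr = np.array([Terrain.from_label(t).value for t in terrain])
    levels = tuple(sorted(set(terr), key=lambda v: v != Terrain.ROCKY.value))
    offset = np.log(a)

    if len(levels) == 1:
        warnings.warn(
            f"single terrain level {levels[0]!r}: fitting an intercept-only model",
            UserWarning, stacklevel=2,
        )
        X = np.ones((y.size, 1))
    else:
        X = np.column_stack([np.ones(y.size), (terr == Terrain.SANDY.value).astype(float)])
        for lev in levels:
            if (terr == lev).sum() < 2:
                raise ValueError(f"need at least 2 polygons per terrain level; {lev!r} is short")

    theta = float(theta_init)
    ll_prev = -np.inf
    res = None
    start = None
    converged = False
    for it in range(1, max_iter + 1):
        model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta),
                       offset=offset)
        res = model.fit(start_params=start)
        start = res.params
        mu = res.mu
        theta = _ml_theta(y, mu, theta)
        ll = _nb_loglik(y, mu, theta)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    if not converged:
        raise RuntimeError(f"NB GLM did not converge in {max_iter} iterations")

    # refit at the final theta so coefficient covariance matches it
    model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta),
                   offset=offset)
    res = model.fit(start_params=start)
    mu = res.mu
    ll = _nb_loglik(y, mu, theta)

    null_model = sm.GLM(y, np.ones((y.size, 1)),
                        family=sm.families.NegativeBinomial(alpha=1.0 / theta),
                        offset=offset)
    null_dev = float(null_model.fit().deviance)

    return NBModelFit(
        params=np.asarray(res.params), cov=np.asarray(res.cov_params()),
        terrain_levels=levels, theta=theta, se_theta=_theta_se(y, mu, theta),
        null_deviance=null_dev, resid_deviance=float(res.deviance),
        loglik=ll, n_obs=int(y.size), converged=converged, n_iter=it,
    )


def _ml_theta(y: np.ndarray, mu: np.ndarray, theta0: float) -> float:
    """Maximize the NB log-likelihood over theta at fixed means."""
    def neg(log_t):
        return -_nb_loglik(y, mu, math.exp(log_t))

    res = optimize.minimize_scalar(
        neg, bracket=(math.log(theta0) - 1.0, math.log(theta0) + 1.0),
        method="brent", options={"xtol": 1e-10},
    )
    return float(min(math.exp(res.x), 1e7))


def _theta_se(y: np.ndarray, mu: np.ndarray, theta: float) -> "float | None":
    """SE of theta from the observed information: central second difference
    of the profile log-likelihood in theta at fixed means."""
    h = max(1e-4, 1e-4 * theta)
    d2 = (_nb_loglik(y, mu, theta + h) - 2 * _nb_loglik(y, mu, theta)
          + _nb_loglik(y, mu, theta - h)) / h**2
    if d2 >= 0:
        return None
    return float(1.0 / math.sqrt(-d2))


def predict_nb(
    fit: NBModelFit,
    area: float,
    terrain: "Terrain | str",
    site_id: str = "",
    survey_date: "dt.date | None" = None,
) -> AbundanceEstimate:
    """Predicted mean abundance for a haulout of given area and terrain.

    Point estimate exponentiates the linear predictor (log link with the
    log-area offset).  The delta-method CI maps the coefficient variance to
    the log-count scale, sd_log = sqrt(log(1 + var(c)/c^2)), and reports
    c * exp(-/+ 2 sd_log): asymmetric and strictly positive.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    terrain = Terrain.from_label(terrain)
    if terrain.value not in fit.terrain_levels:
        raise ValueError(
            f"terrain {terrain.value!r} was not a fitted level {fit.terrain_levels}"
        )
    x = np.array([1.0] + ([1.0 if terrain is Terrain.SANDY else 0.0]
                          if len(fit.params) > 1 else []))
    eta = float(x @ fit.params) + math.log(area)
    c = math.exp(eta)
    var_eta = float(x @ fit.cov @ x)          # var(c)/c^2 by the delta method
    sd_log = math.sqrt(math.log1p(var_eta))
    lo, hi = c * math.exp(-2.0 * sd_log), c * math.exp(2.0 * sd_log)
    return AbundanceEstimate(
        method="nb_glm", site_id=site_id, survey_date=survey_date,
        point=c, ci_lower=lo, ci_upper=hi, n_polygons=fit.n_obs or None,
    )


def deviance_explained(fit: NBModelFit) -> float:
    """Percent of null deviance explained: 100 x (1 - residual/null).

    A degenerate dataset the null model already fits perfectly (null
    deviance 0 with residual deviance 0) explains nothing: 0%.
    """
    if not (fit.null_deviance >= 0):
        raise ValueError("null deviance is unavailable")
    if fit.null_deviance <= 1e-12:
        if fit.resid_deviance <= 1e-12:
            return 0.0
        raise ValueError("null deviance is zero but residual deviance is not")
    return 100.0 * (1.0 - fit.resid_deviance / fit.null_deviance)
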