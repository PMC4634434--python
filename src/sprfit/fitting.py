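"""Nonlinear least-squares fitting of full SPR curves and fit-quality stats.

The fitting models are scikit-learn style regressors (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so they
compose with sklearn pipelines and model selection; the module-level
functions ``fit_curve`` and ``fit_polynomial`` are thin wrappers returning a
:class:`FitResult`.

Fit quality follows the field's two statistics: the coefficient of
determination R^2 and the error variance EV, the population variance of the
residuals E_i = fitted_i - observed_i (offset-invariant: a constant residual
gives EV = 0). Quality is reported separately for the critical-angle region
(left of a criterion angle) and the resonance-angle region (right of it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .core import SPRCurve
from .curve_models import (
    AsymmetricParams,
    PolynomialParams,
    SigmoidAsymmetricParams,
    eval_asymmetric,
    eval_polynomial,
    eval_sigmoid_asymmetric,
    eval_sigmoid_asymmetric_derivative,
    _sigmoid,
)

__all__ = [
    "SPRShapeError",
    "FitResult",
    "RegionSplit",
    "SigmoidAsymmetricRegressor",
    "AsymmetricRegressor",
    "SPRPolynomialRegressor",
    "initial_guess",
    "fit_curve",
    "fit_polynomial",
    "coefficient_of_determination",
    "error_variance",
    "region_quality",
    "default_criterion",
]

MODEL_SIGMOID_ASYMMETRIC = "sigmoid_asymmetric"
MODEL_ASYMMETRIC = "asymmetric"
MODEL_POLYNOMIAL = "polynomial"


class SPRShapeError(ValueError):
    """Raised when a curve lacks the morphology of a full SPR curve."""


@dataclass(frozen=True)
class RegionSplit:
    """Criterion angle separating critical-angle (left) from resonance (right)."""

    criterion: float

    def masks(self, angles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        left = angles < self.criterion
        return left, ~left

    def validate(self, curve: SPRCurve) -> None:
        lo, hi = curve.angle_range
        if not lo < self.criterion < hi:
            raise ValueError(
                f"criterion {self.criterion} outside curve range ({lo}, {hi})"
            )
        left, right = self.masks(curve.angles_deg)
        if left.sum() < 3 or right.sum() < 3:
            raise ValueError("each region must contain at least 3 points")

    @classmethod
    def from_pixel(cls, pixel: int, geometry) -> "RegionSplit":
        """Instrument-protocol split given as a pixel column (e.g. 600/550)."""
        return cls(criterion=geometry.pixel_to_angle(pixel))


@dataclass
class FitResult:
    """Outcome of fitting one model to one curve.

    ``residuals`` are fitted minus observed, so ``sse = sum(residuals**2)``.
    """

    model_id: str
    params: SigmoidAsymmetricParams | AsymmetricParams | PolynomialParams
    residuals: np.ndarray
    sse: float
    converged: bool
    n_iter: int
    curve: SPRCurve
    region_stats: Optional[pd.DataFrame] = None

    def predict(self, X):
        if self.model_id == MODEL_SIGMOID_ASYMMETRIC:
            return eval_sigmoid_asymmetric(self.params, X)
        if self.model_id == MODEL_ASYMMETRIC:
            return eval_asymmetric(self.params, X)
        if self.model_id == MODEL_POLYNOMIAL:
            return eval_polynomial(self.params, X)
        raise ValueError(f"unknown model_id {self.model_id!r}")

    def derivative(self, X):
        """Analytic d(model)/d(angle); only the sigmoid-asymmetric model has one."""
        if self.model_id != MODEL_SIGMOID_ASYMMETRIC:
            raise ValueError(
                f"model {self.model_id!r} has no analytic derivative; "
                "critical-angle detection needs the sigmoid-asymmetric fit"
            )
        return eval_sigmoid_asymmetric_derivative(self.params, X)

    @property
    def fitted_values(self) -> np.ndarray:
        return self.curve.values + self.residuals


def coefficient_of_determination(observed, fitted) -> float:
    """R^2 = 1 - SS_res / SS_tot of fitted against observed values."""
    y = np.asarray(observed, dtype=float)
    x = np.asarray(fitted, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("observed and fitted must be equal-length 1-D, length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    ss_res = float(np.sum((y - x) ** 2))
    return 1.0 - ss_res / ss_tot


def error_variance(observed, fitted) -> float:
    """Population variance of the residuals E_i = fitted_i - observed_i."""
    y = np.asarray(observed, dtype=float)
    x = np.asarray(fitted, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size < 1:
        raise ValueError("observed and fitted must be equal-length 1-D")
    e = x - y
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite residuals")
    return float(np.mean((e - e.mean()) ** 2))


def _as_xy(X, y=None):
    """Accept (n,), (n,1) or SPRCurve input; return 1-D x and y arrays."""
    if isinstance(X, SPRCurve):
        return X.angles_deg, X.values
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise ValueError(f"expected a single angle feature, got shape {x.shape}")
        x = x[:, 0]
    if y is None:
        raise ValueError("y (reflectance values) is required")
    yv = np.asarray(y, dtype=float)
    if yv.shape != x.shape:
        raise ValueError(f"X and y lengths differ: {x.shape} vs {yv.shape}")
    return x, yv


def initial_guess(curve: SPRCurve) -> SigmoidAsymmetricParams:
    """Data-driven starting point for the nine-parameter fit.

    Reads the curve's morphology directly: the dip center D is the global
    minimum, the step center H is the steepest rise left of the dip, F is
    the step height, E the dip half-width at half depth, A the (negative)
    dip amplitude scaled by E^2, G the logistic steepness matching the rise
    width, and I the residual tilt through the endpoints.

    Raises
    ------
    SPRShapeError
        If the minimum sits at a curve end or no rising edge exists left of
        it (the curve lacks SPR morphology).
    """
    x, y = curve.angles_deg, curve.values
    n = x.size
    i_min = int(np.argmin(y))
    if i_min in (0, n - 1):
        raise SPRShapeError("curve lacks SPR morphology: minimum at curve boundary")
    D = float(x[i_min])
    y_min = float(y[i_min])

    fd = np.diff(y)
    left_fd = fd[:i_min]
    if left_fd.size == 0 or np.max(left_fd) <= 0:
        raise SPRShapeError("curve lacks SPR morphology: no steep rise left of the dip")
    j = int(np.argmax(left_fd))
    H = float(0.5 * (x[j] + x[j + 1]))

    # plateau between the rise and the dip; base level left of the rise
    mid = (x > H) & (x < D)
    plateau = float(np.max(y[mid])) if mid.any() else float(np.max(y))
    base_mask = x < H
    base = float(np.median(y[base_mask])) if base_mask.any() else float(y[0])
    F = max(plateau - base, 1e-6)
    depth = max(plateau - y_min, 1e-6)

    # half-width of the dip at half depth
    half_level = y_min + 0.5 * depth
    k_r = i_min
    while k_r < n - 1 and y[k_r] < half_level:
        k_r += 1
    k_l = i_min
    while k_l > 0 and y[k_l] < half_level:
        k_l -= 1
    dx = curve.step_deg
    E = max(0.5 * (x[k_r] - x[k_l]), dx)
    A = -depth * E * E
    B = 0.0
    C = 0.0

    # steep-rise width: contiguous run around j where the slope keeps
    # at least half its peak value
    thresh = 0.5 * left_fd[j]
    lo = j
    while lo > 0 and left_fd[lo - 1] >= thresh:
        lo -= 1
    hi = j
    while hi < left_fd.size - 1 and left_fd[hi + 1] >= thresh:
        hi += 1
    rise_width = max((hi - lo + 1) * dx, dx)
    G = -4.0 / rise_width

    # tilt: the model has no intercept, so the baseline level must come from
    # I*X through the origin; least-squares match of I*x to the endpoint
    # residuals after step/dip removal
    p0 = SigmoidAsymmetricParams(A, B, C, D, E, F, G, H, 0.0)
    r0 = float(y[0] - eval_sigmoid_asymmetric(p0, float(x[0])))
    r1 = float(y[-1] - eval_sigmoid_asymmetric(p0, float(x[-1])))
    I = (x[0] * r0 + x[-1] * r1) / (x[0] ** 2 + x[-1] ** 2)
    return SigmoidAsymmetricParams(A, B, C, D, E, F, G, H, I)


def _sa_model_and_jac(theta: np.ndarray, x: np.ndarray):
    """Model values and 9-column Jacobian of the sigmoid-asymmetric model."""
    A, B, C, D, E, F, G, H, I = theta
    u = x - D
    L = u * u + E * E
    N = 1.0 - (B + C * u)
    asym = A * N / L
    s = _sigmoid(G * (x - H))
    model = asym + F * s + I * x

    jac = np.empty((x.size, 9))
    jac[:, 0] = N / L
    jac[:, 1] = -A / L
    jac[:, 2] = -A * u / L
    jac[:, 3] = A * (C * L + 2.0 * u * N) / (L * L)
    jac[:, 4] = -2.0 * A * E * N / (L * L)
    jac[:, 5] = s
    sp = s * (1.0 - s)
    jac[:, 6] = -F * sp * (x - H)
    jac[:, 7] = F * sp * G
    jac[:, 8] = x
    return model, jac


def _asym_model_and_jac(theta: np.ndarray, x: np.ndarray):
    A, B, C, D, E = theta
    u = x - D
    L = u * u + E * E
    N = 1.0 - (B + C * u)
    model = A * N / L
    jac = np.empty((x.size, 5))
    jac[:, 0] = N / L
    jac[:, 1] = -A / L
    jac[:, 2] = -A * u / L
    jac[:, 3] = A * (C * L + 2.0 * u * N) / (L * L)
    jac[:, 4] = -2.0 * A * E * N / (L * L)
    return model, jac


class _LeastSquaresCurveRegressor(RegressorMixin, BaseEstimator):
    """Shared trust-region least-squares driver for the closed-form models."""

    _n_params: int = 0
    model_id: str = ""

    def __init__(
        self,
        init=None,
        bounds=None,
        max_iter: int = 2000,
        tol: float = 1e-10,
        n_restarts: int = 1,
        random_state: int | None = 0,
    ):
        self.init = init
        self.bounds = bounds
        self.max_iter = max_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.random_state = random_state

    # subclasses provide these
    def _default_init(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def _model_and_jac(self, theta: np.ndarray, x: np.ndarray):
        raise NotImplementedError

    def _params_from_array(self, theta: np.ndarray):
        raise NotImplementedError

    def fit(self, X, y=None):
        x, yv = _as_xy(X, y)
        if x.size < self._n_params:
            raise ValueError(
                f"need at least {self._n_params} points to fit {self.model_id}, got {x.size}"
            )
        if self.init is not None:
            theta0 = (
                self.init.to_array()
                if hasattr(self.init, "to_array")
                else np.asarray(self.init, dtype=float)
            )
            if theta0.size != self._n_params:
                raise ValueError(
                    f"init has {theta0.size} parameters, expected {self._n_params}"
                )
        else:
            theta0 = self._default_init(x, yv)
        bounds = self.bounds if self.bounds is not None else (-np.inf, np.inf)

        def residual(theta):
            return self._model_and_jac(theta, x)[0] - yv

        def jac(theta):
            return self._model_and_jac(theta, x)[1]

        best = None
        rng = np.random.default_rng(self.random_state)
        start = theta0
        for attempt in range(1 + max(self.n_restarts, 0)):
            res = least_squares(
                residual,
                start,
                jac=jac,
                bounds=bounds,
                method="trf",
                ftol=self.tol,
                xtol=1e-14,
                gtol=1e-14,
                max_nfev=self.max_iter,
            )
            if best is None or res.cost < best.cost:
                best = res
            if best.status > 0 and best.cost <= np.sum(residual(theta0) ** 2) / 2:
                break
            # perturbed restart on non-convergence
            start = theta0 * (1.0 + 0.05 * rng.standard_normal(theta0.size))
            start += 0.01 * rng.standard_normal(theta0.size)

        self.params_ = self._params_from_array(best.x)
        self.residuals_ = best.fun.copy()  # fitted - observed
        self.sse_ = float(2.0 * best.cost)
        self.converged_ = bool(best.status > 0)
        self.n_iter_ = int(best.nfev)
        self.n_features_in_ = 1
        self._x_fit = x
        self._y_fit = yv
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return self._evaluate(self.params_, x)

    def _evaluate(self, params, x):
        raise NotImplementedError

    def to_fit_result(self) -> FitResult:
        curve = SPRCurve(angles_deg=self._x_fit, values=self._y_fit)
        return FitResult(
            model_id=self.model_id,
            params=self.params_,
            residuals=self.residuals_,
            sse=self.sse_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            curve=curve,
        )


class SigmoidAsymmetricRegressor(_LeastSquaresCurveRegressor):
    """Nine-parameter sigmoid-asymmetric fit of a full SPR curve.

    Fits dip, step and tilt simultaneously by trust-region least squares
    with an analytic Jacobian, starting from the morphology-based
    :func:`initial_guess` unless ``init`` is supplied. One seeded perturbed
    restart is attempted on non-convergence.

    Examples
    --------
    >>> reg = SigmoidAsymmetricRegressor().fit(angles[:, None], reflectance)
    >>> reg.params_.D   # dip-center angle, degrees  # doctest: +SKIP
    """

    _n_params = 9
    model_id = MODEL_SIGMOID_ASYMMETRIC

    def _default_init(self, x, y):
        return initial_guess(SPRCurve(angles_deg=x, values=y)).to_array()

    def _model_and_jac(self, theta, x):
        return _sa_model_and_jac(theta, x)

    def _params_from_array(self, theta):
        return SigmoidAsymmetricParams.from_array(theta)

    def _evaluate(self, params, x):
        return eval_sigmoid_asymmetric(params, x)

    def derivative(self, X):
        """Analytic slope of the fitted model (for critical-angle detection)."""
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return eval_sigmoid_asymmetric_derivative(self.params_, x)


class AsymmetricRegressor(_LeastSquaresCurveRegressor):
    """Five-parameter asymmetric (resonance-dip only) fit.

    The classical model: accurate around the resonance minimum but unable to
    represent the critical-angle step, which is exactly the deficiency the
    sigmoid-asymmetric model removes.
    """

    _n_params = 5
    model_id = MODEL_ASYMMETRIC

    def _default_init(self, x, y):
        return initial_guess(SPRCurve(angles_deg=x, values=y)).to_array()[:5]

    def _model_and_jac(self, theta, x):
        return _asym_model_and_jac(theta, x)

    def _params_from_array(self, theta):
        return AsymmetricParams.from_array(theta)

    def _evaluate(self, params, x):
        return eval_asymmetric(params, x)


class SPRPolynomialRegressor(RegressorMixin, BaseEstimator):
    """High-order polynomial regression on a rescaled angle domain.

    Order 24 by default. The angle range is mapped to [-1, 1] before the
    least-squares solve; fitting in raw degrees at this order is numerically
    unstable.
    """

    model_id = MODEL_POLYNOMIAL

    def __init__(self, order: int = 24):
        self.order = order

    def fit(self, X, y=None):
        x, yv = _as_xy(X, y)
        if x.size <= self.order:
            raise ValueError(
                f"need more than {self.order} points for an order-{self.order} fit, got {x.size}"
            )
        from numpy.polynomial import Polynomial

        poly = Polynomial.fit(x, yv, deg=self.order)
        self.params_ = PolynomialParams(
            order=self.order,
            coefficients=np.asarray(poly.coef, dtype=float),
            domain=(float(poly.domain[0]), float(poly.domain[1])),
        )
        fitted = eval_polynomial(self.params_, x)
        self.residuals_ = fitted - yv
        self.sse_ = float(np.sum(self.residuals_**2))
        self.converged_ = True
        self.n_iter_ = 1
        self.n_features_in_ = 1
        self._x_fit = x
        self._y_fit = yv
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            x = x[:, 0]
        return eval_polynomial(self.params_, x)

    def to_fit_result(self) -> FitResult:
        curve = SPRCurve(angles_deg=self._x_fit, values=self._y_fit)
        return FitResult(
            model_id=self.model_id,
            params=self.params_,
            residuals=self.residuals_,
            sse=self.sse_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            curve=curve,
        )


_ESTIMATORS = {
    MODEL_SIGMOID_ASYMMETRIC: SigmoidAsymmetricRegressor,
    MODEL_ASYMMETRIC: AsymmetricRegressor,
    MODEL_POLYNOMIAL: SPRPolynomialRegressor,
}


def fit_curve(
    curve: SPRCurve,
    model_id: str = MODEL_SIGMOID_ASYMMETRIC,
    init=None,
    bounds=None,
    **estimator_kwargs,
) -> FitResult:
    """Fit one of the three models to a curve and return a :class:`FitResult`."""
    if model_id not in _ESTIMATORS:
        raise ValueError(f"unknown model_id {model_id!r}; choose from {sorted(_ESTIMATORS)}")
    if model_id == MODEL_POLYNOMIAL:
        est = SPRPolynomialRegressor(**estimator_kwargs)
    else:
        est = _ESTIMATORS[model_id](init=init, bounds=bounds, **estimator_kwargs)
    est.fit(curve.angles_deg, curve.values)
    return est.to_fit_result()


def fit_polynomial(curve: SPRCurve, order: int = 24) -> FitResult:
    """Least-squares polynomial fit of the given order (rescaled domain)."""
    return fit_curve(curve, MODEL_POLYNOMIAL, order=order)


def default_criterion(curve: SPRCurve) -> RegionSplit:
    """Criterion angle halfway between the step center and dip center.

    Uses the morphology-based initial guess, so it works on raw curves
    before any model has been fitted. Instrument protocols with a fixed
    pixel criterion should use :meth:`RegionSplit.from_pixel` instead.
    """
    p0 = initial_guess(curve)
    return RegionSplit(criterion=0.5 * (p0.H + p0.D))


def region_quality(curve: SPRCurve, fit: FitResult, split: RegionSplit) -> pd.DataFrame:
    """Per-region R^2 and error variance, critical (left) vs resonance (right).

    Returns a DataFrame indexed by region name with columns ``cd``, ``ev``,
    ``sse`` and ``n``; also stored on ``fit.region_stats``.
    """
    split.validate(curve)
    fitted = fit.predict(curve.angles_deg)
    left, right = split.masks(curve.angles_deg)
    rows = {}
    for name, mask in (("critical", left), ("resonance", right)):
        if mask.sum() < 3:
            raise ValueError(f"{name} region has fewer than 3 points")
        obs, mod = curve.values[mask], fitted[mask]
        rows[name] = {
            "cd": coefficient_of_determination(obs, mod),
            "ev": error_variance(obs, mod),
            "sse": float(np.sum((mod - obs) ** 2)),
            "n": int(mask.sum()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    fit.region_stats = table
    return table
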