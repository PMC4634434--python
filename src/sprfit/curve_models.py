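"""Closed-form fitting models for full SPR curves.

Three candidate models are compared throughout the package:

* the sigmoid-asymmetric model, whose nine parameters A..I capture a full
  SPR curve — an asymmetric Lorentzian-like dip (resonance region), a
  logistic step (critical-angle rise) and a linear tilt:

      R(X) = A * [1 - (B + C*(X - D))] / ((X - D)^2 + E^2)
             + F / (1 + exp(G * (X - H)))
             + I * X

* the asymmetric model alone (the first term, parameters A..E), the
  classical resonance-dip fit;
* a high-order (default 24) polynomial, evaluated in a rescaled basis for
  conditioning.

A reflectance dip requires A * (1 - B) < 0 at the dip center; a step that
rises with angle requires G < 0 in this sign convention. The analytic first
derivative of the sigmoid-asymmetric model is what locates the critical
angle, so it is provided in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

__all__ = [
    "SigmoidAsymmetricParams",
    "AsymmetricParams",
    "PolynomialParams",
    "eval_sigmoid_asymmetric",
    "eval_sigmoid_asymmetric_derivative",
    "eval_asymmetric",
    "eval_polynomial",
]

_LETTERS = ("A", "B", "C", "D", "E", "F", "G", "H", "I")


@dataclass(frozen=True)
class SigmoidAsymmetricParams:
    """The nine parameters A..I of the sigmoid-asymmetric model.

    A: dip amplitude; B: dimensionless asymmetry offset; C: asymmetry slope
    (1/deg); D: dip-center angle (deg); E: dip half-width (deg, nonzero);
    F: step amplitude; G: step steepness (1/deg, negative for a rising
    step); H: step-center angle (deg); I: linear tilt (1/deg).
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float
    H: float
    I: float

    def __post_init__(self) -> None:
        vals = self.to_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all parameters must be finite")
        if self.E == 0:
            raise ValueError("E must be nonzero (pole of the asymmetric term)")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _LETTERS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "SigmoidAsymmetricParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError(f"expected 9 parameters, got shape {arr.shape}")
        return cls(*arr.tolist())

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in _LETTERS}

    def asymmetric_part(self) -> "AsymmetricParams":
        return AsymmetricParams(self.A, self.B, self.C, self.D, self.E)

    def canonical(self) -> "SigmoidAsymmetricParams":
        """Equivalent parameters in the identifiable gauge B = 0.

        The numerator A*[1 - B - C*(X-D)] only determines the products
        A*(1-B) and A*C, so (A, B, C) carry a one-dimensional redundancy:
        any B != 1 can be absorbed into A and C without changing the model.
        Comparisons between fitted parameter sets must be made in this
        gauge.
        """
        if self.B == 1:
            raise ValueError("B = 1 degenerate: dip amplitude A*(1-B) vanishes")
        return SigmoidAsymmetricParams(
            A=self.A * (1.0 - self.B),
            B=0.0,
            C=self.C / (1.0 - self.B),
            D=self.D,
            E=self.E,
            F=self.F,
            G=self.G,
            H=self.H,
            I=self.I,
        )


@dataclass(frozen=True)
class AsymmetricParams:
    """Parameters A..E of the asymmetric (resonance-dip) model alone."""

    A: float
    B: float
    C: float
    D: float
    E: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.to_array())):
            raise ValueError("all parameters must be finite")
        if self.E == 0:
            raise ValueError("E must be nonzero (pole of the asymmetric term)")

    def to_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.D, self.E], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "AsymmetricParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError(f"expected 5 parameters, got shape {arr.shape}")
        return cls(*arr.tolist())

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in _LETTERS[:5]}

    def canonical(self) -> "AsymmetricParams":
        """Equivalent parameters in the identifiable gauge B = 0."""
        if self.B == 1:
            raise ValueError("B = 1 degenerate: dip amplitude A*(1-B) vanishes")
        return AsymmetricParams(
            A=self.A * (1.0 - self.B),
            B=0.0,
            C=self.C / (1.0 - self.B),
            D=self.D,
            E=self.E,
        )


@dataclass(frozen=True)
class PolynomialParams:
    """High-order polynomial in a numerically scaled basis.

    ``coefficients`` are power-basis coefficients on the window [-1, 1];
    ``domain`` is the angle interval mapped onto that window, as done by
    :meth:`numpy.polynomial.Polynomial.fit`. Raw-degree evaluation of an
    order-24 polynomial over a narrow angular window is catastrophically
    ill-conditioned, hence the mandatory rescaling.
    """

    order: int
    coefficients: np.ndarray
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        if self.order < 0:
            raise ValueError(f"order must be >= 0, got {self.order}")
        if coef.size != self.order + 1:
            raise ValueError(
                f"need {self.order + 1} coefficients for order {self.order}, got {coef.size}"
            )
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"degenerate domain {self.domain}")
        object.__setattr__(self, "coefficients", coef)
        object.__setattr__(self, "domain", (float(lo), float(hi)))

    def as_polynomial(self) -> Polynomial:
        return Polynomial(self.coefficients, domain=self.domain, window=(-1.0, 1.0))

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "coefficients": self.coefficients.tolist(),
            "domain": list(self.domain),
        }


def _sigmoid(g: np.ndarray) -> np.ndarray:
    """1 / (1 + exp(g)), overflow-safe for large |g|."""
    out = np.empty_like(g, dtype=float)
    pos = g >= 0
    out[pos] = np.exp(-g[pos]) / (1.0 + np.exp(-g[pos]))
    eg = np.exp(g[~pos])
    out[~pos] = 1.0 / (1.0 + eg)
    return out


def eval_asymmetric(p: AsymmetricParams | SigmoidAsymmetricParams, X):
    """Asymmetric dip term A*[1 - (B + C*(X-D))] / ((X-D)^2 + E^2)."""
    scalar = np.isscalar(X)
    x = np.atleast_1d(np.asarray(X, dtype=float))
    u = x - p.D
    val = p.A * (1.0 - (p.B + p.C * u)) / (u * u + p.E * p.E)
    return float(val[0]) if scalar else val


def eval_sigmoid_asymmetric(p: SigmoidAsymmetricParams, X):
    """The full nine-parameter model value at angle(s) X."""
    scalar = np.isscalar(X)
    x = np.atleast_1d(np.asarray(X, dtype=float))
    u = x - p.D
    asym = p.A * (1.0 - (p.B + p.C * u)) / (u * u + p.E * p.E)
    step = p.F * _sigmoid(p.G * (x - p.H))
    val = asym + step + p.I * x
    return float(val[0]) if scalar else val


def eval_sigmoid_asymmetric_derivative(p: SigmoidAsymmetricParams, X):
    """Analytic d/dX of the sigmoid-asymmetric model.

    The critical angle is located at the maximum of this derivative on the
    left (critical-angle) region of the curve.
    """
    scalar = np.isscalar(X)
    x = np.atleast_1d(np.asarray(X, dtype=float))
    u = x - p.D
    L = u * u + p.E * p.E
    N = 1.0 - (p.B + p.C * u)
    d_asym = p.A * (-p.C * L - 2.0 * u * N) / (L * L)
    s = _sigmoid(p.G * (x - p.H))
    d_step = -p.F * p.G * s * (1.0 - s)
    val = d_asym + d_step + p.I
    return float(val[0]) if scalar else val


def eval_polynomial(p: PolynomialParams, X):
    """Evaluate the polynomial model in its scaled basis (stable at order 24)."""
    scalar = np.isscalar(X)
    x = np.atleast_1d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite evaluation point")
    val = p.as_polynomial()(x)
    return float(val[0]) if scalar else val
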