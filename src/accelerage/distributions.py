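"""Parametric baseline survival distributions for adult mortality.

Two families are supported: the Gompertz law ``h0(t) = a * exp(b*t)``,
the canonical description of adult human mortality, and the Weibull law
in the rate parameterization ``h0(t) = lam * nu * t**(nu-1)``.

Covariates act on the baseline either through proportional hazards (PH),
``h(t|x) = theta * h0(t)``, or through accelerated failure time (AFT),
``S(t|x) = S0(theta * t)`` with acceleration factor ``theta = exp(beta @ x)``.

The Gompertz family is closed under AFT time-rescaling: if the baseline is
Gompertz(a, b), the conditional law at acceleration theta is exactly
Gompertz(a*theta, b*theta).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GompertzParams",
    "WeibullParams",
    "CovariateEffect",
    "baseline_functions",
    "inverse_cumulative_hazard",
    "conditional_survival_and_hazard",
]

# Ages beyond this are treated as having zero survival; exp(b*t) would
# overflow double precision long before b*t ~ 700.
MAX_AGE = 200.0


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard parameters: ``h0(t) = a * exp(b * t)``.

    Parameters
    ----------
    a : float
        Hazard level at age 0, per year. Must be positive.
    b : float
        Exponential rate of hazard increase, per year. Must be positive.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Gompertz parameters must be positive, got a={self.a}, b={self.b}")

    def log_params(self) -> np.ndarray:
        return np.array([np.log(self.a), np.log(self.b)])

    @classmethod
    def from_log_params(cls, log_params) -> "GompertzParams":
        la, lb = np.asarray(log_params, dtype=float)
        return cls(a=float(np.exp(la)), b=float(np.exp(lb)))

    def scaled(self, theta: float) -> "GompertzParams":
        """Conditional law under AFT acceleration theta: Gompertz(a*theta, b*theta)."""
        return GompertzParams(a=self.a * theta, b=self.b * theta)

    def hazard(self, t):
        t = _check_age(t)
        return self.a * np.exp(self.b * np.minimum(t, MAX_AGE))

    def cumulative_hazard(self, t):
        t = _check_age(t)
        # expm1 keeps precision near t = 0
        return (self.a / self.b) * np.expm1(self.b * np.minimum(t, MAX_AGE))

    def survival(self, t):
        t = _check_age(t)
        s = np.exp(-self.cumulative_hazard(t))
        return np.where(np.asarray(t) > MAX_AGE, 0.0, s)

    def inverse_cumulative_hazard(self, x):
        x = _check_cumhaz(x)
        return np.log1p(self.b * x / self.a) / self.b


@dataclass(frozen=True)
class WeibullParams:
    """Weibull hazard parameters in the rate form ``h0(t) = lam * nu * t**(nu-1)``."""

    lam: float
    nu: float

    def __post_init__(self) -> None:
        if not (self.lam > 0 and self.nu > 0):
            raise ValueError(f"Weibull parameters must be positive, got lam={self.lam}, nu={self.nu}")

    def log_params(self) -> np.ndarray:
        return np.array([np.log(self.lam), np.log(self.nu)])

    @classmethod
    def from_log_params(cls, log_params) -> "WeibullParams":
        ll, ln = np.asarray(log_params, dtype=float)
        return cls(lam=float(np.exp(ll)), nu=float(np.exp(ln)))

    def scaled(self, theta: float) -> "WeibullParams":
        """Conditional law under AFT acceleration theta: Weibull(lam*theta**nu, nu)."""
        return WeibullParams(lam=self.lam * theta**self.nu, nu=self.nu)

    def hazard(self, t):
        t = _check_age(t)
        with np.errstate(divide="ignore"):
            return self.lam * self.nu * np.power(t, self.nu - 1.0)

    def cumulative_hazard(self, t):
        t = _check_age(t)
        return self.lam * np.power(t, self.nu)

    def survival(self, t):
        t = _check_age(t)
        return np.exp(-self.cumulative_hazard(t))

    def inverse_cumulative_hazard(self, x):
        x = _check_cumhaz(x)
        return np.power(x / self.lam, 1.0 / self.nu)


BaselineParams = GompertzParams | WeibullParams


@dataclass(frozen=True)
class CovariateEffect:
    """Log-scale covariate coefficients under a PH or AFT assumption.

    ``beta`` holds one coefficient per marker; the acceleration factor
    (AFT) or hazard ratio (PH) for a marker vector x is exp(beta @ x).
    """

    beta: np.ndarray
    assumption: str  # "PH" or "AFT"

    def __post_init__(self) -> None:
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not np.all(np.isfinite(beta)):
            raise ValueError("coefficients must be finite")
        if self.assumption not in ("PH", "AFT"):
            raise ValueError(f"assumption must be 'PH' or 'AFT', got {self.assumption!r}")
        object.__setattr__(self, "beta", beta)

    def linear_predictor(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.ndim == 1:
            if x.shape[0] != self.beta.shape[0]:
                raise ValueError(
                    f"marker vector of length {x.shape[0]} does not match "
                    f"{self.beta.shape[0]} coefficients"
                )
            return np.array(x @ self.beta)
        if x.shape[1] != self.beta.shape[0]:
            raise ValueError(
                f"marker matrix with {x.shape[1]} columns does not match "
                f"{self.beta.shape[0]} coefficients"
            )
        return x @ self.beta

    def theta(self, x) -> np.ndarray:
        return np.exp(self.linear_predictor(x))

    @property
    def lp_sd_std_normal(self) -> float:
        """SD of beta @ X for independent standard-normal markers."""
        return float(np.sqrt(np.sum(self.beta**2)))


def _check_age(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("age must be nonnegative")
    return t


def _check_cumhaz(x):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("cumulative hazard must be nonnegative")
    return x


def baseline_functions(params: BaselineParams, t) -> dict:
    """Evaluate baseline hazard, cumulative hazard and survival at age ``t``.

    Vectorized over ``t``. Raises ``ValueError`` for negative ages.
    """
    return {
        "hazard": params.hazard(t),
        "cumulative_hazard": params.cumulative_hazard(t),
        "survival": params.survival(t),
    }


def inverse_cumulative_hazard(params: BaselineParams, x):
    """Age at which the baseline cumulative hazard reaches ``x`` (>= 0)."""
    return params.inverse_cumulative_hazard(x)


def conditional_survival_and_hazard(
    params: BaselineParams, effect: CovariateEffect, x, t
) -> dict:
    """Conditional survival and hazard given markers ``x`` at age ``t``.

    PH:  S(t|x) = S0(t)**theta,    h(t|x) = theta * h0(t)
    AFT: S(t|x) = S0(theta * t),   h(t|x) = theta * h0(theta * t)
    with theta = exp(beta @ x).
    """
    t = _check_age(t)
    theta = float(effect.theta(x))
    if effect.assumption == "PH":
        # work on the log scale: S0(t)^theta = exp(-theta * H0(t))
        survival = np.exp(-theta * params.cumulative_hazard(t))
        hazard = theta * params.hazard(t)
    else:
        survival = np.exp(-params.cumulative_hazard(theta * t))
        hazard = theta * params.hazard(theta * t)
    return {"survival": survival, "hazard": hazard}


def conditional_params(params: BaselineParams, theta: float) -> BaselineParams:
    """Closed-form conditional law under AFT acceleration ``theta``.

    Both families are closed under AFT rescaling; this returns the
    conditional distribution's own parameters.
    """
    return params.scaled(theta)
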