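"""Closed-form logistic growth and Luedeking-Piret product-formation kinetics.

The biomass model is the logistic equation

    dX/dt = mu_max * (1 - X/Xmax) * X

whose solution, written in an overflow-safe form, is

    X(t) = Xmax / (1 + ((Xmax - X0)/X0) * exp(-mu_max * t)).

Product formation follows the Luedeking-Piret rate law

    dP/dt = alpha * X + beta * dX/dt

where ``beta * dX/dt`` is the growth-associated synthesis rate and
``alpha * X`` the non-growth-associated one.  Integrating along the logistic
trajectory gives the closed form

    P(t) = P0 + beta * (X(t) - X0) + alpha * (Xmax/mu_max) * ln D(t),
    D(t) = 1 - (X0/Xmax) * (1 - exp(mu_max * t)).

A widely reproduced printed variant of the integrated form attaches alpha to
the ``(X - X0)`` term and beta to the logarithmic term; that variant is the
integral of ``dP/dt = alpha*dX/dt + beta*X``, i.e. the same model family with
the two coefficients exchanged.  This module keeps the rate-law convention
above (alpha on X, beta on dX/dt) throughout; see ``docs/methods.md``.

The specific production rate is q_P = (dP/dt)/X = alpha +
beta*mu_max*(1 - X/Xmax), a non-increasing function of time whenever both
coefficients are non-negative, so its maximum sits at t = 0.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthParams",
    "ProductParams",
    "AssociationClass",
    "logistic_rate",
    "logistic_solution",
    "lp_rate",
    "lp_solution",
    "specific_production_rate",
    "max_specific_production_rate",
    "classify_association",
]


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth parameters.

    Parameters
    ----------
    X0 : float
        Initial biomass concentration (g/L or OD-equivalent), strictly
        positive and below the carrying capacity.
    Xmax : float
        Carrying capacity, same units as ``X0``.
    mu_max : float
        Maximum specific growth rate (1/h), strictly positive.
    """

    X0: float
    Xmax: float
    mu_max: float

    def __post_init__(self) -> None:
        if not (0.0 < self.X0 < self.Xmax):
            raise ValueError(
                f"require 0 < X0 < Xmax, got X0={self.X0}, Xmax={self.Xmax}"
            )
        if not self.mu_max > 0.0:
            raise ValueError(f"require mu_max > 0, got {self.mu_max}")


@dataclass(frozen=True)
class ProductParams:
    """Luedeking-Piret product-formation parameters.

    ``alpha`` (1/h) scales the non-growth-associated term ``alpha*X``;
    ``beta`` (g product per g biomass) scales the growth-associated term
    ``beta*dX/dt``.  Negative fitted values are legal (they arise from noisy
    regressions) and are flagged downstream rather than clipped.
    """

    P0: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.P0 < 0.0:
            raise ValueError(f"require P0 >= 0, got {self.P0}")
        for name in ("alpha", "beta"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


class AssociationClass(str, enum.Enum):
    """Growth-association class of product formation."""

    growth_associated = "growth_associated"
    non_growth_associated = "non_growth_associated"
    mixed = "mixed"
    none = "none"


def logistic_rate(gp: GrowthParams, X):
    """Logistic growth rate dX/dt = mu_max*(1 - X/Xmax)*X at biomass ``X``.

    Vectorized over ``X``; raises ``ValueError`` for negative biomass.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0.0):
        raise ValueError("biomass X must be non-negative")
    out = gp.mu_max * (1.0 - X / gp.Xmax) * X
    return out if out.ndim else float(out)


def logistic_solution(gp: GrowthParams, t):
    """Biomass X(t) of the logistic model, vectorized over times ``t`` (h).

    Uses the rearranged form Xmax / (1 + c*exp(-mu*t)) with
    c = (Xmax - X0)/X0, which never overflows for large ``t``.
    """
    t = np.asarray(t, dtype=float)
    c = (gp.Xmax - gp.X0) / gp.X0
    out = gp.Xmax / (1.0 + c * np.exp(-gp.mu_max * t))
    return out if out.ndim else float(out)


def lp_rate(pp: ProductParams, X, dXdt):
    """Luedeking-Piret product formation rate alpha*X + beta*dX/dt."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0.0):
        raise ValueError("biomass X must be non-negative")
    out = pp.alpha * X + pp.beta * np.asarray(dXdt, dtype=float)
    return out if out.ndim else float(out)


def _log_D(gp: GrowthParams, t: np.ndarray) -> np.ndarray:
    # ln D(t) = ln[(c + e^{mu t})/(c + 1)] with c = (Xmax-X0)/X0, computed as
    # mu*t + log1p(c e^{-mu t}) - log1p(c) so e^{mu t} never overflows.
    c = (gp.Xmax - gp.X0) / gp.X0
    mt = gp.mu_max * t
    return mt + np.log1p(c * np.exp(-mt)) - np.log1p(c)


def lp_solution(gp: GrowthParams, pp: ProductParams, t):
    """Product concentration P(t) from integrating the rate law along X(t).

    P(t) = P0 + beta*(X(t) - X0) + alpha*(Xmax/mu_max)*ln D(t), with
    D(t) = 1 - (X0/Xmax)*(1 - exp(mu_max*t)); the log is evaluated in an
    overflow-safe form.
    """
    t = np.asarray(t, dtype=float)
    X = gp.Xmax / (1.0 + (gp.Xmax - gp.X0) / gp.X0 * np.exp(-gp.mu_max * t))
    out = (
        pp.P0
        + pp.beta * (X - gp.X0)
        + pp.alpha * (gp.Xmax / gp.mu_max) * _log_D(gp, t)
    )
    return out if out.ndim else float(out)


def specific_production_rate(gp: GrowthParams, pp: ProductParams, t):
    """Specific production rate q_P(t) = (dP/dt)/X (1/h).

    Along the logistic trajectory this is
    alpha + beta*mu_max*(1 - X(t)/Xmax); non-increasing in time when both
    coefficients are non-negative.
    """
    t = np.asarray(t, dtype=float)
    X = logistic_solution(gp, t)
    out = pp.alpha + pp.beta * gp.mu_max * (1.0 - np.asarray(X) / gp.Xmax)
    return out if out.ndim else float(out)


def max_specific_production_rate(
    gp: GrowthParams,
    pp: ProductParams,
    t_window: tuple[float, float] = (0.0, 120.0),
    dt: float = 0.01,
) -> float:
    """Maximum specific production rate q_P,max (1/h).

    For alpha, beta >= 0, q_P is non-increasing so the maximum is its value
    at t = 0.  If either coefficient is negative the function may not be
    monotone; the maximum is then taken over a dense grid on ``t_window``
    (step ``dt`` hours) and a non-monotonicity warning is emitted.
    """
    if pp.alpha >= 0.0 and pp.beta >= 0.0:
        return float(specific_production_rate(gp, pp, 0.0))
    warnings.warn(
        "negative alpha or beta: q_P may be non-monotone; "
        "maximizing over a dense time grid",
        stacklevel=2,
    )
    grid = np.arange(t_window[0], t_window[1] + dt, dt)
    return float(np.max(specific_production_rate(gp, pp, grid)))


def classify_association(pp: ProductParams, tol: float = 1e-6) -> AssociationClass:
    """Classify product formation by which coefficients are effectively nonzero.

    ``|alpha| > tol`` and ``|beta| > tol`` -> mixed (partially growth-coupled);
    only beta -> growth_associated; only alpha -> non_growth_associated;
    neither -> none.  ``tol`` is in the coefficient's own units.
    """
    if not tol > 0.0:
        raise ValueError("tol must be positive")
    a = abs(pp.alpha) > tol
    b = abs(pp.beta) > tol
    if a and b:
        return AssociationClass.mixed
    if b:
        return AssociationClass.growth_associated
    if a:
        return AssociationClass.non_growth_associated
    return AssociationClass.none
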