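"""Auxiliary constructions: orthogonal exponential pairs, Stein operators,
and the quantile-flow identity.

These are verifiable building blocks for alternative routes to the integral
equation behind the factorisation criterion.  The orthogonalisation and the
Stein characterisation are constructed and certified here; using them to
*solve* the integral equation for a statistic is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import sympy as sp
from scipy import integrate

__all__ = [
    "OrthoPair",
    "SteinOperatorExp",
    "build_ortho_pair",
    "stein_check",
    "quantile_flow",
]


@dataclass
class OrthoPair:
    """f0(c) = exp(-lam c/psi) and the Gram-Schmidt partner phi1 indexed by kappa.

    ``kappa`` here is the index of the second exponential f1(c) =
    exp(-lam kappa c / psi); it is unrelated to the normalising constant of a
    factorised density.  Inner products are over L2(0, infinity).
    """

    kappa: float
    lam: float
    psi: float
    inner_products: dict = dc_field(default_factory=dict)
    normaliser: float = 0.0

    def f0(self, c):
        return np.exp(-self.lam * np.asarray(c, dtype=float) / self.psi)

    def f1(self, c):
        return np.exp(-self.lam * self.kappa * np.asarray(c, dtype=float) / self.psi)

    def phi0(self, c):
        return self.f0(c)

    def phi1(self, c):
        k, lam, psi = self.kappa, self.lam, self.psi
        amp = np.sqrt(2 * k * lam) / ((k - 1) * np.sqrt(psi))
        return amp * ((k + 1) * self.f1(c) - 2.0 * self.f0(c))

    def orthogonality_residual(self, epsabs: float = 1e-12) -> float:
        val, _ = integrate.quad(
            lambda c: self.phi0(c) * self.phi1(c), 0, np.inf, epsabs=epsabs
        )
        return float(val)


def build_ortho_pair(kappa_index: float, lam: float, psi: float) -> OrthoPair:
    """Construct the orthogonal pair (phi0, phi1^(kappa)) in closed form.

    The target function phi1 is D1(c)/sqrt(D0 D1) with D1(c) =
    <f0,f0> f1(c) - <f0,f1> f0(c); the closed-form inner products are

        <f0, f1> = psi / (lam (1 + kappa)),
        <f1, f1> = psi / (2 kappa lam),
        <f0, f0> = psi / (2 lam).

    Raises for kappa = 1, where f1 is not linearly independent of f0.
    """
    k, lam, psi = float(kappa_index), float(lam), float(psi)
    if k <= 0:
        raise ValueError("kappa index must be positive")
    if k == 1:
        raise ValueError("kappa = 1: f1 coincides with f0, no orthogonal partner")
    if lam <= 0 or psi <= 0:
        raise ValueError("lam and psi must be positive")
    ip = {
        ("f0", "f0"): psi / (2 * lam),
        ("f0", "f1"): psi / (lam * (1 + k)),
        ("f1", "f1"): psi / (2 * k * lam),
    }
    D0 = ip[("f0", "f0")]
    D1 = D0 * ip[("f1", "f1")] - ip[("f0", "f1")] ** 2
    normaliser = 2 * np.sqrt(2 * k) * (k + 1) * lam**1.5 / ((k - 1) * psi**1.5)
    pair = OrthoPair(kappa=k, lam=lam, psi=psi, inner_products=ip,
                     normaliser=float(normaliser))
    # sanity: closed-form normaliser against the determinant definition
    assert np.isclose(abs(normaliser), (D0 * D1) ** -0.5, rtol=1e-12)
    return pair


@dataclass(frozen=True)
class SteinOperatorExp:
    """Stein operator of the exponential law of rate rho:
    (A f)(x) = (1 - rho x) f'(x) + x f''(x), annihilated in expectation
    exactly by Exp(rho)."""

    rate: float

    def apply(self, f_expr: sp.Expr, x: sp.Symbol) -> sp.Expr:
        return (1 - self.rate * x) * sp.diff(f_expr, x) + x * sp.diff(f_expr, x, 2)


def _as_derivatives(f, x: sp.Symbol | None = None):
    """Return callables (f', f'') from a sympy expression or callable pair."""
    if isinstance(f, sp.Expr):
        xs = sorted(f.free_symbols, key=str)
        if len(xs) > 1:
            raise ValueError("test function must be univariate")
        x = xs[0] if xs else sp.Symbol("x")
        d1 = sp.lambdify(x, sp.diff(f, x), "numpy")
        d2 = sp.lambdify(x, sp.diff(f, x, 2), "numpy")
        return d1, d2
    if isinstance(f, tuple) and len(f) == 3:
        _, d1, d2 = f
        return d1, d2
    raise TypeError("pass a sympy expression or a (f, f', f'') callable triple")


def stein_check(f, rho: float, under_rate: float | None = None,
                epsabs: float = 1e-10) -> float:
    """E[(A_Q f)(X)] for Q = Exp(rho), X ~ Exp(under_rate or rho).

    Zero (to quadrature accuracy) when X follows the characterised law;
    evaluating under a different rate demonstrates the power of the
    characterisation.  ``f`` is a sympy expression in one symbol or a triple
    of callables (f, f', f'').
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    d1, d2 = _as_derivatives(f)
    lam = under_rate if under_rate is not None else rho

    def integrand(x):
        return ((1 - rho * x) * d1(x) + x * d2(x)) * lam * np.exp(-lam * x)

    val, err = integrate.quad(integrand, 0, np.inf, epsabs=epsabs, limit=200)
    if not np.isfinite(val) or err > 1e-6:
        raise ValueError("test function has a non-integrable tail")
    return float(val)


def quantile_flow(cdf: Callable, pdf: Callable, theta: float, y: float,
                  dtheta: float | None = None) -> float:
    """Velocity of a fixed quantile under a parameter change:
    dy/dtheta = - (dF/dtheta) / f(y; theta).

    ``cdf`` and ``pdf`` are callables (y, theta); the parameter derivative of
    the distribution function is taken by central differences when no closed
    form is supplied.
    """
    fy = pdf(y, theta)
    if fy <= 0:
        raise ValueError("zero density at the requested point")
    h = dtheta if dtheta is not None else 1e-6 * max(abs(theta), 1.0)
    dF = (cdf(y, theta + h) - cdf(y, theta - h)) / (2 * h)
    return float(-dF / fy)
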