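"""Construction of factorisable transformations by the method of characteristics.

A block density f(y_1,...,y_m; psi, lambda) admits a marginal-likelihood
factorisation when it can be written as

    f = kappa * prod_j dw_j/dy_j * g(w_1(y_1), ..., w_m(y_m); psi)

with bijective per-outcome maps w_j carrying all the lambda-dependence and a
nuisance-free base density g.  A statistic s(y) whose distribution is free of
lambda must then be constant along the flow of the block in lambda, i.e. solve
the first-order linear homogeneous PDE

    sum_j a_j(y) ds/dy_j = 0,     a_j(y) = d y_j(w_j; psi, lambda) / d lambda,

which the method of characteristics reduces to an ODE whose first integrals
are exactly the admissible transformations.  This module verifies the
factorised form, builds the characteristic coefficients, solves the PDE
(symbolically, with a numeric characteristic-tracing fallback), tests joint
solvability for two nuisance parameters, and handles the perturbed
(inhomogeneous) variant in which the right-hand side is a slowly varying
function of lambda rather than zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .catalog import ModelSpec, UnknownModelError

__all__ = [
    "ChangeOfVariables",
    "CharacteristicField",
    "Transformation",
    "PerturbationSpec",
    "FactorisationReport",
    "SolvabilityReport",
    "catalog_change_of_variables",
    "reference_params",
    "check_factorisation_form",
    "characteristic_field",
    "solve_characteristics",
    "solve_characteristics_block",
    "joint_solvability",
    "solve_inhomogeneous",
    "taylor_simplify",
    "functionally_dependent",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ChangeOfVariables:
    """Per-outcome bijective maps w_j(y_j; psi, lambda) with base density g."""

    outcome_symbols: tuple
    aux_symbols: tuple  # symbols of the transformed variables w_j
    forward: tuple  # w_j as expressions in y_j and parameters
    base_density: sp.Expr  # g in the aux symbols and interest parameters
    kappa_const: sp.Expr = sp.Integer(1)

    def forward_subs(self):
        """Substitution map aux symbol -> forward expression."""
        return dict(zip(self.aux_symbols, self.forward))

    def inverse(self, j: int) -> sp.Expr | None:
        """Closed-form inverse y_j(w_j), or None if sympy cannot solve."""
        y = self.outcome_symbols[j]
        w = self.aux_symbols[j]
        sols = sp.solve(sp.Eq(w, self.forward[j]), y)
        return sols[0] if len(sols) >= 1 else None

    def check_identity(self) -> bool:
        """forward(inverse(w)) == w symbolically, per outcome."""
        for j, w in enumerate(self.aux_symbols):
            inv = self.inverse(j)
            if inv is None:
                return False
            back = sp.simplify(self.forward[j].subs(self.outcome_symbols[j], inv) - w)
            if back != 0:
                return False
        return True


@dataclass(frozen=True)
class CharacteristicField:
    """Coefficients a_j(y; psi, lambda) of the characteristic PDE."""

    outcome_symbols: tuple
    coeffs: tuple
    wrt: sp.Symbol  # the nuisance symbol differentiated against

    @property
    def coeff_t(self) -> sp.Expr:
        return self.coeffs[0]

    @property
    def coeff_c(self) -> sp.Expr:
        return self.coeffs[1]

    def residual(self, expr: sp.Expr) -> sp.Expr:
        """a . grad s, which must vanish for a solution s."""
        return sp.simplify(
            sum(a * sp.diff(expr, y) for a, y in zip(self.coeffs, self.outcome_symbols))
        )


@dataclass
class Transformation:
    """A candidate statistic s(y), one representative of the class {s^k, k != 0}."""

    expr: sp.Expr | None
    outcome_symbols: tuple
    parameter_free: bool = True
    family_exponent: float = 1.0
    completion: sp.Expr | None = None
    method: str = "symbolic"
    numeric_fn: Callable | None = None  # set when method == "numeric"

    def __call__(self, *values, params: dict | None = None):
        if self.method == "numeric":
            return self.numeric_fn(*values)
        subs = {str(k): v for k, v in (params or {}).items()}
        e = self.expr.subs(
            {s: subs[str(s)] for s in self.expr.free_symbols if str(s) in subs}
        )
        fn = sp.lambdify(self.outcome_symbols, e, "numpy")
        return fn(*values)

    @property
    def free_parameters(self) -> tuple:
        if self.expr is None:
            return ()
        return tuple(
            s for s in self.expr.free_symbols if s not in self.outcome_symbols
        )


@dataclass(frozen=True)
class PerturbationSpec:
    """Quadratic local expansion h(lambda) ~ kappa + eps1*d + eps2*d^2, d = lambda - lambda0.

    This kappa is the expansion constant of the perturbed equation, a distinct
    quantity from the normalising constant of the factorised density.
    """

    base_point: float
    const: float = 0.0
    eps1: float = 0.0
    eps2: float = 0.0

    def h(self, lam: sp.Symbol) -> sp.Expr:
        d = lam - self.base_point
        return self.const + self.eps1 * d + self.eps2 * d**2

    def integral(self, lam: sp.Symbol) -> sp.Expr:
        """Antiderivative of h vanishing at the base point."""
        d = lam - self.base_point
        return self.const * d + sp.Rational(1, 2) * self.eps1 * d**2 + sp.Rational(
            1, 3
        ) * self.eps2 * d**3


@dataclass(frozen=True)
class FactorisationReport:
    ok: bool
    symbolic: bool
    max_relative_residual: float | None = None
    message: str = ""


@dataclass(frozen=True)
class SolvabilityReport:
    solvable: bool
    determinant: sp.Expr = sp.Integer(0)
    recommendation: str = ""


# --------------------------------------------------------------------------
# catalog changes of variables (the worked derivations)
# --------------------------------------------------------------------------


def catalog_change_of_variables(model: ModelSpec) -> ChangeOfVariables:
    """The standard nuisance-absorbing change of variables for a catalog model."""
    name = model.name
    ys = model.outcome_symbols
    params = {str(s): s for s in model.parameters}
    if name == "logistic_pair":
        raise ValueError("binary model: no smooth change of variables applies")
    m = len(ys)
    us = sp.symbols(f"u1:{m + 1}", positive=all(s.is_positive for s in ys))
    if not isinstance(us, tuple):
        us = (us,)
    lam = params.get("lambda")
    psi = params.get("psi")
    exp_base = sp.exp(-sum(us))
    if name == "exp_hazard_pair":
        fwd = (lam * psi * ys[0], lam * ys[1] / psi)
        g = exp_base
    elif name == "exp_mean_shift_pair":
        fwd = (ys[0] * lam / (1 - lam * psi), ys[1] * lam / (1 + lam * psi))
        g = exp_base
    elif name == "weibull_pair":
        alpha = params["alpha"]
        fwd = (lam * psi * ys[0] ** alpha, (lam / psi) * ys[1] ** alpha)
        g = exp_base
    elif name == "cauchy_pair":
        fwd = ((ys[0] - lam) / psi, (ys[1] - lam) / psi)
        g = 1 / (sp.pi**2 * (1 + us[0] ** 2) * (1 + us[1] ** 2))
    elif name == "normal_pair":
        mu, sigma2 = params["mu"], params["sigma2"]
        fwd = (ys[0] - mu, ys[1] - mu)
        g = sp.exp(-(us[0] ** 2 + us[1] ** 2) / (2 * sigma2)) / (2 * sp.pi * sigma2)
    elif name == "exp_triplet":
        psi1, psi2 = params["psi1"], params["psi2"]
        fwd = (lam * psi1 * ys[0], lam * psi2 * ys[1], lam * ys[2])
        g = exp_base
    elif name == "exp_reg":
        xi, x1 = model.covariates
        fwd = (
            ys[0] * sp.exp(-xi * psi) / lam,
            ys[1] * sp.exp(-x1 * psi) / lam,
        )
        g = exp_base
    elif name == "loglogistic_reg":
        beta = params["beta"]
        xi, x1 = model.covariates
        a_i = lam * sp.exp(xi * psi)
        a_1 = lam * sp.exp(x1 * psi)
        fwd = ((ys[0] / a_i) ** beta, (ys[1] / a_1) ** beta)
        g = 1 / ((1 + us[0]) ** 2 * (1 + us[1]) ** 2)
    else:
        raise UnknownModelError(name)
    return ChangeOfVariables(
        outcome_symbols=ys, aux_symbols=tuple(us), forward=fwd, base_density=g
    )


_REFERENCE = {
    "psi": 0.8,
    "lambda": 0.6,
    "alpha": 1.7,
    "beta": 1.4,
    "psi1": 0.8,
    "psi2": 1.3,
    "mu": 0.4,
    "sigma2": 1.2,
    "xi": 0.3,
    "x1": -0.5,
}


def reference_params(model: ModelSpec) -> dict:
    """A representative interior parameter point for numeric grid checks."""
    out = {}
    for s in tuple(model.parameters) + tuple(model.covariates):
        out[s] = _REFERENCE.get(str(s), 0.7)
    if model.name == "exp_mean_shift_pair":
        out = {s: (0.4 if str(s) == "psi" else v) for s, v in out.items()}
    return out


def _support_grid(support, n: int) -> np.ndarray:
    lo, hi = support
    if lo == 0:
        # logarithmic grid spanning the bulk of a unit-rate positive variable
        return np.geomspace(0.05, 4.0, n)
    return np.linspace(-2.5, 2.5, n)


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------


def check_factorisation_form(
    model: ModelSpec, cov: ChangeOfVariables, grid_n: int = 5
) -> FactorisationReport:
    """Verify density == kappa * prod dw_j/dy_j * g(w(y)).

    The verdict is True when the ratio simplifies to one symbolically;
    otherwise the maximum relative residual of ``ratio - 1`` over a grid of
    outcomes and nuisance values is reported and the verdict is False.
    """
    kappa = sp.nsimplify(cov.kappa_const)
    if kappa.is_number and kappa <= 0:
        raise ValueError("kappa must be a positive constant")
    g_sub = cov.base_density.subs(cov.forward_subs())
    jac = sp.Mul(*[sp.diff(w, y) for w, y in zip(cov.forward, model.outcome_symbols)])
    candidate = kappa * jac * g_sub

    _check_monotone_maps(model, cov)

    ratio = sp.simplify(model.density / candidate)
    if ratio == 1:
        return FactorisationReport(ok=True, symbolic=True)

    # numeric fallback over outcomes x nuisance values at reference interest
    ref = reference_params(model)
    lam = model.nuisances[0]
    f_num = sp.lambdify(
        tuple(model.outcome_symbols) + (lam,),
        (model.density / candidate).subs({k: v for k, v in ref.items() if k != lam}),
        "numpy",
    )
    grids = [_support_grid(s, grid_n) for s in model.support]
    lam_vals = np.linspace(0.4, 1.6, grid_n) * ref[lam]
    worst = 0.0
    for pt in itertools.product(*grids):
        for lv in lam_vals:
            r = f_num(*pt, lv)
            worst = max(worst, abs(r - 1.0))
    ok = worst < 1e-9
    return FactorisationReport(
        ok=ok,
        symbolic=False,
        max_relative_residual=float(worst),
        message="" if ok else "density does not match the factorised form",
    )


def _check_monotone_maps(model: ModelSpec, cov: ChangeOfVariables, n: int = 7) -> None:
    """Each w_j must be strictly monotone in y_j on the support (bijectivity)."""
    ref = reference_params(model)
    for w, y, support in zip(cov.forward, model.outcome_symbols, model.support):
        dw = sp.diff(w, y).subs(ref)
        fn = sp.lambdify(y, dw, "numpy")
        vals = np.asarray([fn(v) for v in _support_grid(support, n)], dtype=float)
        if not (np.all(vals > 0) or np.all(vals < 0)):
            raise ValueError(f"map {w} is not monotone in {y} on the support")


def characteristic_field(
    model: ModelSpec, cov: ChangeOfVariables, nuisance: sp.Symbol | str
) -> CharacteristicField:
    """Coefficients a_j = d y_j(w_j; psi, lambda)/d nuisance, back-substituted.

    Uses implicit differentiation of w_j(y_j; lambda) = const, which needs no
    closed-form inverse:  a_j = - (dw_j/d lambda) / (dw_j/dy_j).
    """
    if isinstance(nuisance, str):
        matches = [s for s in model.parameters if str(s) == nuisance]
        if not matches:
            raise ValueError(f"unknown nuisance symbol {nuisance!r}")
        nuisance = matches[0]
    coeffs = []
    for w, y in zip(cov.forward, model.outcome_symbols):
        dnu = sp.diff(w, nuisance)
        dy = sp.diff(w, y)
        if dy == 0:
            raise ValueError(f"map {w} does not depend on outcome {y}")
        coeffs.append(sp.simplify(-dnu / dy))
    return CharacteristicField(
        outcome_symbols=tuple(model.outcome_symbols),
        coeffs=tuple(coeffs),
        wrt=nuisance,
    )


def _strip_constants(expr: sp.Expr, outcomes: Sequence[sp.Symbol]) -> sp.Expr:
    """Drop multiplicative/additive factors free of the outcome symbols."""
    expr = sp.powsimp(sp.simplify(expr))
    changed = True
    while changed:
        changed = False
        if expr.is_Add:
            keep = [a for a in expr.args if a.free_symbols & set(outcomes)]
            if len(keep) < len(expr.args) and keep:
                expr = sp.Add(*keep)
                changed = True
        if expr.is_Mul:
            keep = [a for a in expr.args if a.free_symbols & set(outcomes)]
            if len(keep) < len(expr.args) and keep:
                expr = sp.Mul(*keep)
                changed = True
        if expr.is_Mul:
            # product of powers with proportional rational exponents: divide
            # the exponents by their gcd (class representative with k = 1)
            parts = [f.as_base_exp() for f in expr.args]
            if all(e.is_Rational for _, e in parts):
                import functools

                g = functools.reduce(sp.gcd, [abs(e) for _, e in parts])
                if g not in (0, 1):
                    expr = sp.Mul(*[bs ** (e / g) for bs, e in parts])
                    changed = True
        if expr.is_Pow and expr.exp.is_number and expr.exp != 1:
            # representative of the class {s^k}: take k = 1
            base = expr.base
            if base.free_symbols & set(outcomes):
                expr = base if expr.exp > 0 else 1 / base
                changed = True
        if isinstance(expr, sp.exp):
            arg = expr.args[0]
            if arg.free_symbols & set(outcomes):
                expr = arg
                changed = True
    return expr


def _monotone_direction(expr: sp.Expr, outcomes, param_vals) -> int:
    """Sign of ds/d(first outcome) on probe points; 0 when not monotone."""
    d = sp.diff(expr, outcomes[0]).subs(param_vals)
    fn = sp.lambdify(outcomes, d, "numpy")
    probes = [(1.3, 0.7), (2.1, 1.6), (0.6, 2.3)] if len(outcomes) == 2 else [
        tuple(0.5 + 0.4 * j + 0.2 * k for j in range(len(outcomes)))
        for k in range(3)
    ]
    signs = set()
    for pt in probes:
        try:
            v = float(fn(*pt))
        except (TypeError, ValueError, ZeroDivisionError):
            continue
        if np.isfinite(v) and v != 0:
            signs.add(int(np.sign(v)))
    if signs == {1}:
        return 1
    if signs == {-1}:
        return -1
    return 0


def _canonicalise(expr: sp.Expr, outcomes, param_vals=None) -> sp.Expr:
    """Canonical class representative: k = 1, constants stripped, increasing
    in the first outcome symbol where monotone."""
    param_vals = param_vals or {
        s: _REFERENCE.get(str(s), 0.5) for s in expr.free_symbols if s not in outcomes
    }
    expr = _strip_constants(expr, outcomes)
    if _monotone_direction(expr, outcomes, param_vals) < 0:
        if expr.is_Add:
            expr = -expr
        else:
            expr = 1 / expr
        expr = _strip_constants(sp.simplify(expr), outcomes)
    return expr


def _first_integral_ode(a, b, t, c):
    """First integral of dc/dt = b/a via sympy dsolve."""
    C = sp.Function("C_char")
    ode = sp.Eq(C(t).diff(t), sp.simplify(b / a).subs(c, C(t)))
    try:
        sols = sp.dsolve(ode, C(t))
    except (NotImplementedError, ValueError):
        return None
    if not isinstance(sols, list):
        sols = [sols]
    for sol in sols:
        eq = sp.Eq(sol.lhs.subs(C(t), c), sol.rhs.subs(C(t), c))
        consts = [s for s in eq.free_symbols if s.name == "C1"]
        if not consts:
            continue
        try:
            fi = sp.solve(eq, consts[0])
        except (NotImplementedError, ValueError):
            continue
        if fi:
            return sp.simplify(fi[0])
    return None


def solve_characteristics(field: CharacteristicField) -> Transformation:
    """Solve a ds/dt + b ds/dc = 0 for a first integral s(t, c).

    Symbolic ODE solution of dc/dt = b/a first; if that fails, characteristics
    are traced numerically and the resulting (non-symbolic) first integral is
    returned flagged ``method="numeric"``.
    """
    t, c = field.outcome_symbols[:2]
    a = sp.simplify(field.coeff_t)
    b = sp.simplify(field.coeff_c)
    if a == 0 and b == 0:
        raise ValueError("both characteristic coefficients vanish identically")
    if a == 0:
        return Transformation(t, field.outcome_symbols, completion=c)
    if b == 0:
        return Transformation(c, field.outcome_symbols, completion=t)
    fi = _first_integral_ode(a, b, t, c)
    if fi is not None:
        expr = _canonicalise(fi, field.outcome_symbols)
        pf = not (expr.free_symbols - set(field.outcome_symbols))
        tr = Transformation(
            expr,
            field.outcome_symbols,
            parameter_free=pf,
            completion=field.outcome_symbols[-1],
        )
        res = field.residual(expr)
        if res != 0 and sp.simplify(res) != 0:
            raise RuntimeError(f"candidate {expr} fails the PDE residual: {res}")
        return tr
    return _numeric_first_integral(field)


def _numeric_first_integral(field: CharacteristicField) -> Transformation:
    """Trace dc/dt = b/a numerically: s(t, c) := level of the characteristic
    through (t, c) at a reference abscissa t_ref."""
    t, c = field.outcome_symbols[:2]
    ref = {
        s: _REFERENCE.get(str(s), 0.5)
        for s in (field.coeff_t.free_symbols | field.coeff_c.free_symbols)
        if s not in (t, c)
    }
    slope = sp.lambdify((t, c), sp.simplify(field.coeff_c / field.coeff_t).subs(ref))
    t_ref = 1.0

    def s_fn(tv, cv):
        tv = np.atleast_1d(np.asarray(tv, dtype=float))
        cv = np.atleast_1d(np.asarray(cv, dtype=float))
        out = np.empty_like(tv)
        for i, (t0, c0) in enumerate(zip(tv, cv)):
            if np.isclose(t0, t_ref):
                out[i] = c0
                continue
            sol = solve_ivp(
                lambda x, y: np.atleast_1d(slope(x, y[0])),
                (t0, t_ref),
                [c0],
                rtol=1e-9,
                atol=1e-12,
                dense_output=False,
            )
            out[i] = sol.y[0, -1]
        return out if out.size > 1 else float(out[0])

    return Transformation(
        expr=None,
        outcome_symbols=field.outcome_symbols,
        parameter_free=False,
        completion=field.outcome_symbols[-1],
        method="numeric",
        numeric_fn=s_fn,
    )


def functionally_dependent(s1: sp.Expr, s2: sp.Expr, outcomes) -> bool:
    """True when s1 and s2 share level sets (vanishing 2x2 Jacobian)."""
    t, c = outcomes[:2]
    jac = sp.simplify(
        sp.diff(s1, t) * sp.diff(s2, c) - sp.diff(s1, c) * sp.diff(s2, t)
    )
    return jac == 0


def solve_characteristics_block(field: CharacteristicField) -> list[Transformation]:
    """First integrals for a block of m outcomes.

    Pairs each outcome with the last one and solves the two-variable
    characteristic ODE, yielding m - 1 functionally independent integrals;
    the completion statistic is the last outcome itself.  Joint bijectivity
    of (s_1, ..., s_{m-1}, r) is checked by a non-vanishing Jacobian on a
    probe grid.
    """
    ys = field.outcome_symbols
    m = len(ys)
    if m < 2:
        raise ValueError("need block size m >= 2")
    if m == 2:
        return [solve_characteristics(field)]
    out = []
    for j in range(m - 1):
        sub = CharacteristicField(
            outcome_symbols=(ys[j], ys[-1]),
            coeffs=(field.coeffs[j], field.coeffs[-1]),
            wrt=field.wrt,
        )
        tr = solve_characteristics(sub)
        tr.completion = ys[-1]
        out.append(tr)
    _check_block_jacobian(out, ys)
    return out


def _check_block_jacobian(transforms, ys) -> None:
    exprs = [tr.expr for tr in transforms] + [ys[-1]]
    J = sp.Matrix([[sp.diff(e, y) for y in ys] for e in exprs])
    det = sp.simplify(J.det())
    if det == 0:
        raise ValueError("fewer than m-1 independent first integrals found")
    subs = {s: _REFERENCE.get(str(s), 0.5) for s in det.free_symbols if s not in ys}
    fn = sp.lambdify(ys, det.subs(subs), "numpy")
    pts = np.linspace(0.4, 2.2, 4)
    for pt in itertools.product(pts, repeat=len(ys)):
        v = float(fn(*pt))
        if not np.isfinite(v) or np.isclose(v, 0.0):
            raise ValueError("block transformation Jacobian vanishes on the grid")


def joint_solvability(
    field1: CharacteristicField, field2: CharacteristicField
) -> SolvabilityReport:
    """Can one statistic annihilate both nuisance directions simultaneously?

    For two outcomes a common non-constant solution of the two characteristic
    PDEs exists iff the characteristic directions coincide everywhere, i.e.
    the determinant a1*b2 - a2*b1 vanishes identically.
    """
    if field1.outcome_symbols != field2.outcome_symbols:
        raise ValueError("fields must share outcome symbols")
    if len(field1.outcome_symbols) != 2:
        raise ValueError("determinant test applies to two outcomes")
    det = sp.simplify(
        field1.coeff_t * field2.coeff_c - field2.coeff_t * field1.coeff_c
    )
    if det == 0:
        return SolvabilityReport(solvable=True, determinant=det)
    return SolvabilityReport(
        solvable=False,
        determinant=det,
        recommendation=(
            "no common non-constant solution; eliminate the per-block nuisance "
            "(each block introduces a fresh copy of it)"
        ),
    )


def solve_inhomogeneous(
    field: CharacteristicField, pert: PerturbationSpec
) -> Transformation:
    """Solve a s_t + b s_c = h(lambda) with h quadratic around a base point.

    Along the characteristic flow parameterised by lambda (the transformed
    variables w, v held fixed), ds/d lambda = h(lambda), so a particular term
    is the antiderivative of h; the returned statistic is the homogeneous
    first integral plus that lambda-dependent term.  As eps1, eps2 -> 0 with
    the constant zero, the homogeneous solution is recovered exactly.
    """
    hom = solve_characteristics(field)
    if hom.expr is None:
        raise ValueError("no closed-form homogeneous solution to perturb")
    lam = field.wrt
    part = pert.integral(lam)
    expr = hom.expr + part
    pf = not (expr.free_symbols - set(field.outcome_symbols))
    tr = Transformation(
        sp.simplify(expr),
        field.outcome_symbols,
        parameter_free=pf,
        completion=hom.completion,
    )
    # exact-limit contract: zero perturbation returns the homogeneous solution
    if pert.const == 0 and pert.eps1 == 0 and pert.eps2 == 0:
        assert sp.simplify(tr.expr - hom.expr) == 0
    return tr


def taylor_simplify(
    transformation: Transformation,
    interest: sp.Symbol | str = "psi",
    nuisance: sp.Symbol | str = "lambda",
    at: float = 0.0,
) -> tuple[Transformation, Transformation | None]:
    """Leading-order expansion of a parameter-dependent statistic in the
    product interest*nuisance around ``at``; returns (leading, plug_in).

    The plug-in variant replaces any remaining parameter-dependent exponent on
    an outcome symbol by the crude data-based estimate t/c (ratio of the two
    outcomes), the first-moment estimator of that exponent.
    """
    expr = transformation.expr
    if expr is None:
        raise ValueError("numeric transformations cannot be expanded")
    syms = {str(s): s for s in expr.free_symbols}
    if str(interest) not in syms or str(nuisance) not in syms:
        return transformation, None  # already parameter-free
    psi = syms[str(interest)]
    lam = syms[str(nuisance)]
    rho = sp.Symbol("_rho")
    expanded = expr.subs(lam, rho / psi)
    series = sp.simplify(sp.series(expanded, rho, at, 1).removeO())
    lead = _canonicalise(series, transformation.outcome_symbols)
    leading = Transformation(
        lead,
        transformation.outcome_symbols,
        parameter_free=not (lead.free_symbols - set(transformation.outcome_symbols)),
        completion=transformation.completion,
    )
    plug = _plug_in_exponent(expr, transformation.outcome_symbols, (psi, lam))
    plug_tr = None
    if plug is not None:
        plug_tr = Transformation(
            plug, transformation.outcome_symbols, parameter_free=True,
            completion=transformation.completion,
        )
    return leading, plug_tr


def _plug_in_exponent(expr, outcomes, params):
    """Replace a parameter-dependent exponent on an outcome by t/c."""
    t, c = outcomes[:2]
    crude = t / c
    hits = {}
    for p in expr.atoms(sp.Pow):
        if p.base in outcomes and (p.exp.free_symbols & set(params)):
            hits[p] = p.base ** crude
    if not hits:
        return None
    return expr.xreplace(hits)
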