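"""Equilibria and local stability of the transformed 4-D couple system.

At an equilibrium the pass-through rows force y2* = y4* = 0, and the
remaining two algebraic equations reduce, after eliminating y1, to a
univariate polynomial of degree <= 9 in y3.  The Jacobian at an equilibrium
has the fixed sparsity pattern

    [ 0    1   0   0 ]
    [ -a1  0   a   0 ]        a = beta1 * (1 - 3*eps*y3*^2)
    [ 0    0   0   1 ]        b = beta2 * (1 - 3*eps*y1*^2)
    [ b    0  -a2  0 ]

whose characteristic polynomial is biquadratic,
P(lambda) = lambda^4 + a1*lambda^2 + a2 with a1 = alpha1 + alpha2 and
a2 = alpha1*alpha2 - a*b.  Substituting k = lambda^2 gives a quadratic, and
two independent stability verdicts follow:

* fractional Routh-Hurwitz on (a1, a2): a1 > 0 and a2 > 0 implies local
  asymptotic stability for every order alpha in (0, 1); a2 < 0 implies
  instability (a positive real eigenvalue exists);
* the direct eigenvalue test: asymptotically stable iff every eigenvalue
  satisfies |arg(lambda)| > alpha*pi/2.

The two verdicts can disagree when the k roots are complex and alpha is
close to 1; the report flags rather than resolves such cases.
"""

from __future__ import annotations

import cmath
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial import polynomial as npoly

from .fde import FractionalOrder
from .model import CoupleParameters, rhs_2d, transform_to_first_order

__all__ = [
    "Equilibrium",
    "JacobianSummary",
    "CharCoefficients",
    "StabilityReport",
    "NoEquilibriumError",
    "find_equilibria",
    "jacobian_at",
    "characteristic_coefficients",
    "reduced_roots",
    "routh_hurwitz_classify",
    "arg_condition_classify",
    "full_stability_report",
]

SIGN_TOL = 1e-12  # strictness tolerance for sign tests; boundary -> indeterminate


class NoEquilibriumError(RuntimeError):
    """No real equilibrium survived the residual filter."""


@dataclass(frozen=True)
class Equilibrium:
    """A steady state (y1*, 0, y3*, 0) with its rhs residual (max-norm)."""

    y: tuple
    residual: float

    @property
    def y1(self) -> float:
        return self.y[0]

    @property
    def y3(self) -> float:
        return self.y[2]

    @property
    def is_positive(self) -> bool:
        return self.y1 > 0 and self.y3 > 0


@dataclass(frozen=True)
class JacobianSummary:
    a: float
    b: float
    J: np.ndarray


@dataclass(frozen=True)
class CharCoefficients:
    """Coefficients of the reduced quadratic k^2 + a1*k + a2 (k = lambda^2)."""

    a1: float
    a2: float


@dataclass(frozen=True)
class StabilityReport:
    equilibrium: Equilibrium
    jac: JacobianSummary
    coeffs: CharCoefficients
    k_roots: tuple
    lambda_roots: tuple
    routh_verdict: str
    arg_verdict: str
    verdicts_agree: bool
    alpha: FractionalOrder

    def to_dict(self) -> dict:
        def c2d(z):
            return {"re": float(z.real), "im": float(z.imag)}

        return {
            "equilibrium": {"y": list(self.equilibrium.y),
                            "residual": self.equilibrium.residual},
            "jacobian": {"a": self.jac.a, "b": self.jac.b,
                         "J": self.jac.J.tolist()},
            "char_coefficients": {"a1": self.coeffs.a1, "a2": self.coeffs.a2},
            "k_roots": [c2d(k) for k in self.k_roots],
            "lambda_roots": [c2d(l) for l in self.lambda_roots],
            "routh_verdict": self.routh_verdict,
            "arg_verdict": self.arg_verdict,
            "verdicts_agree": self.verdicts_agree,
            "alpha": self.alpha.alpha,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def find_equilibria(params: CoupleParameters, tol: float = 1e-8) -> list[Equilibrium]:
    """All real equilibria of the transformed system, residual-filtered.

    Sets y2 = y4 = 0, eliminates y1 = (beta1*y3*(1 - eps*y3^2) + A1)/alpha1
    from the first algebraic equation, substitutes into the second to get a
    degree <= 9 polynomial in y3, and takes its real companion-matrix roots.
    Back-substituted candidates are kept when the 2-D rhs max-norm residual
    is below ``tol``, then de-duplicated.

    The polynomial coefficients are assembled symbolically from the
    parameters (products of exact coefficient polynomials), avoiding the
    floating cancellation a naive expansion would introduce; this is what
    makes the printed 5-decimal equilibrium reproducible.
    """
    p = params
    if p.alpha1 == 0:
        raise ValueError("elimination requires alpha1 != 0")
    if tol <= 0:
        raise ValueError("tol must be positive")

    # y1 as a polynomial in y3 (coefficients in ascending order)
    y1_poly = np.array([p.A1 / p.alpha1, p.beta1 / p.alpha1, 0.0,
                        -p.beta1 * p.eps / p.alpha1])
    # second equation: -alpha2*y3 + beta2*(y1 - eps*y1^3) + A2 = 0
    y1_cubed = npoly.polypow(y1_poly, 3)
    poly = npoly.polymul([p.beta2], npoly.polysub(
        y1_poly, npoly.polymul([p.eps], y1_cubed)))
    poly = npoly.polyadd(poly, [p.A2, -p.alpha2])
    poly = np.trim_zeros(np.atleast_1d(poly), trim="b")
    if poly.size <= 1:
        return []

    roots = npoly.polyroots(poly)
    # scale-aware realness filter for companion-matrix roots
    im_tol = 1e-8 * max(1.0, float(np.max(np.abs(roots))) if roots.size else 1.0)

    found: list[Equilibrium] = []
    for r in roots:
        if abs(r.imag) > im_tol:
            continue
        y3 = float(r.real)
        y1 = float(npoly.polyval(y3, y1_poly))
        f1, f2 = rhs_2d(p, y1, y3)
        residual = max(abs(f1), abs(f2))
        if residual >= tol:
            continue
        if any(math.isclose(y1, e.y1, rel_tol=0, abs_tol=10 * im_tol)
               and math.isclose(y3, e.y3, rel_tol=0, abs_tol=10 * im_tol)
               for e in found):
            continue
        found.append(Equilibrium(y=(y1, 0.0, y3, 0.0), residual=residual))
    found.sort(key=lambda e: (e.y1, e.y3))
    return found


def jacobian_at(params: CoupleParameters, eq: Equilibrium) -> JacobianSummary:
    """Jacobian of the 4-D rhs at an equilibrium, via the closed-form a, b."""
    p = params
    a = p.beta1 * (1.0 - 3.0 * p.eps * eq.y3**2)
    b = p.beta2 * (1.0 - 3.0 * p.eps * eq.y1**2)
    J = np.array([
        [0.0, 1.0, 0.0, 0.0],
        [-p.alpha1, 0.0, a, 0.0],
        [0.0, 0.0, 0.0, 1.0],
        [b, 0.0, -p.alpha2, 0.0],
    ])
    return JacobianSummary(a=a, b=b, J=J)


def characteristic_coefficients(params: CoupleParameters,
                                jac: JacobianSummary) -> CharCoefficients:
    """(a1, a2) of the biquadratic characteristic polynomial."""
    return CharCoefficients(
        a1=params.alpha2 + params.alpha1,
        a2=params.alpha1 * params.alpha2 - jac.a * jac.b,
    )


def reduced_roots(coeffs: CharCoefficients) -> tuple[complex, complex]:
    """Both roots of k^2 + a1*k + a2 = 0 by the quadratic formula."""
    a1, a2 = coeffs.a1, coeffs.a2
    disc = cmath.sqrt(complex(a1 * a1 - 4.0 * a2))
    return ((-a1 + disc) / 2.0, (-a1 - disc) / 2.0)


def routh_hurwitz_classify(coeffs: CharCoefficients,
                           tol: float = SIGN_TOL) -> str:
    """Fractional Routh-Hurwitz verdict from the signs of (a1, a2).

    a1 > 0 and a2 > 0  -> "stable" (for every order alpha in (0, 1));
    a2 < 0             -> "unstable" (a positive real eigenvalue exists);
    anything else      -> "indeterminate" (outside both sign conditions).
    """
    if coeffs.a1 > tol and coeffs.a2 > tol:
        return "stable"
    if coeffs.a2 < -tol:
        return "unstable"
    return "indeterminate"


def arg_condition_classify(lambdas, alpha: FractionalOrder,
                           tol: float = SIGN_TOL) -> str:
    """Direct eigenvalue-argument verdict: |arg(lambda)| > alpha*pi/2.

    "stable" if every eigenvalue's argument exceeds the threshold by more
    than ``tol``, "unstable" if some eigenvalue's argument falls short by
    more than ``tol``, "marginal" otherwise.  A zero eigenvalue has no
    argument and is treated as violating the condition.
    """
    threshold = alpha.alpha * math.pi / 2.0
    args = []
    for lam in lambdas:
        lam = complex(lam)
        if lam == 0:
            return "unstable"
        args.append(abs(cmath.phase(lam)))
    if all(a > threshold + tol for a in args):
        return "stable"
    if any(a < threshold - tol for a in args):
        return "unstable"
    return "marginal"


def _select_equilibrium(equilibria: list[Equilibrium]) -> Equilibrium:
    # Prefer the positive equilibrium of smallest norm (the "positive
    # equilibrium point" of the simulations); else the smallest residual.
    positive = [e for e in equilibria if e.is_positive]
    if positive:
        return min(positive, key=lambda e: math.hypot(e.y1, e.y3))
    return min(equilibria, key=lambda e: e.residual)


def full_stability_report(params: CoupleParameters,
                          alpha: FractionalOrder | None = None,
                          tol: float = 1e-8) -> StabilityReport:
    """Assemble the complete stability analysis for one parameter set.

    Selects the reporting equilibrium, computes the Jacobian summary, the
    reduced quadratic's k roots, the four lambda roots (both square roots
    of each k, principal branch), and both classifications.
    """
    if alpha is None:
        alpha = FractionalOrder(params.alpha)
    equilibria = find_equilibria(params, tol=tol)
    if not equilibria:
        raise NoEquilibriumError(
            "no real equilibrium found for these parameters")
    eq = _select_equilibrium(equilibria)
    jac = jacobian_at(params, eq)
    coeffs = characteristic_coefficients(params, jac)
    k1, k2 = reduced_roots(coeffs)
    lambdas = []
    for k in (k1, k2):
        s = cmath.sqrt(k)  # principal branch, arg in (-pi/2, pi/2]
        lambdas.extend([s, -s])
    routh = routh_hurwitz_classify(coeffs)
    argv = arg_condition_classify(lambdas, alpha)
    return StabilityReport(
        equilibrium=eq, jac=jac, coeffs=coeffs,
        k_roots=(k1, k2), lambda_roots=tuple(lambdas),
        routh_verdict=routh, arg_verdict=argv,
        verdicts_agree=(routh == argv),
        alpha=alpha,
    )
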