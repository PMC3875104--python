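"""A-priori upper bounds for 2-D Caputo systems of order alpha in (0, 1).

Given right-hand sides dominated by a linear envelope in |x1|, |x2| with
continuous nonnegative coefficient functions,

    |f1(t, x1, x2)| <= a1(t)|x1| + b1(t)|x2|,
    |f2(t, x1, x2)| <= b2(t)|x1| + a2(t)|x2|,

the solutions started from zero satisfy explicit upper-bound curves built
from three ingredients:

* a closed-form Beta-function identity for the convolution integral
  ``int_0^t (t-s)^{p(beta-1)} s^{p(gamma-1)} ds`` (:func:`beta_integral`);
* the Hoelder conjugate pair p = (1+4a)/(1+3a), q = (1+4a)/a and the
  nondecreasing kernel
  ``k*(t) = t^{q a - 1} B^{q/p}[m, m] / Gamma^q(a)`` with
  m = p(a-1)+1 = 4a^2/(1+3a) (:func:`holder_exponents`, :func:`kstar`);
* a coupled two-function Gronwall-type inequality
  (:func:`coupled_gronwall_bound`).

:func:`theorem9_bounds` combines them into the bound curves

    |x1(t)| <= t^{a-1} * exp{ (1/q) k*(t) [ int_0^t a1^q
               + int_0^t b1^q Psi2 (k* int_0^s b2^q Psi1) ] }

(and symmetrically for x2), with Psi_i(t) = exp(k*(t) int_0^t a_i^q).

A structural caveat, documented rather than patched: the envelope forces
f(t, 0, 0) = 0, so the couple model with nonzero attraction constants does
not satisfy it, and under the envelope the only solution with zero initial
data is the zero function.  The machinery is therefore exposed generically;
:func:`couple_envelope` derives constant coefficients for the attraction-free
model on a stated box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import integrate as _integrate
from scipy.special import betaln, gammaln

from .fde import FractionalOrder, Trajectory
from .model import CoupleParameters

__all__ = [
    "BoundExponents",
    "CoefficientFunctions",
    "GronwallInputs",
    "BoundCurve",
    "ScaledTrajectory",
    "BoundVerification",
    "beta_integral",
    "holder_exponents",
    "kstar",
    "coupled_gronwall_bound",
    "theorem9_bounds",
    "scaled_trajectory",
    "verify_bound",
    "couple_envelope",
]

_MONO_SLACK = 1e-12


@dataclass(frozen=True)
class BoundExponents:
    """Hoelder conjugate pair attached to an order alpha in (0, 1)."""

    p: float
    q: float
    alpha: FractionalOrder


@dataclass(frozen=True)
class CoefficientFunctions:
    """Envelope coefficients a1(t), a2(t), b1(t), b2(t), vectorized in t."""

    a1_t: Callable[[np.ndarray], np.ndarray]
    a2_t: Callable[[np.ndarray], np.ndarray]
    b1_t: Callable[[np.ndarray], np.ndarray]
    b2_t: Callable[[np.ndarray], np.ndarray]

    @classmethod
    def constant(cls, a1: float, a2: float, b1: float, b2: float):
        for name, v in (("a1", a1), ("a2", a2), ("b1", b1), ("b2", b2)):
            if v < 0:
                raise ValueError(f"envelope coefficient {name} must be >= 0")
        return cls(
            a1_t=lambda t: np.full_like(np.asarray(t, dtype=float), a1),
            a2_t=lambda t: np.full_like(np.asarray(t, dtype=float), a2),
            b1_t=lambda t: np.full_like(np.asarray(t, dtype=float), b1),
            b2_t=lambda t: np.full_like(np.asarray(t, dtype=float), b2),
        )


@dataclass(frozen=True)
class GronwallInputs:
    """Data of the coupled integral inequality.

    f1, f2 : nondecreasing nonnegative forcing terms, vectorized in t
    phi    : kernels phi11, phi12, phi21, phi22 as callables (t, s) -> value,
             each nonnegative and nondecreasing in t for fixed s; must
             broadcast over an array of s at fixed scalar t
    """

    f1: Callable[[np.ndarray], np.ndarray]
    f2: Callable[[np.ndarray], np.ndarray]
    phi11: Callable[[float, np.ndarray], np.ndarray]
    phi12: Callable[[float, np.ndarray], np.ndarray]
    phi21: Callable[[float, np.ndarray], np.ndarray]
    phi22: Callable[[float, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class BoundCurve:
    """Evaluated a-priori bound curves on a strictly positive grid."""

    grid: np.ndarray
    bound_x1: np.ndarray
    bound_x2: np.ndarray
    kstar_values: np.ndarray
    Psi1: np.ndarray
    Psi2: np.ndarray

    def write_csv(self, path) -> None:
        header = "t,bound_x1,bound_x2,kstar,Psi1,Psi2"
        data = np.column_stack([self.grid, self.bound_x1, self.bound_x2,
                                self.kstar_values, self.Psi1, self.Psi2])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.17g")


@dataclass(frozen=True)
class ScaledTrajectory:
    """beta(t) = |x1(t)| t^{1-alpha}, gamma(t) = |x2(t)| t^{1-alpha}."""

    grid: np.ndarray
    beta_t: np.ndarray
    gamma_t: np.ndarray


@dataclass(frozen=True)
class BoundVerification:
    fraction_within: float
    worst_ratio: float
    n_points: int


def beta_integral(p: float, beta: float, gamma: float, t: float) -> float:
    """Closed form of ``int_0^t (t-s)^{p(beta-1)} s^{p(gamma-1)} ds``.

    Equals ``t^theta * B[p(gamma-1)+1, p(beta-1)+1]`` with
    theta = p(beta + gamma - 2) + 1, provided both Beta arguments are
    positive (otherwise the integral diverges and the call is rejected).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    xb = p * (beta - 1.0) + 1.0
    xg = p * (gamma - 1.0) + 1.0
    if xb <= 0 or xg <= 0:
        raise ValueError(
            f"non-integrable exponents: p(beta-1)+1={xb}, p(gamma-1)+1={xg}"
        )
    theta = p * (beta + gamma - 2.0) + 1.0
    return t**theta * math.exp(betaln(xg, xb))


def holder_exponents(alpha: FractionalOrder | float) -> BoundExponents:
    """The conjugate pair p = (1+4a)/(1+3a), q = (1+4a)/a for a in (0, 1).

    By construction 1/p + 1/q = 1, p(a-1)+1 = 4a^2/(1+3a) > 0 and
    q*a - 1 = 4a > 0, which is exactly what keeps the kernel ``k*``
    finite and vanishing at t = 0.
    """
    a = alpha.alpha if isinstance(alpha, FractionalOrder) else float(alpha)
    if not (0.0 < a < 1.0):
        raise ValueError(f"bounds analysis requires alpha in (0, 1), got {a}")
    p = (1.0 + 4.0 * a) / (1.0 + 3.0 * a)
    q = (1.0 + 4.0 * a) / a
    return BoundExponents(p=p, q=q, alpha=FractionalOrder(a))


def kstar(t, alpha: FractionalOrder | float):
    """The kernel ``k*(t) = t^{4a} B^{q/p}[m, m] / Gamma^q(a)``, m = p(a-1)+1.

    Nondecreasing in t and zero at t = 0 (its t-exponent q*a - 1 = 4a is
    positive).  The Beta and Gamma powers are assembled in log space to
    avoid overflow at the large exponents q/p and q.
    """
    ex = holder_exponents(alpha)
    a, p, q = ex.alpha.alpha, ex.p, ex.q
    m = p * (a - 1.0) + 1.0
    log_const = (q / p) * betaln(m, m) - q * gammaln(a)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    out = np.zeros_like(t_arr)
    mask = t_arr > 0
    out[mask] = np.power(t_arr[mask], q * a - 1.0) * math.exp(log_const)
    return float(out[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def _running_integral(kernel_of_t, grid: np.ndarray) -> np.ndarray:
    """I[k] = int_0^{g_k} kernel(g_k, s) ds by composite Simpson per point."""
    out = np.zeros(grid.size)
    for k in range(1, grid.size):
        s = grid[: k + 1]
        out[k] = _integrate.simpson(np.asarray(kernel_of_t(grid[k], s)), x=s)
    return out


def _check_monotone(name: str, values: np.ndarray) -> None:
    diffs = np.diff(values)
    bad = np.where(diffs < -_MONO_SLACK * np.maximum(1.0, np.abs(values[:-1])))[0]
    if bad.size:
        raise ValueError(
            f"{name} is not nondecreasing on the grid (first violation at "
            f"grid index {int(bad[0]) + 1})"
        )


def _refine(grid: np.ndarray) -> np.ndarray:
    mid = 0.5 * (grid[:-1] + grid[1:])
    return np.sort(np.concatenate([grid, mid]))


def coupled_gronwall_bound(inputs: GronwallInputs,
                           grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the coupled Gronwall-type bounds on ``grid``.

    For u, v satisfying

        u(t) <= f1(t) + int_0^t [phi11(t,s) u(s) + phi12(t,s) v(s)] ds
        v(t) <= f2(t) + int_0^t [phi21(t,s) u(s) + phi22(t,s) v(s)] ds

    returns the explicit dominating curves

        u(t) <= [f1 + f2 * int phi12 Phi2] *
                exp{ int phi11 + int phi12 Phi2 (int_0^s phi21 Phi1) }
        v(t) <= [f2 + f1 * int phi21 Phi1] *
                exp{ int phi22 + int phi21 Phi1 (int_0^s phi12 Phi2) }

    with Phi_i(t) = exp(int_0^t phi_ii(t, s) ds).  All integrals are
    composite Simpson on the evaluation grid; the nested inner integrals
    use a once-refined (midpoint-inserted) grid.  The monotonicity
    hypotheses are checked on the grid and violations are rejected with the
    offending index.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 3:
        raise ValueError("grid must be 1-D with at least 3 points")
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must start at 0 and increase strictly")

    f1 = np.asarray(inputs.f1(grid), dtype=float)
    f2 = np.asarray(inputs.f2(grid), dtype=float)
    for name, vals in (("f1", f1), ("f2", f2)):
        if np.any(vals < -_MONO_SLACK):
            raise ValueError(f"{name} must be nonnegative")
        _check_monotone(name, vals)
    for name, phi in (("phi11", inputs.phi11), ("phi12", inputs.phi12),
                      ("phi21", inputs.phi21), ("phi22", inputs.phi22)):
        # nondecreasing in t for fixed s, checked columnwise on the grid
        for j in range(0, grid.size, max(1, grid.size // 16)):
            s = grid[j]
            col = np.array([float(np.asarray(phi(t, np.array([s]))).reshape(-1)[0])
                            for t in grid[j:]])
            if np.any(col < -_MONO_SLACK):
                raise ValueError(f"{name} must be nonnegative")
            _check_monotone(f"{name}(., s={s})", col)

    fine = _refine(grid)
    idx = np.searchsorted(fine, grid)

    # Phi_i on the refined grid
    int11_fine = _running_integral(inputs.phi11, fine)
    int22_fine = _running_integral(inputs.phi22, fine)
    Phi1_fine = np.exp(int11_fine)
    Phi2_fine = np.exp(int22_fine)

    # nested inner integrals G1(s) = int_0^s phi21(s,tau) Phi1(tau) dtau
    G1_fine = _running_integral(
        lambda t, s: np.asarray(inputs.phi21(t, s)) * np.interp(s, fine, Phi1_fine),
        fine)
    G2_fine = _running_integral(
        lambda t, s: np.asarray(inputs.phi12(t, s)) * np.interp(s, fine, Phi2_fine),
        fine)

    def outer(kernel):
        return _running_integral(kernel, fine)[idx]

    int11 = int11_fine[idx]
    int22 = int22_fine[idx]
    C12 = outer(lambda t, s: np.asarray(inputs.phi12(t, s))
                * np.interp(s, fine, Phi2_fine))
    C21 = outer(lambda t, s: np.asarray(inputs.phi21(t, s))
                * np.interp(s, fine, Phi1_fine))
    D1 = outer(lambda t, s: np.asarray(inputs.phi12(t, s))
               * np.interp(s, fine, Phi2_fine) * np.interp(s, fine, G1_fine))
    D2 = outer(lambda t, s: np.asarray(inputs.phi21(t, s))
               * np.interp(s, fine, Phi1_fine) * np.interp(s, fine, G2_fine))

    u_bound = (f1 + f2 * C12) * np.exp(int11 + D1)
    v_bound = (f2 + f1 * C21) * np.exp(int22 + D2)
    return u_bound, v_bound


def theorem9_bounds(coeffs: CoefficientFunctions,
                    alpha: FractionalOrder | float,
                    grid: np.ndarray,
                    refine: int = 1) -> BoundCurve:
    """Evaluate the a-priori upper-bound curves on a strictly positive grid.

    The integrals from 0 are taken over an internal grid that prepends t = 0
    and inserts midpoints ``refine`` times; cumulative Simpson handles the
    running integrals, and the curves are reported at the user's grid points.
    The grid must be strictly positive because of the t^{alpha-1} prefactor.
    """
    ex = holder_exponents(alpha)
    a, q = ex.alpha.alpha, ex.q
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("grid must be 1-D with at least 2 points")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly positive and increasing "
                         "(the t^(alpha-1) prefactor is singular at 0)")

    fine = np.concatenate([[0.0], grid])
    for _ in range(max(0, refine)):
        fine = _refine(fine)
    idx = np.searchsorted(fine, grid)

    a1q = np.asarray(coeffs.a1_t(fine), dtype=float) ** q
    a2q = np.asarray(coeffs.a2_t(fine), dtype=float) ** q
    b1q = np.asarray(coeffs.b1_t(fine), dtype=float) ** q
    b2q = np.asarray(coeffs.b2_t(fine), dtype=float) ** q
    for name, vals in (("a1", a1q), ("a2", a2q), ("b1", b1q), ("b2", b2q)):
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"coefficient function {name} must be finite "
                             "and nonnegative on the grid")

    ks_fine = kstar(fine, ex.alpha)

    def cumint(y):
        return _integrate.cumulative_simpson(y, x=fine, initial=0.0)

    I_a1 = cumint(a1q)
    I_a2 = cumint(a2q)
    Psi1 = np.exp(ks_fine * I_a1)
    Psi2 = np.exp(ks_fine * I_a2)

    inner1 = ks_fine * cumint(b2q * Psi1)   # k*(s) int_0^s b2^q Psi1
    inner2 = ks_fine * cumint(b1q * Psi2)
    J1 = cumint(b1q * Psi2 * inner1)
    J2 = cumint(b2q * Psi1 * inner2)

    expo1 = (ks_fine * (I_a1 + J1) / q)[idx]
    expo2 = (ks_fine * (I_a2 + J2) / q)[idx]
    pref = grid ** (a - 1.0)
    curve = BoundCurve(
        grid=grid,
        bound_x1=pref * np.exp(expo1),
        bound_x2=pref * np.exp(expo2),
        kstar_values=ks_fine[idx],
        Psi1=Psi1[idx],
        Psi2=Psi2[idx],
    )
    if not (np.all(np.isfinite(curve.bound_x1))
            and np.all(np.isfinite(curve.bound_x2))):
        raise ValueError("bound curves overflowed; shorten the horizon or "
                         "shrink the coefficient functions")
    return curve


def scaled_trajectory(traj: Trajectory, alpha: FractionalOrder | float,
                      components: tuple[int, int] = (0, 1)) -> ScaledTrajectory:
    """The scaled curves beta = |x1| t^{1-a}, gamma = |x2| t^{1-a}.

    The t = 0 row is skipped (the scaling is defined for t > 0).
    ``components`` selects which state columns play (x1, x2) — (0, 2) for
    trajectories of the transformed 4-D system.
    """
    a = alpha.alpha if isinstance(alpha, FractionalOrder) else float(alpha)
    pos = traj.times > 0
    t = traj.times[pos]
    i, j = components
    scale = t ** (1.0 - a)
    return ScaledTrajectory(
        grid=t,
        beta_t=np.abs(traj.states[pos, i]) * scale,
        gamma_t=np.abs(traj.states[pos, j]) * scale,
    )


def verify_bound(traj: Trajectory, curve: BoundCurve,
                 components: tuple[int, int] = (0, 1)) -> BoundVerification:
    """Empirically check a trajectory against bound curves on a shared grid.

    Reports the fraction of grid points where both |x1| <= bound_x1 and
    |x2| <= bound_x2, and the worst ratio max(|x_i| / bound_i).
    """
    pos = traj.times > 0
    t = traj.times[pos]
    if t.size != curve.grid.size or not np.allclose(t, curve.grid,
                                                    rtol=0, atol=1e-12):
        raise ValueError("trajectory grid and bound-curve grid do not match")
    i, j = components
    x1 = np.abs(traj.states[pos, i])
    x2 = np.abs(traj.states[pos, j])
    within = (x1 <= curve.bound_x1) & (x2 <= curve.bound_x2)
    ratios = np.maximum(x1 / curve.bound_x1, x2 / curve.bound_x2)
    return BoundVerification(
        fraction_within=float(np.mean(within)),
        worst_ratio=float(np.max(ratios)),
        n_points=int(t.size),
    )


def couple_envelope(params: CoupleParameters, box: float) -> CoefficientFunctions:
    """Constant envelope coefficients for the attraction-free couple model.

    On the box |x_i| <= M the cubic reaction term obeys
    |beta_i x (1 - eps x^2)| <= |beta_i| (1 + eps M^2) |x|, giving the
    constant envelope a_i = alpha_i, b_i = |beta_i| (1 + eps M^2).  This is
    a local (box-restricted) linearization, not a global one.  The envelope
    forces f(t, 0, 0) = 0, so nonzero attraction constants are rejected.
    """
    if params.A1 != 0 or params.A2 != 0:
        raise ValueError(
            "the linear envelope requires A1 = A2 = 0 (it forces "
            "f(t, 0, 0) = 0, which nonzero attraction constants violate)"
        )
    if box <= 0:
        raise ValueError("box half-width must be positive")
    amp = 1.0 + params.eps * box**2
    return CoefficientFunctions.constant(
        a1=params.alpha1, a2=params.alpha2,
        b1=abs(params.beta1) * amp, b2=abs(params.beta2) * amp,
    )
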