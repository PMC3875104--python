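"""Generic machinery for Caputo fractional initial-value problems of order
``alpha`` in (0, 1].

The central object is :class:`FDESystem`, a vector Caputo problem

.. math::

    D^\\alpha y(t) = f(t, y(t)), \\qquad y(0) = y_0,

solved on a uniform grid by the Adams--Bashforth--Moulton predictor--corrector
(PECE) scheme of Diethelm, Ford and Freed.  The scheme carries the full
memory of the trajectory: the fractional derivative is non-local, so every
step sums over the whole history and the total cost is O(N^2) in the number
of grid points.  That is entirely acceptable at desk scale (a few thousand
steps) and is the variant used throughout this package.

:func:`mittag_leffler` provides the analytic solution kernel of linear
problems, ``y(t) = y0 * E_alpha(lambda * t**alpha)``, and serves as the
independent oracle for the solver in the test-suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate as _integrate
from scipy.special import gamma as _gamma

__all__ = [
    "FractionalOrder",
    "FDESystem",
    "SolverConfig",
    "Trajectory",
    "MittagLefflerError",
    "SolverBlowUpError",
    "mittag_leffler",
    "caputo_pece_solve",
    "estimate_convergence_order",
]


class MittagLefflerError(ArithmeticError):
    """Raised when no representation of E_alpha(z) converges to tolerance."""


class SolverBlowUpError(RuntimeError):
    """Raised when the PECE iteration produces a non-finite state.

    Attributes
    ----------
    step_index : int
        Index of the grid point at which the state first became non-finite.
    """

    def __init__(self, step_index: int):
        self.step_index = step_index
        super().__init__(
            f"non-finite state encountered at step index {step_index}; "
            "the right-hand side likely blew up for these parameters"
        )


@dataclass(frozen=True)
class FractionalOrder:
    """Order of a Caputo derivative, restricted to the solver's range (0, 1].

    Orders in (1, 2] are never integrated directly; they are reduced to a
    first-order-in-alpha system beforehand (see :mod:`couplefde.model`).
    """

    alpha: float

    def __post_init__(self) -> None:
        a = float(self.alpha)
        if not (0.0 < a <= 1.0) or not math.isfinite(a):
            raise ValueError(f"fractional order must lie in (0, 1], got {a}")
        object.__setattr__(self, "alpha", a)


@dataclass(frozen=True)
class FDESystem:
    """A Caputo initial-value problem D^alpha y = rhs(t, y), y(0) = y0."""

    order: FractionalOrder
    dimension: int
    rhs: Callable[[float, np.ndarray], np.ndarray]
    initial_state: np.ndarray

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be a positive integer")
        y0 = np.asarray(self.initial_state, dtype=float).reshape(-1)
        if y0.size != self.dimension:
            raise ValueError(
                f"initial_state has length {y0.size}, expected {self.dimension}"
            )
        if not np.all(np.isfinite(y0)):
            raise ValueError("initial_state must be finite")
        object.__setattr__(self, "initial_state", y0)

    def eval_rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        f = np.asarray(self.rhs(t, y), dtype=float).reshape(-1)
        if f.size != self.dimension:
            raise ValueError(
                f"rhs returned length {f.size}, expected {self.dimension}"
            )
        return f


@dataclass(frozen=True)
class SolverConfig:
    """Uniform-grid PECE settings: step h, horizon T, corrector sweeps."""

    step: float
    horizon: float
    corrector_iterations: int = 1

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step h must be positive")
        if self.horizon <= 0:
            raise ValueError("horizon T must be positive")
        if self.step > self.horizon:
            raise ValueError("step must not exceed the horizon")
        if self.corrector_iterations < 1:
            raise ValueError("corrector_iterations must be >= 1")

    @property
    def n_steps(self) -> int:
        n = int(round(self.horizon / self.step))
        return max(n, 1)


@dataclass(frozen=True)
class Trajectory:
    """Discrete solution on the uniform grid t_j = j*h, j = 0..N."""

    times: np.ndarray
    states: np.ndarray
    order: FractionalOrder

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.states, dtype=float)
        if y.ndim != 2 or y.shape[0] != t.size:
            raise ValueError("states must be (N+1) x dimension, aligned with times")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", y)

    @property
    def dimension(self) -> int:
        return self.states.shape[1]

    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def write_csv(self, path) -> None:
        """Write `t,y1,...,yn` rows at full double precision (17 sig. digits)."""
        header = "t," + ",".join(f"y{i + 1}" for i in range(self.dimension))
        data = np.column_stack([self.times, self.states])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.17g")


def _ml_series(alpha: float, z: float, tol: float, max_terms: int = 600) -> float:
    # Direct power series.  Reliable in double precision only while the
    # largest intermediate term stays moderate; for alternating sums the
    # achievable absolute accuracy is ~1e-16 * max|term| (cancellation).
    total = 0.0
    max_term = 0.0
    for k in range(max_terms):
        term = z**k / _gamma(alpha * k + 1.0)
        total += term
        max_term = max(max_term, abs(term))
        if max_term * 1e-15 > tol:
            raise MittagLefflerError(
                f"series for E_{alpha}({z}) cancels below tol={tol} "
                "in double precision"
            )
        if k > 0 and abs(term) <= tol * 0.1 and abs(z) ** (k + 1) / _gamma(
            alpha * (k + 1) + 1.0
        ) <= tol * 0.1:
            return total
    raise MittagLefflerError(
        f"power series for E_{alpha}({z}) did not converge in {max_terms} terms"
    )


def _ml_negative_integral(alpha: float, z: float) -> float:
    # Spectral representation on the negative real axis, 0 < alpha < 1:
    #   E_alpha(-x) = int_0^inf exp(-r * x**(1/alpha)) * K(r) dr,
    #   K(r) = (1/pi) * r**(alpha-1) sin(pi alpha)
    #          / (r**(2 alpha) + 2 r**alpha cos(pi alpha) + 1).
    # The kernel is a completely monotone density; quad handles the
    # integrable r**(alpha-1) endpoint singularity.
    x = -z
    s = x ** (1.0 / alpha)
    sin_a = math.sin(math.pi * alpha)
    cos_a = math.cos(math.pi * alpha)

    def kernel(r: float) -> float:
        ra = r**alpha
        return (
            math.exp(-r * s)
            * ra
            / r
            * sin_a
            / (ra * ra + 2.0 * ra * cos_a + 1.0)
            / math.pi
        )

    with warnings.catch_warnings():
        # near the roundoff floor QUADPACK warns while still returning the
        # best achievable value (abs error ~1e-12), which is what we want
        warnings.simplefilter("ignore", _integrate.IntegrationWarning)
        val, _err = _integrate.quad(kernel, 0.0, np.inf, limit=400,
                                    epsabs=1e-12, epsrel=1e-11)
    return val


def _ml_positive_asymptotic(alpha: float, z: float, tol: float) -> float:
    # Exponential + algebraic asymptotics for large z > 0, 0 < alpha < 2:
    #   E_alpha(z) ~ (1/alpha) exp(z**(1/alpha)) - sum_{k>=1} z**-k / Gamma(1 - alpha k)
    lead = math.exp(z ** (1.0 / alpha)) / alpha
    tail = 0.0
    prev = math.inf
    for k in range(1, 30):
        g = _gamma(1.0 - alpha * k)
        term = 0.0 if math.isinf(g) else z ** (-k) / g
        if abs(term) > prev:  # asymptotic series started diverging
            break
        tail += term
        prev = abs(term)
        if abs(term) <= tol * 0.1:
            break
    return lead - tail


def mittag_leffler(alpha: float, z: float, tol: float = 1e-12) -> float:
    """One-parameter Mittag-Leffler function E_alpha(z) for real z.

    E_alpha(z) = sum_{k>=0} z**k / Gamma(alpha*k + 1).  The power series is
    used for |z| <= 5; beyond that it suffers catastrophic cancellation in
    double precision, so the negative real axis switches to the spectral
    integral representation (0 < alpha < 1) and the positive axis to the
    exponential asymptotic expansion.

    Parameters
    ----------
    alpha : float
        Order parameter, 0 < alpha <= 2.
    z : float
        Real argument.
    tol : float
        Absolute truncation-error target.

    Raises
    ------
    MittagLefflerError
        If no available representation converges for this (alpha, z).
    """
    if not (0.0 < alpha <= 2.0):
        raise ValueError(f"alpha must lie in (0, 2], got {alpha}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if alpha == 1.0:
        return math.exp(z)
    if abs(z) <= 5.0:
        try:
            return _ml_series(alpha, z, tol)
        except MittagLefflerError:
            # the series cancels badly for small alpha well inside |z| <= 5;
            # the integral representation covers the negative axis
            if not (z < 0.0 and alpha < 1.0):
                raise
            return _ml_negative_integral(alpha, z)
    if z < 0.0 and alpha < 1.0:
        return _ml_negative_integral(alpha, z)
    if z > 0.0:
        return _ml_positive_asymptotic(alpha, z, tol)
    raise MittagLefflerError(
        f"no convergent representation for E_{alpha}({z}) with alpha > 1 on "
        "the far negative axis"
    )


def _abm_weights(alpha: float, n_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Precompute the ABM weight building blocks.

    Returns (b_diff, c) where
      b_diff[m] = (m+1)**alpha - m**alpha             (predictor, m = n - j)
      c[m]      = (m+2)**(a+1) + m**(a+1) - 2*(m+1)**(a+1)  (interior corrector)
    """
    m = np.arange(n_steps + 1, dtype=float)
    b_diff = (m + 1.0) ** alpha - m**alpha
    ap1 = alpha + 1.0
    c = (m + 2.0) ** ap1 + m**ap1 - 2.0 * (m + 1.0) ** ap1
    return b_diff, c


def caputo_pece_solve(system: FDESystem, config: SolverConfig) -> Trajectory:
    """Solve a Caputo IVP with the fractional Adams-Bashforth-Moulton scheme.

    Predictor (fractional Adams-Bashforth):

        y^P_{n+1} = y0 + (h^alpha / Gamma(alpha+1)) *
                    sum_{j=0}^{n} [(n+1-j)^alpha - (n-j)^alpha] f(t_j, y_j)

    Corrector (fractional Adams-Moulton, applied ``corrector_iterations``
    times, re-evaluating f at the newest iterate):

        y_{n+1} = y0 + (h^alpha / Gamma(alpha+2)) *
                  [ f(t_{n+1}, y^P_{n+1}) + sum_{j=0}^{n} a_{j,n+1} f(t_j, y_j) ]

    with a_{0,n+1} = n^{alpha+1} - (n - alpha)(n+1)^alpha and the interior
    weights a_{j,n+1} = (n-j+2)^{alpha+1} + (n-j)^{alpha+1} - 2(n-j+1)^{alpha+1}.
    At alpha = 1 the pair reduces to the classical second-order
    Adams-Bashforth-Moulton one-step scheme (trapezoidal corrector).

    Raises
    ------
    SolverBlowUpError
        If any computed state is non-finite; cubic right-hand sides can
        escape to infinity in finite time for unfortunate parameters.
    """
    alpha = system.order.alpha
    h = config.step
    n_steps = config.n_steps
    dim = system.dimension

    times = np.arange(n_steps + 1, dtype=float) * h
    states = np.empty((n_steps + 1, dim))
    fhist = np.empty((n_steps + 1, dim))

    y0 = system.initial_state
    states[0] = y0
    fhist[0] = system.eval_rhs(0.0, y0)
    if not np.all(np.isfinite(fhist[0])):
        raise SolverBlowUpError(0)

    b_diff, c = _abm_weights(alpha, n_steps)
    h_alpha = h**alpha
    pred_scale = h_alpha / _gamma(alpha + 1.0)  # = h^a / (a * Gamma(a))
    corr_scale = h_alpha / _gamma(alpha + 2.0)

    for n in range(n_steps):
        t_next = times[n + 1]
        # predictor: weights b_{j,n+1} ~ b_diff[n - j]
        w_pred = b_diff[n::-1]  # j = 0..n -> m = n-j
        y_pred = y0 + pred_scale * (w_pred @ fhist[: n + 1])

        # corrector history weights a_{j,n+1}
        w_corr = np.empty(n + 1)
        w_corr[0] = n ** (alpha + 1.0) - (n - alpha) * (n + 1.0) ** alpha
        if n >= 1:
            w_corr[1:] = c[n - 1 :: -1]  # j = 1..n -> m = n-j
        hist = w_corr @ fhist[: n + 1]

        y_new = y_pred
        for _ in range(config.corrector_iterations):
            f_new = system.eval_rhs(t_next, y_new)
            y_new = y0 + corr_scale * (f_new + hist)
        if not np.all(np.isfinite(y_new)):
            raise SolverBlowUpError(n + 1)
        states[n + 1] = y_new
        fhist[n + 1] = system.eval_rhs(t_next, y_new)

    return Trajectory(times=times, states=states, order=system.order)


def estimate_convergence_order(
    system: FDESystem,
    reference: Callable[[float], np.ndarray],
    steps: Sequence[float],
    horizon: float,
    corrector_iterations: int = 1,
) -> float:
    """Empirical convergence order of the PECE scheme on a known problem.

    Solves the system at each step size, measures the max-norm error against
    ``reference`` at the final time, and returns the least-squares slope of
    log(error) versus log(h).  Theoretical order for smooth solutions is
    min(2, 1 + alpha).
    """
    steps = list(steps)
    if len(steps) < 3:
        raise ValueError("need at least 3 step sizes")
    if reference is None:
        raise ValueError("a reference solution is required")
    errors = []
    for h in steps:
        n = horizon / h
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"step {h} does not divide the horizon {horizon}")
        cfg = SolverConfig(step=h, horizon=horizon,
                           corrector_iterations=corrector_iterations)
        traj = caputo_pece_solve(system, cfg)
        ref = np.asarray(reference(horizon), dtype=float).reshape(-1)
        errors.append(float(np.max(np.abs(traj.final_state() - ref))))
    log_h = np.log(np.asarray(steps))
    log_e = np.log(np.asarray(errors))
    slope = np.polyfit(log_h, log_e, 1)[0]
    return float(slope)
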