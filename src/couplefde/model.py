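"""The fractional-order couple model.

Two individuals' feelings x1(t), x2(t) evolve under a Caputo derivative of
order nu:

    D^nu x1 = -alpha1*x1 + beta1*x2*(1 - eps*x2**2) + A1
    D^nu x2 = -alpha2*x2 + beta2*x1*(1 - eps*x1**2) + A2

with x1(0) = x2(0) = 0 (no feelings before the relationship starts).  The
alpha_i > 0 are oblivion constants (one's own feeling decays), beta_i are
reaction constants (response to the partner, softened by the cubic
saturation eps), and A_i are attraction constants (intrinsic appeal).

For 1 < nu <= 2 the model expresses "acceleration in feelings".  Writing
alpha = nu/2 and introducing y2 = D^alpha x1, y4 = D^alpha x2 — legitimate
because D^alpha(D^alpha x) = D^(2*alpha) x under zero initial data — the
problem becomes a 4-D system of order alpha in (0.5, 1] that the PECE
solver handles directly; (y1, y3) of its solution IS the order-nu solution
(x1, x2).  For 0 < nu < 1 the 2-D system is solved as written (a-priori
bound analysis lives in :mod:`couplefde.bounds`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fde import FDESystem, FractionalOrder

__all__ = [
    "CoupleParameters",
    "ScenarioSet",
    "STYLE_SIGNS",
    "PAPER_SECTION5",
    "rhs_2d",
    "transform_to_first_order",
    "two_d_system",
    "sample_scenarios",
]

_PARAM_KEYS = ("alpha1", "alpha2", "beta1", "beta2", "eps", "A1", "A2", "nu")


@dataclass(frozen=True)
class CoupleParameters:
    """The seven model constants plus the derivative order nu.

    alpha1, alpha2 : oblivion (decay) constants, must be > 0
    beta1, beta2   : reaction constants (sign encodes romantic style)
    eps            : shared cubic saturation constant, >= 0
    A1, A2         : attraction constants
    nu             : derivative order; (1, 2] for the accelerated 4-D path,
                     (0, 1) for the 2-D bounds path
    """

    alpha1: float
    alpha2: float
    beta1: float
    beta2: float
    eps: float
    A1: float
    A2: float
    nu: float = 1.6

    def __post_init__(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("oblivion constants alpha1, alpha2 must be positive")
        if self.eps < 0:
            raise ValueError("saturation constant eps must be >= 0")
        if not (0.0 < self.nu <= 2.0):
            raise ValueError(f"order nu must lie in (0, 2], got {self.nu}")

    @property
    def alpha(self) -> float:
        """Transformed order nu/2 used by the 4-D system."""
        return self.nu / 2.0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "CoupleParameters":
        return cls(**{k: float(d[k]) for k in _PARAM_KEYS})

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "CoupleParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: The printed simulation parameter set (order 2*alpha = 1.6, alpha = 0.8).
PAPER_SECTION5 = CoupleParameters(
    alpha1=0.005, alpha2=0.006, beta1=0.0004, beta2=-0.0001,
    eps=0.001, A1=0.02, A2=0.03, nu=1.6,
)

#: Romantic-style sign constraints, as (parameter, required sign) pairs.
#: "secure_cautious": individual 1 retreats from their own feelings
#: (decay alpha1 > 0) but is encouraged by the partner (beta1 > 0).
#: "hermit": individual 2 retreats from their own feelings (alpha2 > 0)
#: and from the partner's (beta2 < 0).
STYLE_SIGNS: dict[str, dict[str, int]] = {
    "secure_cautious": {"alpha1": +1, "beta1": +1},
    "hermit": {"alpha2": +1, "beta2": -1},
}


def rhs_2d(params: CoupleParameters, x1: float, x2: float):
    """Right-hand side of the 2-D couple model at (x1, x2).

    Returns ( -alpha1*x1 + beta1*x2*(1 - eps*x2^2) + A1,
              -alpha2*x2 + beta2*x1*(1 - eps*x1^2) + A2 ).
    Accepts scalars or arrays (broadcasting elementwise).
    """
    p = params
    f1 = -p.alpha1 * x1 + p.beta1 * x2 * (1.0 - p.eps * x2**2) + p.A1
    f2 = -p.alpha2 * x2 + p.beta2 * x1 * (1.0 - p.eps * x1**2) + p.A2
    return f1, f2


def transform_to_first_order(params: CoupleParameters) -> FDESystem:
    """Reduce the order-nu model (1 < nu <= 2) to a 4-D order-(nu/2) system.

    With y1 = x1, y2 = D^alpha x1, y3 = x2, y4 = D^alpha x2 (alpha = nu/2):

        D^alpha y1 = y2
        D^alpha y2 = -alpha1*y1 + beta1*y3*(1 - eps*y3^2) + A1
        D^alpha y3 = y4
        D^alpha y4 = -alpha2*y3 + beta2*y1*(1 - eps*y1^2) + A2

    The composition identity D^alpha(D^alpha x) = D^(2*alpha) x that
    justifies the reduction holds only under zero initial conditions, which
    the model's premise (no initial feelings) guarantees; the zero initial
    state is therefore hard-wired here.
    """
    if not (1.0 < params.nu <= 2.0):
        raise ValueError(
            "order reduction requires 1 < nu <= 2; "
            f"got nu={params.nu} (use the 2-D system directly for nu < 1)"
        )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        f1, f2 = rhs_2d(params, y[0], y[2])
        return np.array([y[1], f1, y[3], f2])

    return FDESystem(
        order=FractionalOrder(params.alpha),
        dimension=4,
        rhs=rhs,
        initial_state=np.zeros(4),
    )


def two_d_system(params: CoupleParameters,
                 initial_state=(0.0, 0.0)) -> FDESystem:
    """The order-nu 2-D system for 0 < nu <= 1 (bounds-analysis path).

    Initial conditions default to zero as in the model statement but are
    user-settable here, unlike the order-reduced path.
    """
    if not (0.0 < params.nu <= 1.0):
        raise ValueError(f"2-D path requires 0 < nu <= 1, got {params.nu}")

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        return np.array(rhs_2d(params, x[0], x[1]))

    return FDESystem(
        order=FractionalOrder(params.nu),
        dimension=2,
        rhs=rhs,
        initial_state=np.asarray(initial_state, dtype=float),
    )


@dataclass(frozen=True)
class ScenarioSet:
    """A reproducible, seeded collection of romantic-style parameter draws."""

    seed: int
    styles: tuple
    draws: tuple

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "styles": list(self.styles),
            "draws": [d.to_dict() for d in self.draws],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ScenarioSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            styles=tuple(payload["styles"]),
            draws=tuple(CoupleParameters.from_dict(d) for d in payload["draws"]),
        )


# Default magnitude ranges: within one order of magnitude of the printed
# simulation values, keeping the cubic term perturbative.
_DEFAULT_RANGES = {
    "alpha1": (0.0015, 0.015), "alpha2": (0.0015, 0.015),
    "beta1": (0.0001, 0.001), "beta2": (0.00003, 0.0003),
    "eps": (0.0003, 0.003), "A1": (0.006, 0.06), "A2": (0.01, 0.1),
}


def sample_scenarios(styles, n: int, seed: int,
                     ranges: dict | None = None,
                     nu: float = 1.6) -> ScenarioSet:
    """Draw ``n`` parameter sets per requested style, reproducibly.

    Magnitudes are uniform over ``ranges`` (defaults near the printed
    simulation regime); each style then imposes its sign pattern from
    :data:`STYLE_SIGNS`.  The special style name ``"paper_section5"`` yields
    the exact printed parameter set instead of random draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    styles = list(styles)
    for s in styles:
        if s != "paper_section5" and s not in STYLE_SIGNS:
            raise ValueError(
                f"unknown style {s!r}; choose from "
                f"{sorted(STYLE_SIGNS) + ['paper_section5']}"
            )
    rng_ranges = dict(_DEFAULT_RANGES)
    if ranges:
        for k, (lo, hi) in ranges.items():
            if lo <= 0 or hi <= 0 or hi < lo:
                raise ValueError(f"range for {k} must be positive and ordered")
            rng_ranges[k] = (float(lo), float(hi))

    rng = np.random.default_rng(seed)
    draws: list[CoupleParameters] = []
    for style in styles:
        if style == "paper_section5":
            draws.extend([PAPER_SECTION5] * n)
            continue
        signs = STYLE_SIGNS[style]
        for _ in range(n):
            vals = {k: rng.uniform(*rng_ranges[k]) for k in rng_ranges}
            # oblivion constants stay positive; betas take the style's sign
            for k, sgn in signs.items():
                vals[k] = sgn * abs(vals[k])
            draws.append(CoupleParameters(nu=nu, **vals))
    return ScenarioSet(seed=seed, styles=tuple(styles), draws=tuple(draws))
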