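# Methods

## Numerical scheme

The solver is the fractional Adams–Bashforth–Moulton predictor–corrector
(PECE) for Caputo initial-value problems D^α y = f(t, y), y(0) = y₀, on a
uniform grid t_j = jh.  The predictor is the fractional Adams–Bashforth
rule with weights b_{j,n+1} = (h^α/α)((n+1−j)^α − (n−j)^α); the corrector
is the fractional Adams–Moulton (trapezoidal) rule with the standard
weights a_{0,n+1} = n^{α+1} − (n−α)(n+1)^α and
a_{j,n+1} = (n−j+2)^{α+1} + (n−j)^{α+1} − 2(n−j+1)^{α+1}.  The corrector
is applied once by default (classic PECE); the count is configurable since
more sweeps trade work for a slightly smaller corrector residual.  At
α = 1 the pair reduces exactly to the classical second-order
Adams–Bashforth–Moulton one-step scheme; the suite verifies an empirical
slope of 2 there and ≥ 1 (theory: min(2, 1+α)) at α = 0.8 against the
Mittag-Leffler reference.

The fractional derivative is non-local, so every step sums over the full
history: per-step work grows linearly in the step index and the total cost
is O(N²).  All headline computations run on a few thousand steps, where
this is a fraction of a second.  The grid is uniform only; no adaptivity.
Non-finite states abort the run with the offending step index rather than
being clipped — the cubic right-hand side can genuinely escape in finite
time for unfortunate parameters, and clipping would mask that.

Orders in (1, 2] are never integrated directly.  The composition identity
D^α(D^α x) = D^(2α) x holds under zero initial data, which the model's
premise (no initial feelings) guarantees, so the order-2α problem is
always reduced to the 4-D order-α system first and only y(0) is ever
needed as initial data.

## Mittag-Leffler evaluation

E_α(z) = Σ z^k/Γ(αk+1) is the solution kernel of linear Caputo problems
and the solver's independent oracle.  The power series is summed directly
for |z| ≤ 5 with a cancellation guard: an alternating sum is abandoned
once the largest intermediate term implies a double-precision floor above
the requested tolerance (for small α this happens well inside |z| ≤ 5).
On the negative axis with 0 < α < 1 the spectral representation
E_α(−x) = ∫₀^∞ e^{−r x^{1/α}} K_α(r) dr, with the completely monotone
density K_α(r) ∝ r^{α−1} sin(απ)/(r^{2α} + 2r^α cos(απ) + 1), is evaluated
by adaptive quadrature (absolute accuracy ≈ 1e−12).  Large positive
arguments use the exponential-plus-algebraic asymptotic expansion.
Combinations outside these regimes (α > 1 far down the negative axis)
raise an explicit error instead of returning a degraded value.

## Equilibria and stability

Steady states force y₂ = y₄ = 0.  Eliminating
y₁ = (β₁y₃(1−εy₃²) + A₁)/α₁ and substituting into the second algebraic
equation yields a univariate polynomial of degree ≤ 9 in y₃ whose
coefficients are assembled by exact polynomial arithmetic on the parameter
values (no floating expansion of nested products); roots come from the
companion matrix, are filtered by a scale-aware imaginary-part test and a
residual test on the original 2-D right-hand side, and de-duplicated.
This pipeline reproduces the positive equilibrium (4.38469, 4.92833) of
the built-in parameter set to five decimals.

The characteristic polynomial at an equilibrium is biquadratic; the
reduced quadratic k² + a₁k + a₂ (k = λ²) is solved in closed form and each
k root contributes both of its square roots (principal branch and its
negative) to the eigenvalue set.  Sign tests use a strictness tolerance of
1e−12: boundary cases (a₂ = 0, a₁ ≤ 0 with a₂ ≥ 0) are reported as
"indeterminate"/"marginal" rather than forced into a verdict, since the
sign criteria are silent there.  The eigenvalue-argument test is applied
to the λ roots (the system eigenvalues), with a zero eigenvalue treated as
violating the condition.  When both k roots are real and negative the two
classifiers provably agree (all eigenvalues purely imaginary); when the k
roots are complex they can disagree for α near 1, and the report carries
both verdicts plus an agreement flag instead of resolving the tension.

For reporting, the equilibrium with both feeling coordinates positive and
smallest norm is selected (the "positive equilibrium" of interest); if
none exists, the smallest-residual one.

## A-priori bounds

The bound machinery applies to 2-D order-α systems, α ∈ (0, 1), whose
right-hand sides are dominated by a linear envelope with continuous
nonnegative coefficient functions.  Ingredients:

* **Beta-integral identity** ∫₀ᵗ (t−s)^{p(β−1)} s^{p(γ−1)} ds =
  t^θ B[p(γ−1)+1, p(β−1)+1], θ = p(β+γ−2)+1, valid when both Beta
  arguments are positive; non-integrable exponents are rejected.
* **Hölder pair and kernel**: p = (1+4α)/(1+3α), q = (1+4α)/α satisfy
  1/p + 1/q = 1, qα − 1 = 4α and p(α−1)+1 = 4α²/(1+3α) > 0, making
  k*(t) = t^{4α} B^{q/p}[m,m]/Γ^q(α) finite, zero at t = 0 and
  nondecreasing.  Beta and Gamma powers are assembled in log space
  (exp(betaln·q/p − gammaln·q)) to avoid overflow at the large exponents.
* **Coupled Gronwall inequality**: explicit dominating curves for two
  functions satisfying linear integral inequalities with kernels
  nondecreasing in the outer time variable.  All integrals are composite
  Simpson on the evaluation grid; nested inner integrals run on a
  once-midpoint-refined grid.  Monotonicity and nonnegativity of the
  inputs are checked on the grid and violations rejected with the
  offending index.

The final bound curves t^{α−1}·exp{(1/q)k*(t)[∫αᵢ^q + ∫βᵢ^qΨ_j(k*∫β_j^qΨᵢ)]}
are evaluated by cumulative Simpson on an internal grid that prepends
t = 0 and refines once; the user grid must be strictly positive because
the prefactor t^{α−1} diverges at 0 for α < 1.

Two structural caveats are documented rather than patched.  First, the
envelope forces f(t, 0, 0) = 0, so the couple model with nonzero
attraction constants does not satisfy it; the provided helper derives
constant envelope coefficients (aᵢ = αᵢ, bᵢ = |βᵢ|(1 + εM²) on a box
|xᵢ| ≤ M — a local, not global, linearization) and requires A₁ = A₂ = 0.
Second, under the envelope with zero initial data the only solution is
identically zero — the bound's own Gronwall argument forces it — so the
bound cannot be exercised by a nonzero exact solution.  The empirical
check therefore perturbs the initial data slightly and confirms the
curves dominate the resulting small trajectory; this is a sanity check of
the evaluation pipeline, not a theorem instance.

## Flagship simulation and its time scales

The built-in parameter set has a₁ = 0.011, a₂ ≈ 3.0035e−5 > 0: stable by
both criteria.  The k roots are −0.005036 and −0.005964, so the four
eigenvalues are purely imaginary with frequencies 0.0710 and 0.0772
(periods ≈ 88.5 and 81.4).  Damping is purely fractional and algebraic,
and the two nearly-degenerate modes beat with period ≈ 1000: the max-norm
distance to the equilibrium is 1.79 at t = 60, bumps to 0.124 near t ≈ 300
(a beat-envelope maximum, confirmed h-converged at h = 0.1/0.05/0.025),
and falls to 0.0086 by t = 600.  The default solver grid is therefore
h = 0.05 with horizon 600 — the shortest round horizon at which the
trajectory has visibly saturated (within 0.01) at the equilibrium — and
"asymptotic approach" is operationalized as: distance at T below 0.05 and
below the distance at T/10.

## Scenario generation

Romantic-style draws sample parameter magnitudes uniformly within one
order of magnitude of the built-in simulation values (keeping the cubic
term perturbative) and then impose the style's sign pattern:
secure/cautious lover (α₁ > 0, β₁ > 0), hermit (α₂ > 0, β₂ < 0).  The
convention stores all oblivion constants as positive — "retreating from
one's own feelings" is the effective self-coefficient −αᵢ being negative —
which matches the signs actually used in the built-in set.  Draws are
reproducible from a seed via numpy's Generator; the generator emulates
parameter regimes, not measured relationship data, so passing sweeps say
nothing about fitting real couples.

## Problem sizes

Headline computations use: 6000-step 4-D solves (h = 0.05, T = 300–600)
for the flagship trajectory checks; 1000-step solves for the solver-vs-
Mittag-Leffler comparison; 41-point grids (refined internally) for
Gronwall and bound-curve evaluations; 100–1000 random draws for the
identity sweeps.

## Known limitations

* O(N²) memory-sum solver; no short-memory truncation or adaptivity.
* Incommensurate (multi-order) systems are out of scope; orders above 1
  are handled only through the order-halving transformation, which
  requires zero initial data.
* The stability analysis is local; basins of attraction, bifurcations and
  global behavior are not addressed.
* The bound curves grow rapidly (double exponential in the envelope
  integrals); on long horizons they overflow and the evaluation rejects
  the grid rather than returning infinities.
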