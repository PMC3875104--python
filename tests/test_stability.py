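"""Equilibria, characteristic coefficients, and the two stability verdicts."""

import cmath

import numpy as np
import pytest

from couplefde import (CoupleParameters, FractionalOrder, PAPER_SECTION5,
                       SolverConfig, arg_condition_classify, caputo_pece_solve,
                       characteristic_coefficients, find_equilibria,
                       full_stability_report, jacobian_at, reduced_roots,
                       routh_hurwitz_classify, transform_to_first_order)
from couplefde.stability import CharCoefficients, NoEquilibriumError


def _params(**overrides):
    base = dict(alpha1=0.005, alpha2=0.006, beta1=0.0004, beta2=-0.0001,
                eps=0.001, A1=0.02, A2=0.03, nu=1.6)
    base.update(overrides)
    return CoupleParameters(**base)


class TestEquilibria:
    def test_origin_when_no_attraction(self):
        eqs = find_equilibria(_params(A1=0.0, A2=0.0))
        assert any(abs(e.y1) < 1e-10 and abs(e.y3) < 1e-10 for e in eqs)

    def test_positive_equilibrium_to_five_decimals(self, paper_params):
        eqs = find_equilibria(paper_params)
        pos = [e for e in eqs if e.is_positive]
        assert len(pos) == 1
        e = pos[0]
        assert round(e.y1, 5) == 4.38469
        assert round(e.y3, 5) == 4.92833
        assert e.y[1] == 0.0 and e.y[3] == 0.0

    def test_linear_case_matches_closed_form(self):
        # eps = 0: the unique equilibrium solves a 2x2 linear system
        p = _params(eps=0.0, beta1=0.002, beta2=0.001)
        A = np.array([[-p.alpha1, p.beta1], [p.beta2, -p.alpha2]])
        expected = np.linalg.solve(A, [-p.A1, -p.A2])
        eqs = find_equilibria(p)
        assert len(eqs) == 1
        assert eqs[0].y1 == pytest.approx(expected[0], rel=1e-10)
        assert eqs[0].y3 == pytest.approx(expected[1], rel=1e-10)

    def test_residuals_below_tolerance(self, paper_params):
        for e in find_equilibria(paper_params, tol=1e-8):
            assert e.residual < 1e-8

    def test_zero_alpha1_rejected(self):
        p = _params()
        object.__setattr__(p, "alpha1", 0.0)  # bypass validation on purpose
        with pytest.raises(ValueError):
            find_equilibria(p)


class TestJacobian:
    def test_closed_form_a_b(self, paper_params):
        eqs = find_equilibria(paper_params)
        eq = next(e for e in eqs if e.is_positive)
        jac = jacobian_at(paper_params, eq)
        # independent arithmetic on the definitions
        assert jac.a == pytest.approx(0.0004 * (1 - 0.003 * eq.y3**2), rel=1e-12)
        assert jac.b == pytest.approx(-0.0001 * (1 - 0.003 * eq.y1**2), rel=1e-12)
        assert jac.a == pytest.approx(3.7085e-4, rel=1e-3)
        assert jac.b == pytest.approx(-9.4232e-5, rel=1e-3)

    def test_eps_zero_gives_betas(self):
        p = _params(eps=0.0)
        eq = find_equilibria(p)[0]
        jac = jacobian_at(p, eq)
        assert jac.a == p.beta1 and jac.b == p.beta2

    def test_fixed_matrix_pattern(self, paper_params):
        eq = find_equilibria(paper_params)[0]
        J = jacobian_at(paper_params, eq).J
        assert J[0, 1] == 1.0 and J[2, 3] == 1.0
        assert J[1, 0] == -paper_params.alpha1
        assert J[3, 2] == -paper_params.alpha2
        zero_mask = np.ones((4, 4), dtype=bool)
        for ij in [(0, 1), (1, 0), (1, 2), (2, 3), (3, 0), (3, 2)]:
            zero_mask[ij] = False
        assert np.all(J[zero_mask] == 0.0)


class TestCharacteristic:
    def test_values_for_builtin_set(self, paper_params):
        eq = next(e for e in find_equilibria(paper_params) if e.is_positive)
        jac = jacobian_at(paper_params, eq)
        coeffs = characteristic_coefficients(paper_params, jac)
        assert coeffs.a1 == pytest.approx(0.011, rel=1e-12)
        assert coeffs.a2 == pytest.approx(
            0.005 * 0.006 - jac.a * jac.b, rel=1e-12)
        assert coeffs.a2 == pytest.approx(3.0035e-5, rel=1e-3)

    def test_matches_numeric_characteristic_polynomial(self):
        # biquadratic closed form vs numpy eigvals on 100 random sets
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = _params(
                alpha1=rng.uniform(0.001, 0.5), alpha2=rng.uniform(0.001, 0.5),
                beta1=rng.uniform(-0.5, 0.5), beta2=rng.uniform(-0.5, 0.5),
                eps=rng.uniform(0, 0.01),
            )
            eqs = find_equilibria(p, tol=1e-6)
            if not eqs:
                continue
            jac = jacobian_at(p, eqs[0])
            coeffs = characteristic_coefficients(p, jac)
            # coefficients of det(J - lambda I) = l^4 + a1 l^2 + a2
            cp = np.poly(jac.J)  # [1, c3, c2, c1, c0]
            assert cp[1] == pytest.approx(0.0, abs=1e-10)
            assert cp[3] == pytest.approx(0.0, abs=1e-10)
            assert cp[2] == pytest.approx(coeffs.a1, rel=1e-10, abs=1e-12)
            assert cp[4] == pytest.approx(coeffs.a2, rel=1e-10, abs=1e-12)


class TestRoots:
    def test_perfect_square(self):
        k1, k2 = reduced_roots(CharCoefficients(a1=2.0, a2=1.0))
        assert k1 == pytest.approx(-1.0) and k2 == pytest.approx(-1.0)

    def test_builtin_coefficients_give_real_negative_roots(self):
        k1, k2 = reduced_roots(CharCoefficients(a1=0.011, a2=3.0035e-5))
        for k in (k1, k2):
            assert abs(k.imag) == 0.0
            assert k.real < 0

    def test_roots_satisfy_quadratic(self):
        coeffs = CharCoefficients(a1=0.37, a2=-1.2)
        for k in reduced_roots(coeffs):
            assert abs(k * k + coeffs.a1 * k + coeffs.a2) < 1e-12


class TestClassifiers:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [
            (0.011, 3.0035e-5, "stable"),
            (1.0, -1.0, "unstable"),
            (0.0, 1.0, "indeterminate"),
            (1.0, 0.0, "indeterminate"),
            (-1.0, 1.0, "indeterminate"),
        ],
    )
    def test_routh_hurwitz(self, a1, a2, expected):
        assert routh_hurwitz_classify(CharCoefficients(a1, a2)) == expected

    def test_arg_condition_pure_imaginary_stable(self):
        lambdas = [1j * 0.3, -1j * 0.3, 1j * 0.5, -1j * 0.5]
        assert arg_condition_classify(lambdas, FractionalOrder(0.8)) == "stable"

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_positive_real_root_always_unstable(self, alpha):
        lambdas = [0.2, -1.0, 1j, -1j]
        assert arg_condition_classify(lambdas, FractionalOrder(alpha)) == "unstable"

    def test_negative_real_root_stable(self):
        assert arg_condition_classify([-1.0], FractionalOrder(0.9)) == "stable"

    def test_zero_root_violates(self):
        assert arg_condition_classify([0.0, -1.0], FractionalOrder(0.5)) == "unstable"


class TestFullReport:
    def test_builtin_scenario_stable_and_consistent(self, paper_params):
        rep = full_stability_report(paper_params, FractionalOrder(0.8))
        assert rep.routh_verdict == "stable"
        assert rep.arg_verdict == "stable"
        assert rep.verdicts_agree
        # lambda roots squared reproduce the k roots
        for lam in rep.lambda_roots:
            assert min(abs(lam**2 - k) for k in rep.k_roots) < 1e-10
        for k in rep.k_roots:
            assert abs(k * k + rep.coeffs.a1 * k + rep.coeffs.a2) < 1e-12

    def test_unstable_case_agrees(self):
        p = CoupleParameters(alpha1=0.1, alpha2=0.1, beta1=1.0, beta2=1.0,
                             eps=0.0, A1=0.0, A2=0.0, nu=1.6)
        rep = full_stability_report(p)
        assert rep.coeffs.a2 == pytest.approx(0.01 - 1.0)
        assert rep.routh_verdict == "unstable"
        assert rep.arg_verdict == "unstable"
        assert rep.verdicts_agree

    def test_real_negative_k_roots_make_classifiers_agree(self):
        # property: both k roots real negative => both verdicts stable
        # for every order in (0, 1)
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            a1 = rng.uniform(0.05, 2.0)
            a2 = rng.uniform(1e-4, a1 * a1 / 4.0 * 0.99)
            coeffs = CharCoefficients(a1, a2)
            k1, k2 = reduced_roots(coeffs)
            assert k1.imag == 0 and k1.real < 0 and k2.real < 0
            lambdas = []
            for k in (k1, k2):
                s = cmath.sqrt(k)
                lambdas += [s, -s]
            for alpha in (0.05, 0.5, 0.95):
                assert routh_hurwitz_classify(coeffs) == "stable"
                assert arg_condition_classify(
                    lambdas, FractionalOrder(alpha)) == "stable"
            hits += 1
        assert hits == 50

    def test_dynamics_cross_check(self, paper_params):
        # simulated distance to the reported equilibrium shrinks over
        # a long horizon relative to one-tenth of that horizon
        system = transform_to_first_order(paper_params)
        traj = caputo_pece_solve(system, SolverConfig(step=0.1, horizon=600.0))
        rep = full_stability_report(paper_params)
        eq = np.asarray(rep.equilibrium.y)
        i10 = np.argmin(np.abs(traj.times - 60.0))
        d_end = np.max(np.abs(traj.final_state() - eq))
        d_10 = np.max(np.abs(traj.states[i10] - eq))
        assert d_end < d_10

    def test_report_json(self, paper_params, tmp_path):
        rep = full_stability_report(paper_params)
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert payload["routh_verdict"] == "stable"
        assert payload["k_roots"][0].keys() == {"re", "im"}
        assert payload["char_coefficients"]["a1"] == pytest.approx(0.011)
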