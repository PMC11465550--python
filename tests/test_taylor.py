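"""Taylor-series structural identifiability: derivatives, coefficients,
classification, against the hand-derivable two-state regulation model."""

import numpy as np
import pytest
import sympy as sp

import odeident as oi
from odeident.taylor import (
    ParamClass,
    analyze_taylor,
    coefficient_cap,
    output_derivatives,
    taylor_coefficients,
)


def syms(model, *names):
    table = {str(s): s for s in model.params + model.states}
    return [table[n] for n in names]


class TestOutputDerivatives:
    def test_first_derivative_of_mrna(self, m1_both):
        k1, k2, mRNA = syms(m1_both, "k1", "k2", "mRNA")
        d = output_derivatives(m1_both, 1)
        assert sp.simplify(d["mRNA"][1] - (k1 - k2 * mRNA)) == 0

    def test_order_zero_is_the_output_itself(self, m1_both, m2):
        for m in (m1_both, m2):
            d = output_derivatives(m, 0)
            for name, seq in d.items():
                assert sp.simplify(seq[0] - m.outputs[name].xreplace(
                    m.substituted_constants())) == 0

    def test_second_derivative_of_protein(self, m1_both):
        """d2(Protein)/dt2 = k3(k1 - k2 mRNA) - k4(k3 mRNA - k4 Protein)."""
        k1, k2, k3, k4, mRNA, Protein = syms(
            m1_both, "k1", "k2", "k3", "k4", "mRNA", "Protein"
        )
        expected = k3 * (k1 - k2 * mRNA) - k4 * (k3 * mRNA - k4 * Protein)
        d = output_derivatives(m1_both, 2)
        assert sp.expand(d["Protein"][2] - expected) == 0

    def test_higher_derivatives_of_both_outputs(self, m1_both):
        """Orders 0-3 of both outputs match the hand derivation."""
        k1, k2, k3, k4, mRNA, Protein = syms(
            m1_both, "k1", "k2", "k3", "k4", "mRNA", "Protein"
        )
        flow = k1 - k2 * mRNA
        pflow = k3 * mRNA - k4 * Protein
        expected = {
            "mRNA": [mRNA, flow, -k2 * flow, k2**2 * flow],
            "Protein": [
                Protein,
                pflow,
                k3 * flow - k4 * pflow,
                -k2 * k3 * flow - k4 * (k3 * flow - k4 * pflow),
            ],
        }
        d = output_derivatives(m1_both, 3)
        for name in expected:
            for k, e in enumerate(expected[name]):
                assert sp.expand(d[name][k] - e) == 0, (name, k)


class TestTaylorCoefficients:
    def test_coefficients_at_t0_match_hand_values(self, m1_both):
        """y^(k)(0) for both outputs, k = 0..3, ICs (2.5, 6.5)."""
        k1, k2, k3, k4 = syms(m1_both, "k1", "k2", "k3", "k4")
        ic_m, ic_p = sp.Rational(5, 2), sp.Rational(13, 2)
        flow0 = k1 - k2 * ic_m
        pflow0 = k3 * ic_m - k4 * ic_p
        expected = {
            "mRNA": [ic_m, flow0, -k2 * flow0, k2**2 * flow0],
            "Protein": [
                ic_p,
                pflow0,
                k3 * flow0 - k4 * pflow0,
                -k2 * k3 * flow0 - k4 * (k3 * flow0 - k4 * pflow0),
            ],
        }
        tc = taylor_coefficients(m1_both, n_coeffs=4)
        for name in expected:
            for k, e in enumerate(expected[name]):
                assert sp.expand(tc.coefficients[name][k] - e) == 0, (name, k)

    def test_solving_protein_rate_coefficient_for_k3(self, m1_both):
        """Protein'(0) = 2.5 k3 - 6.5 k4 solves to k3 = 2.6 k4 + 0.4 c."""
        k3, k4 = syms(m1_both, "k3", "k4")
        c = sp.Symbol("c", real=True)
        tc = taylor_coefficients(m1_both, n_coeffs=2)
        sol = sp.solve(sp.Eq(tc.coefficients["Protein"][1], c), k3)
        assert len(sol) == 1
        expr = sp.expand(sol[0])
        assert expr.coeff(k4) == sp.Rational(13, 5)
        assert expr.coeff(c) == sp.Rational(2, 5)

    def test_coefficients_match_finite_difference_derivatives(self, m1_both, p1):
        """Numeric oracle: coefficients equal FD derivatives of the
        simulated outputs at t0 for an arbitrary parameter point."""
        tc = taylor_coefficients(m1_both, n_coeffs=3)
        subs = {sp.Symbol(k, real=True): v for k, v in p1.items()}
        h = 1e-3
        stencil = np.arange(7) * h  # forward stencil, t >= t0
        traj = oi.simulate(m1_both, p1, stencil, rtol=1e-11, atol=1e-13)
        fd1 = {  # 4th-order forward first derivative
            name: (-25 * y[0] + 48 * y[1] - 36 * y[2] + 16 * y[3] - 3 * y[4]) / (12 * h)
            for name, y in ((n, traj.outputs[n]) for n in traj.outputs)
        }
        fd2 = {
            name: (2 * y[0] - 5 * y[1] + 4 * y[2] - y[3]) / h**2
            for name, y in ((n, traj.outputs[n]) for n in traj.outputs)
        }
        for name in tc.coefficients:
            c0, c1, c2 = (float(e.subs(subs)) for e in tc.coefficients[name][:3])
            assert c0 == pytest.approx(traj.outputs[name][0], rel=1e-9)
            assert c1 == pytest.approx(fd1[name], rel=1e-5, abs=1e-7)
            assert c2 == pytest.approx(fd2[name], rel=1e-3, abs=1e-4)


class TestCoefficientCap:
    def test_two_state_linear_caps_at_three(self, m1_both):
        cap, strict = coefficient_cap(m1_both)
        assert cap == 3 and strict

    def test_one_state_linear_caps_at_one(self):
        m = oi.parse_model(
            "states: [x]\nparameters: [k]\nodes: {x: -k*x}\n"
            "outputs: {x: x}\ninit: {x: 1.0}\n"
        )
        cap, strict = coefficient_cap(m)
        assert cap == 1 and strict

    def test_nonlinear_three_state_flagged_non_strict(self, m2):
        cap, strict = coefficient_cap(m2)
        assert cap == 5 and not strict


class TestClassification:
    def test_both_outputs_all_parameters_global(self, m1_both):
        v = analyze_taylor(m1_both)
        assert all(
            cls == ParamClass.GLOBAL.value for cls in v.per_parameter.values()
        )
        assert v.overall == ParamClass.GLOBAL.value and v.identifiable

    def test_protein_only_still_identifiable(self):
        v = analyze_taylor(oi.model1("protein_only"), n_coeffs=5)
        assert v.identifiable

    def test_mrna_only_k3_k4_unidentifiable(self, m1_mrna):
        v = analyze_taylor(m1_mrna)
        assert v.per_parameter["k1"] != ParamClass.UNIDENTIFIABLE.value
        assert v.per_parameter["k2"] != ParamClass.UNIDENTIFIABLE.value
        assert v.per_parameter["k3"] == ParamClass.UNIDENTIFIABLE.value
        assert v.per_parameter["k4"] == ParamClass.UNIDENTIFIABLE.value
        assert v.overall == ParamClass.UNIDENTIFIABLE.value

    @pytest.mark.parametrize(
        "name,expected,count",
        [
            ("y=2a", ParamClass.GLOBAL, 1),
            ("y=2a^2", ParamClass.LOCAL, 2),
            ("y=a+b", ParamClass.UNIDENTIFIABLE, 0),
        ],
    )
    def test_static_toys(self, name, expected, count):
        v = analyze_taylor(oi.toy(name))
        assert set(v.per_parameter.values()) == {expected.value}
        if count:
            assert set(v.solution_counts.values()) == {count}

    def test_verdict_invariant_to_state_order(self):
        """Re-declaring the states in the opposite order changes nothing."""
        flipped = oi.parse_model(
            """
name: model1_flipped
states: [Protein, mRNA]
parameters: [k1, k2, k3, k4]
odes:
  Protein: k3*mRNA - k4*Protein
  mRNA: k1 - k2*mRNA
outputs: {mRNA: mRNA, Protein: Protein}
init: {Protein: 6.5, mRNA: 2.5}
"""
        )
        v = analyze_taylor(flipped)
        assert v.overall == ParamClass.GLOBAL.value

    def test_verdict_invariant_to_output_scaling(self, m1_mrna):
        """Multiplying an output by a known nonzero constant changes nothing."""
        scaled = oi.parse_model(
            """
name: model1_scaled
states: [mRNA, Protein]
parameters: [k1, k2, k3, k4]
odes:
  mRNA: k1 - k2*mRNA
  Protein: k3*mRNA - k4*Protein
outputs: {y: 3*mRNA}
init: {mRNA: 2.5, Protein: 6.5}
"""
        )
        v_scaled = analyze_taylor(scaled)
        v_plain = analyze_taylor(m1_mrna)
        assert v_scaled.per_parameter["k1"] == v_plain.per_parameter["k1"]
        assert v_scaled.per_parameter["k3"] == v_plain.per_parameter["k3"]
        assert v_scaled.overall == v_plain.overall

    def test_timeout_reports_inconclusive_not_verdict(self, m2):
        v = analyze_taylor(m2, timeout=1e-9)
        assert v.status == "inconclusive"
        assert v.overall == "inconclusive"
        assert "rank" in v.message
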