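"""Forward-model correctness: temperature response, ETR, quadratic solutions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fvcbayes as fb
from fvcbayes.constants import ALPHA_LEAF

from .oracles import ac_bisection, ac_closed_form, aj_bisection, aj_closed_form

PRIOR_MEANS = dict(Vcmax=90.0, Rd=1.17, Gamma_star=3.86, Kc=27.24, Ko=30400.0,
                   O=21278.25)


class TestModelSpec:
    def test_code_round_trip(self):
        for code in fb.MODEL_CODES:
            assert fb.ModelSpec.from_code(code).code == code

    def test_unknown_code(self):
        with pytest.raises(ValueError, match="unknown model code"):
            fb.ModelSpec.from_code("CiCc_Jx")

    def test_structural_parameter_counts(self):
        counts = {
            code: len(fb.enumerate_structural_parameters(fb.ModelSpec.from_code(code)))
            for code in fb.MODEL_CODES
        }
        assert counts == {
            "CiCc_Jf": 6, "CiCc_Jm": 9, "CaCc_Jf": 5, "CaCc_Jm": 8,
            "CiCc_Jf_Temp": 12, "CiCc_Jm_Temp": 16, "CaCc_Jf_Temp": 10,
            "CaCc_Jm_Temp": 14,
        }

    def test_conditional_parameters(self):
        names = fb.enumerate_structural_parameters(fb.ModelSpec.from_code("CaCc_Jf"))
        assert names == ["Vcmax25", "Rd25", "Gamma_star25", "Kc25", "Ko25"]
        names = fb.enumerate_structural_parameters(
            fb.ModelSpec.from_code("CiCc_Jm_Temp")
        )
        assert "E_gm" in names and "E_Jmax" in names and "gm25" in names


class TestArrhenius:
    def test_identity_at_reference_kelvin(self):
        # 24.85 C is exactly 298 K under the model's Kelvin convention
        assert fb.arrhenius_adjust(90.0, 65.4, 24.85) == pytest.approx(90.0)

    def test_identity_at_zero_activation_energy(self):
        assert fb.arrhenius_adjust(3.86, 0.0, 35.0) == pytest.approx(3.86)

    def test_scalar_evaluation(self):
        # direct evaluation: factor exp(65400*(308.15-298)/(298*8.314*308.15))
        assert fb.arrhenius_adjust(90.0, 65.4, 35.0) == pytest.approx(214.7, abs=0.1)


class TestElectronTransport:
    def test_jf_examples(self):
        assert fb.compute_jf(0.0, 2000.0) == 0.0
        assert fb.compute_jf(0.5, 2000.0) == pytest.approx(425.0)
        assert fb.compute_jf(1.0, 1000.0) == pytest.approx(425.0)

    def test_jm_examples(self):
        assert fb.compute_jm(0.0, 171.0, 0.4, 0.8) == pytest.approx(0.0)
        assert fb.compute_jm(2000.0, 171.0, 0.4, 0.8) == pytest.approx(161.0, abs=0.1)

    def test_jm_saturates_at_jmax(self):
        j = fb.compute_jm(1e7, 171.0, 0.4, 0.8)
        assert j < 171.0
        assert j == pytest.approx(171.0, rel=1e-3)

    def test_jm_rectangular_hyperbola_limit(self):
        i2 = 2000.0 * 0.4 * ALPHA_LEAF
        expected = i2 * 171.0 / (i2 + 171.0)
        assert fb.compute_jm(2000.0, 171.0, 0.4, 1e-9) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        q=st.floats(0.0, 5000.0),
        jmax=st.floats(10.0, 400.0),
        phi=st.floats(0.05, 1.0),
        theta=st.floats(0.01, 1.0),
    )
    def test_jm_bounded_by_i2_and_jmax(self, q, jmax, phi, theta):
        j = float(fb.compute_jm(q, jmax, phi, theta))
        i2 = q * phi * ALPHA_LEAF
        assert -1e-9 <= j <= min(i2, jmax) + 1e-9


def _random_ac_inputs(rng, n):
    return dict(
        C=rng.uniform(5.0, 210.0, n),
        g=rng.uniform(0.5, 10.0, n),
        Vcmax=rng.uniform(20.0, 150.0, n),
        Rd=rng.uniform(0.1, 3.0, n),
        Gamma_star=rng.uniform(2.0, 6.0, n),
        Kc=rng.uniform(10.0, 50.0, n),
        Ko=rng.uniform(1e4, 5e4, n),
        O=np.full(n, 21278.25),
    )


class TestQuadraticSolutions:
    def test_ac_infinite_conductance_matches_closed_form(self):
        p = PRIOR_MEANS
        value = fb.ac_solution(40.0, 1e9, p["Vcmax"], p["Rd"], p["Gamma_star"],
                               p["Kc"], p["Ko"], p["O"])
        expected = ac_closed_form(40.0, p["Vcmax"], p["Rd"], p["Gamma_star"],
                                  p["Kc"], p["Ko"], p["O"])
        assert value == pytest.approx(expected, rel=1e-6)
        assert value == pytest.approx(36.5, abs=0.1)

    def test_ac_finite_conductance_below_infinite(self):
        p = PRIOR_MEANS
        finite = fb.ac_solution(40.0, 2.5, p["Vcmax"], p["Rd"], p["Gamma_star"],
                                p["Kc"], p["Ko"], p["O"])
        infinite = fb.ac_solution(40.0, 1e9, p["Vcmax"], p["Rd"], p["Gamma_star"],
                                  p["Kc"], p["Ko"], p["O"])
        assert finite < infinite
        oracle = ac_bisection(40.0, 2.5, p["Vcmax"], p["Rd"], p["Gamma_star"],
                              p["Kc"], p["Ko"], p["O"])
        assert finite == pytest.approx(oracle, rel=1e-9)

    def test_compensation_point(self):
        p = PRIOR_MEANS
        assert fb.ac_solution(p["Gamma_star"], 2.5, p["Vcmax"], 0.0,
                              p["Gamma_star"], p["Kc"], p["Ko"], p["O"]
                              ) == pytest.approx(0.0, abs=1e-9)
        assert fb.aj_solution(p["Gamma_star"], 2.5, 161.0, 0.0,
                              p["Gamma_star"]) == pytest.approx(0.0, abs=1e-9)

    def test_aj_examples(self):
        assert fb.aj_solution(40.0, 1e9, 0.0, 0.0, 3.86) == pytest.approx(0.0)
        value = fb.aj_solution(40.0, 1e9, 161.0, 1.17, 3.86)
        assert value == pytest.approx(aj_closed_form(40.0, 161.0, 1.17, 3.86),
                                      rel=1e-6)
        assert value == pytest.approx(29.3, abs=0.1)

    def test_oracle_equivalence_random_inputs(self, rng):
        p = _random_ac_inputs(rng, 200)
        ours = fb.ac_solution(**p)
        for i in range(200):
            oracle = ac_bisection(p["C"][i], p["g"][i], p["Vcmax"][i], p["Rd"][i],
                                  p["Gamma_star"][i], p["Kc"][i], p["Ko"][i],
                                  p["O"][i])
            assert ours[i] == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_infinite_conductance_monotone_convergence(self, rng):
        p = PRIOR_MEANS
        limit = ac_closed_form(40.0, p["Vcmax"], p["Rd"], p["Gamma_star"],
                               p["Kc"], p["Ko"], p["O"])
        values = [
            float(fb.ac_solution(40.0, g, p["Vcmax"], p["Rd"], p["Gamma_star"],
                                 p["Kc"], p["Ko"], p["O"]))
            for g in (1e2, 1e4, 1e6, 1e9)
        ]
        assert values == sorted(values)
        assert values[-1] == pytest.approx(limit, rel=1e-6)
        assert all(v <= limit + 1e-9 for v in values)

    def test_monotonicity(self, rng):
        p = PRIOR_MEANS
        base = fb.ac_solution(40.0, 2.5, p["Vcmax"], p["Rd"], p["Gamma_star"],
                              p["Kc"], p["Ko"], p["O"])
        assert fb.ac_solution(40.0, 2.5, p["Vcmax"] + 20, p["Rd"],
                              p["Gamma_star"], p["Kc"], p["Ko"], p["O"]) >= base
        assert fb.ac_solution(60.0, 2.5, p["Vcmax"], p["Rd"], p["Gamma_star"],
                              p["Kc"], p["Ko"], p["O"]) >= base
        assert fb.ac_solution(40.0, 2.5, p["Vcmax"], p["Rd"] + 1,
                              p["Gamma_star"], p["Kc"], p["Ko"], p["O"]) <= base
        aj = fb.aj_solution(40.0, 2.5, 161.0, p["Rd"], p["Gamma_star"])
        assert fb.aj_solution(40.0, 2.5, 200.0, p["Rd"], p["Gamma_star"]) >= aj
        assert fb.aj_solution(40.0, 2.5, 161.0, p["Rd"] + 1,
                              p["Gamma_star"]) <= aj


def test_cc_drawdown_diagnostic():
    # supply-function identity: A = g (C - Cc)
    assert fb.cc_drawdown(40.0, 25.0, 2.5) == pytest.approx(30.0)
    assert fb.cc_drawdown(40.0, 0.0, 2.5) == 40.0


class TestPredictAssimilation:
    def _params(self):
        return fb.StructuralParameters(
            Vcmax25=90.0, Rd25=1.17, Gamma_star25=3.86, Kc25=27.24, Ko25=30400.0,
            Jmax25=171.0, phiJ=0.4, thetaJ=0.8, gm25=2.5,
            E_Vcmax=65.4, E_Rd=63.9, E_Gamma_star=26.8, E_Kc=70.4, E_Ko=36.0,
            E_Jmax=46.1, E_gm=49.6,
        )

    def _curve(self, t_leaf=22.0):
        truth = fb.default_truth(fb.ModelSpec.from_code("CaCc_Jm"),
                                 genotypes=("g1",), n_individuals=1,
                                 process_sigma=0.0, T_mean=t_leaf, T_sd=0.0,
                                 seed=1)
        curves, _ = fb.generate_dataset(truth)
        return curves[0]

    def test_min_rule_and_limitation_labels(self):
        spec = fb.ModelSpec.from_code("CaCc_Jm")
        preds = fb.predict_assimilation(self._params(), self._curve(), spec)
        for p in preds:
            assert p.Aexp == pytest.approx(min(p.Ac, p.Aj))
            assert p.limiting == ("rubisco" if p.Ac <= p.Aj else "RuBP")

    def test_limitation_crossover_on_ladder(self):
        # RuBisCO limits at low CO2, RuBP regeneration at high CO2
        spec = fb.ModelSpec.from_code("CaCc_Jm")
        preds = fb.predict_assimilation(self._params(), self._curve(), spec)
        assert preds[0].limiting == "rubisco"
        assert preds[-1].limiting == "RuBP"

    def test_non_temp_spec_ignores_temperature(self):
        spec = fb.ModelSpec.from_code("CaCc_Jm")
        cold = fb.predict_assimilation(self._params(), self._curve(15.0), spec)
        # rebuild an identical curve but warm; drivers other than T match
        warm_curve = self._curve(30.0)
        cold_curve = self._curve(15.0)
        np.testing.assert_allclose(cold_curve.column("Ca"), warm_curve.column("Ca"))
        warm = fb.predict_assimilation(self._params(), warm_curve, spec)
        np.testing.assert_allclose([p.Aexp for p in cold],
                                   [p.Aexp for p in warm], rtol=1e-9)

    def test_temp_spec_responds_to_temperature(self):
        spec = fb.ModelSpec.from_code("CaCc_Jm_Temp")
        cold = fb.predict_assimilation(self._params(), self._curve(15.0), spec)
        warm = fb.predict_assimilation(self._params(), self._curve(30.0), spec)
        assert not np.allclose([p.Aexp for p in cold], [p.Aexp for p in warm])

    def test_missing_parameter_is_an_error(self):
        spec = fb.ModelSpec.from_code("CiCc_Jm")
        params = fb.StructuralParameters(
            Vcmax25=90.0, Rd25=1.17, Gamma_star25=3.86, Kc25=27.24, Ko25=30400.0,
            Jmax25=171.0, phiJ=0.4, thetaJ=0.8,  # gm25 missing
        )
        with pytest.raises(ValueError, match="gm25"):
            fb.predict_assimilation(params, self._curve(), spec)
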