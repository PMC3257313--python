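"""Rate-law families: printed forms, symmetries and limits."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cbckit import rate_laws as rl

conc = st.floats(min_value=1e-3, max_value=50.0, allow_nan=False)


def _params(**kw):
    return dict(kw)


class TestMassAction:
    def test_simple_product(self):
        law = rl.MassAction("k", [("A", 1.0)])
        assert law.evaluate({"A": 3.0, "B": 0.5}, {"k": 2.0}) == 6.0

    def test_reversible_vanishes_at_equilibrium(self):
        law = rl.MassAction("k", [("A", 1.0)], [("B", 1.0)], keq="Keq")
        assert law.evaluate({"A": 1.0, "B": 4.0}, {"k": 2.0, "Keq": 4.0}) == 0.0


class TestMichaelisMenten:
    def test_half_saturation(self):
        law = rl.MichaelisMenten("V", [("S", "Km")])
        assert law.evaluate({"S": 0.3}, {"V": 2.0, "Km": 0.3}) == pytest.approx(1.0)

    def test_one_inhibitor_at_ki_doubles_km(self):
        law = rl.MichaelisMenten("V", [("S", "Km")], [("I", "Ki")])
        v = law.evaluate({"S": 0.3, "I": 0.7}, {"V": 3.0, "Km": 0.3, "Ki": 0.7})
        assert v == pytest.approx(1.0)  # Vmax/3: effective Km doubled


class TestTransketolase:
    P = _params(Vm7=1.0, kE7=0.076, kM71=1.5, kM72=0.5, kM102=0.4, kM103=0.46,
                Vm10=1.0, kM101=2.0, kM104=0.5)

    def test_detailed_balance(self):
        state = {"S7P": 2.0, "GAP": 1.0, "Ri5P": 0.38, "Xu5P": 0.4,
                 "E4P": 0.1, "F6P": 1.0}
        # Ri5P*Xu5P = kE7 * S7P * GAP  ->  0.152 = 0.076*2
        assert rl.transketolase_rate(state, self.P) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("ke7,sign", [(0.076, -1), (10.0, +1)])
    def test_sign_follows_equilibrium_constant_at_unit_ratio(self, ke7, sign):
        p = dict(self.P, kE7=ke7)
        state = {"S7P": 1.0, "GAP": 1.0, "Ri5P": 1.0, "Xu5P": 1.0,
                 "E4P": 0.1, "F6P": 1.0}
        assert np.sign(rl.transketolase_rate(state, p)) == sign

    def test_modifier_combination_variants_differ_below_one_percent(self):
        """At the reference state (modifier terms ~0.1 each) the additive and
        multiplicative encodings agree to < 1% relative."""
        state = {"S7P": 1.5, "GAP": 0.5, "Ri5P": 0.12, "Xu5P": 0.25,
                 "E4P": 0.04, "F6P": 2.0}
        p = dict(self.P)
        p["kM103"] = 1.2  # Ri5P/kM103 = 0.1 at the reference state
        add = rl.transketolase_rate(state, p, "additive_modifiers")
        mult = rl.transketolase_rate(state, p, "multiplicative_modifiers")
        assert add != mult
        assert abs(add - mult) / abs(add) < 0.01

    def test_v10_uses_f6p_and_shares_ke7(self):
        state = {"F6P": 2.0, "GAP": 0.5, "E4P": 0.15, "Xu5P": 0.25,
                 "S7P": 1.5, "Ri5P": 0.12}
        v = rl.transketolase_rate(state, self.P, reaction="v10")
        assert v > 0
        # forward rate scales with the equilibrium constant (the defect class:
        # kE7 = 10 instead of 0.076 overdrives the forward term ~130-fold)
        v_wrong = rl.transketolase_rate(state, dict(self.P, kE7=10.0),
                                        reaction="v10")
        assert v_wrong / v == pytest.approx(
            (10 * 2 * 0.5 - 0.15 * 0.25) / (0.076 * 2 * 0.5 - 0.15 * 0.25))


TRANSLOCATOR_P = _params(Vm11=2.0, KmOP=1.0, KmPGA=0.5, KmT3P=0.8,
                         KmOPc=1.2, KmPGAc=0.6, KmT3Pc=0.7)


def _tstate(pga, op, gap, dhap, pgac, opc, gapc, dhapc):
    return {"PGA": pga, "OP": op, "GAP": gap, "DHAP": dhap,
            "PGAc": pgac, "OPc": opc, "GAPc": gapc, "DHAPc": dhapc}


class TestTranslocator:
    def test_symmetric_compositions_give_zero(self):
        p = dict(TRANSLOCATOR_P, KmOPc=1.0, KmPGAc=0.5, KmT3Pc=0.8)
        state = _tstate(1.0, 2.0, 0.3, 0.4, 1.0, 2.0, 0.3, 0.4)
        assert rl.translocator_rate(state, p) == pytest.approx(0.0, abs=1e-15)

    def test_linear_in_vm11(self):
        state = _tstate(2.0, 1.0, 0.3, 0.4, 0.1, 2.0, 0.2, 0.1)
        v1 = rl.translocator_rate(state, TRANSLOCATOR_P)
        v3 = rl.translocator_rate(state, dict(TRANSLOCATOR_P, Vm11=6.0))
        assert v3 == pytest.approx(3.0 * v1)

    def test_exports_against_cytosolic_phosphate_counter_substrate(self):
        # cytosolic PGA absent but phosphate available for counter-exchange
        state = _tstate(2.0, 1.0, 0.3, 0.4, 0.0, 2.0, 0.0, 0.0)
        assert rl.translocator_rate(state, TRANSLOCATOR_P) > 0

    def test_antiport_stalls_without_any_counter_substrate(self):
        # the printed form carries no idle-carrier term: a completely empty
        # cytosol gives zero exchange (T_c = 0 annihilates the export term)
        state = _tstate(2.0, 1.0, 0.3, 0.4, 0.0, 0.0, 0.0, 0.0)
        assert rl.translocator_rate(state, TRANSLOCATOR_P) == 0.0

    @given(st.lists(conc, min_size=8, max_size=8))
    def test_antisymmetric_under_compartment_swap(self, vals):
        p = dict(TRANSLOCATOR_P, KmOPc=1.0, KmPGAc=0.5, KmT3Pc=0.8)
        state = _tstate(*vals)
        swapped = _tstate(vals[4], vals[5], vals[6], vals[7],
                          vals[0], vals[1], vals[2], vals[3])
        v = rl.translocator_rate(state, p)
        assert rl.translocator_rate(swapped, p) == pytest.approx(-v, rel=1e-9,
                                                                 abs=1e-12)


OXY_P = _params(Vo=3.0, Ko=0.4, Kc=0.3, Kr=1.0, KI11=5.0, KI12=2.0, KI13=2.0,
                KI14=8.0, KI15=2.0)


def _oxstate(**kw):
    base = {"RuBP": 2.0, "O2": 0.25, "CO2": 0.2, "PGA": 0.0, "FBP": 0.0,
            "SBP": 0.0, "Pi": 0.0, "NADPH": 0.0}
    base.update(kw)
    return base


class TestOxygenase:
    def test_zero_oxygen_gives_zero(self):
        assert rl.oxygenase_rate(_oxstate(O2=0.0), OXY_P) == 0.0

    def test_saturation_limit_in_rubp(self):
        limit = 3.0 * 0.25 / (0.25 + 0.4 * (1 + 0.2 / 0.3))
        v = rl.oxygenase_rate(_oxstate(RuBP=1e9), OXY_P)
        assert v == pytest.approx(limit, rel=1e-6)

    def test_co2_competitively_suppresses(self):
        v = [rl.oxygenase_rate(_oxstate(CO2=c), OXY_P) for c in (0.1, 1.0, 1e6)]
        assert v[0] > v[1] > v[2]
        assert v[2] == pytest.approx(0.0, abs=1e-6)

    @given(conc, conc)
    def test_monotone_in_o2_and_inhibitors(self, o2, pga):
        lo = rl.oxygenase_rate(_oxstate(O2=o2), OXY_P)
        hi = rl.oxygenase_rate(_oxstate(O2=o2 * 2), OXY_P)
        assert hi >= lo
        inh = rl.oxygenase_rate(_oxstate(O2=o2, PGA=pga), OXY_P)
        assert inh <= lo


STP = _params(StPase_VM=2.0, StPase_km=1.0, StPase_kiG1P=0.5)


class TestStarchPhosphorylase:
    def test_corrected_form_is_silent_without_starch(self):
        state = {"starch": 0.0, "Pi": 5.0, "G1P": 0.1}
        assert rl.starch_phosphorylase_rate(state, STP, "corrected") == 0.0

    def test_original_form_degrades_nonexistent_starch(self):
        state = {"starch": 0.0, "Pi": 5.0, "G1P": 0.1}
        assert rl.starch_phosphorylase_rate(state, STP, "original") > 0.0

    def test_corrected_half_saturation(self):
        g1p = 0.25
        keff = 1.0 * (1 + g1p / 0.5)
        state = {"starch": keff, "Pi": 5.0, "G1P": g1p}
        assert rl.starch_phosphorylase_rate(state, STP, "corrected") == \
            pytest.approx(1.0)


@pytest.mark.parametrize("law,state,params", [
    (rl.MassAction("k", [("A", 1.0), ("B", 1.0)]), {"A": 2, "B": 3}, {"k": 0.5}),
    (rl.MichaelisMenten("V", [("S", "Km")]), {"S": 1.2}, {"V": 2.0, "Km": 0.4}),
    (rl.ReversibleMM("V", [("A", "Ka")], [("B", "Kb")], "Keq"),
     {"A": 1.0, "B": 0.2}, {"V": 2.0, "Ka": 0.5, "Kb": 0.7, "Keq": 3.0}),
    (rl.StarchPhosphorylase(), {"starch": 1.0, "Pi": 2.0, "G1P": 0.3},
     {"StPase_VM": 1.5, "StPase_km": 1.0, "StPase_kiG1P": 0.5}),
])
def test_positive_homogeneity_in_maximal_rate(law, state, params):
    """Doubling Vmax/k doubles the rate, all else fixed."""
    vmax_name = law.k if isinstance(law, rl.MassAction) else law.vmax
    v1 = law.evaluate(state, params)
    v2 = law.evaluate(state, {**params, vmax_name: 2 * params[vmax_name]})
    assert v2 == pytest.approx(2 * v1)


def test_rate_laws_lower_to_equivalent_expressions():
    """Family evaluation agrees with evaluating the family's own MathML-ready
    expression lowering (the SBML export path)."""
    cases = [
        (rl.MassAction("k", [("A", 1.0)], [("B", 1.0)], "Keq"),
         {"A": 2.0, "B": 0.5}, {"k": 1.3, "Keq": 2.0}),
        (rl.MichaelisMenten("V", [("S", "Km")], [("I", "Ki")]),
         {"S": 1.0, "I": 0.4}, {"V": 2.0, "Km": 0.5, "Ki": 0.8}),
        (rl.Transketolase("Vm7", "S7P", "GAP", "Ri5P", "Xu5P", "kM71", "kM72",
                          modifiers=[("E4P", "kM102"), ("Ri5P", "kM103")]),
         {"S7P": 1.5, "GAP": 0.5, "Ri5P": 0.12, "Xu5P": 0.25, "E4P": 0.15},
         TestTransketolase.P),
        (rl.Translocator(), _tstate(2.0, 1.0, 0.3, 0.4, 0.1, 2.0, 0.2, 0.1),
         TRANSLOCATOR_P),
        (rl.Oxygenase(), _oxstate(PGA=1.0, FBP=0.2), OXY_P),
        (rl.StarchPhosphorylase("original"),
         {"starch": 0.0, "Pi": 2.0, "G1P": 0.3}, STP),
    ]
    from cbckit.expr import evaluate
    for law, state, params in cases:
        env = {**state, **params}
        assert evaluate(law.to_expression(), env) == \
            pytest.approx(law.evaluate(state, params), rel=1e-12)
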