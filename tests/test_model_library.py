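"""Model variants, patches, sinks and lineage reconstruction."""

import numpy as np
import pytest

from cbckit import rate_laws as rl
from cbckit.model_library import (PatchDescriptor, SinkConfig,
                                  aggregate_minor_sinks, apply_patch,
                                  build_model, configure_sink,
                                  default_sink_config, rebuild_from_lineage)
from cbckit.serialize import model_to_dict, models_equal
from cbckit.simulate import find_steady_state


class TestBuildModel:
    def test_d2_reaction_count_and_pgca_product(self):
        m = build_model("cyano_D2")
        # 13 cycle + 3 starch-synthesis + 5 sinks + the PGCA drain of the
        # oxygenation-bearing carboxylation
        assert len(m.reactions) == 22
        assert m.get_reaction("CC_1").stoichiometry["PGCA"] == pytest.approx(0.084)
        assert {f"SR_{s}" for s in ("PGA", "F6P", "DHAP", "E4P", "Ri5P", "PGCA")} \
            <= {r.id for r in m.reactions}

    def test_c1_folds_minor_sinks_into_pga(self):
        c1, c2 = build_model("cyano_C1"), build_model("cyano_C2")
        ids1 = {r.id for r in c1.reactions}
        assert not ids1 & {"SR_DHAP", "SR_E4P", "SR_Ri5P"}
        vm1 = c1.parameters.get("Vm_SR_PGA")
        vm2 = c2.parameters.get("Vm_SR_PGA")
        assert vm1 > vm2  # folded contributions raise the PGA sink's capacity

    def test_explicit_minor_sinks_rejected_for_c1(self):
        cfg = default_sink_config("cyano_C2")
        with pytest.raises(ValueError, match="fold"):
            build_model("cyano_C1", sink_config=cfg)

    def test_variants_have_separate_triose_and_sugar_species(self):
        m = build_model("zhu_S")
        for sid in ("GAP", "DHAP", "F6P", "G6P", "Xu5P", "Ru5P", "Ri5P"):
            assert m.has_species(sid)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model("laisk_complete")

    def test_tk_encoding_distinguishes_zhu_variants(self):
        a, s = build_model("zhu_A"), build_model("zhu_S")
        mode = lambda m: {r.id: r.rate_law.modifier_mode for r in m.reactions
                          if isinstance(r.rate_law, rl.Transketolase)}
        assert set(mode(a).values()) == {"multiplicative_modifiers"}
        assert set(mode(s).values()) == {"additive_modifiers"}
        # uncorrected constants by default
        assert a.parameters.get("kE7") == 10.0
        assert a.parameters.get("kM103") == pytest.approx(0.46)

    def test_designed_state_is_steady_for_every_cyano_variant(self):
        for variant in ("cyano_C1", "cyano_C2", "cyano_D1", "cyano_D2"):
            ss = find_steady_state(build_model(variant))
            assert ss.converged, variant
            assert ss.fluxes["CC_13"] == pytest.approx(0.1, rel=1e-6)


class TestAggregateMinorSinks:
    FRACTIONS = {"Ri5P": 0.007, "DHAP": 0.0032, "E4P": 0.0031}

    def test_raw_fraction_sum_is_133_percent_of_reference(self):
        assert aggregate_minor_sinks(self.FRACTIONS, q_rule="unit") == \
            pytest.approx(0.0133)

    def test_printed_factor_rule(self):
        total = aggregate_minor_sinks(self.FRACTIONS)
        assert total == pytest.approx(5 / 3 * 0.007 + 0.0032 + 4 / 3 * 0.0031)

    def test_pgca_uses_printed_166(self):
        assert aggregate_minor_sinks({"PGCA": 0.042}) == pytest.approx(0.06972)

    def test_carbon_ratio_rule(self):
        assert aggregate_minor_sinks({"PGCA": 0.042}, q_rule="carbon_ratio") == \
            pytest.approx(0.042 * 2 / 3)

    def test_empty_and_invalid(self):
        assert aggregate_minor_sinks({}) == 0.0
        with pytest.raises(ValueError):
            aggregate_minor_sinks({"Ri5P": -0.1})


class TestPatches:
    def test_set_ke7_changes_only_that_parameter(self, cyano_c2):
        patched = apply_patch(cyano_c2, PatchDescriptor("set_kE7", {"value": 10.0}))
        assert patched.parameters.get("kE7") == 10.0
        d1, d2 = model_to_dict(cyano_c2), model_to_dict(patched)
        assert d1["species"] == d2["species"]
        assert d1["reactions"] == d2["reactions"]
        diff = {k for k in d1["parameters"]
                if d1["parameters"][k] != d2["parameters"][k]}
        assert diff == {"kE7"}
        assert patched.lineage[-1]["prior"] == {"kE7": 0.076}

    def test_starch_fix_is_idempotent(self):
        from cbckit.fixtures import calvin_mini_fixture
        m = calvin_mini_fixture(starch_variant="original")
        once = apply_patch(m, PatchDescriptor("starch_fix"))
        twice = apply_patch(once, PatchDescriptor("starch_fix"))
        assert once.get_reaction("st_deg").rate_law.variant == "corrected"
        assert models_equal(once, twice, ignore_lineage=True)

    def test_starch_fix_requires_target_reaction(self, cyano_c2):
        with pytest.raises(KeyError):
            apply_patch(cyano_c2, PatchDescriptor("starch_fix"))

    def test_modifier_mode_patch_flips_both_tk_laws(self, cyano_c2):
        patched = apply_patch(cyano_c2, PatchDescriptor(
            "tk_modifier_mode", {"mode": "multiplicative_modifiers"}))
        modes = [r.rate_law.modifier_mode for r in patched.reactions
                 if isinstance(r.rate_law, rl.Transketolase)]
        assert modes == ["multiplicative_modifiers"] * 2

    def test_lump_and_split_oxygenation_share_the_steady_state(self):
        """Replacing the lumped stoichiometry by an explicit oxygenase
        parameterised at the steady state leaves state and fluxes unchanged
        (the two encodings are equivalent at and near steady state)."""
        m = build_model("cyano_D2")
        split = apply_patch(m, PatchDescriptor("split_oxygenation"))
        assert any(r.id == "CC_1ox" for r in split.reactions)
        ss_l, ss_s = find_steady_state(m), find_steady_state(split)
        for sid, v in ss_l.state.items():
            if not sid.startswith("SINK"):
                assert ss_s.state[sid] == pytest.approx(v, rel=1e-6, abs=1e-9)
        # total RuBP consumption and PGCA production both agree
        assert ss_s.fluxes["CC_1"] + ss_s.fluxes["CC_1ox"] == \
            pytest.approx(ss_l.fluxes["CC_1"], rel=1e-9)
        assert ss_s.fluxes["CC_1ox"] == \
            pytest.approx(0.084 * ss_l.fluxes["CC_1"], rel=1e-6)

    def test_unknown_patch_rejected(self, cyano_c2):
        with pytest.raises(ValueError):
            apply_patch(cyano_c2, PatchDescriptor("recalibrate_everything"))


class TestConfigureSink:
    def test_exactly_one_pga_export_with_requested_family(self, cyano_c2):
        for kin, law_type in (("MA", rl.MassAction), ("MMcb", rl.MichaelisMenten),
                              ("MM", rl.MichaelisMenten)):
            m = configure_sink(cyano_c2, "PGA", kin)
            sinks = [r for r in m.reactions if r.id == "SR_PGA"]
            assert len(sinks) == 1
            assert isinstance(sinks[0].rate_law, law_type)

    def test_families_agree_at_the_operating_point(self, cyano_c2):
        state = cyano_c2.initial_state()
        rates = {}
        for kin in ("MA", "MM", "MMcb"):
            m = configure_sink(cyano_c2, "PGA", kin)
            r = m.get_reaction("SR_PGA")
            rates[kin] = r.rate_law.evaluate(state, m.parameters)
        vals = list(rates.values())
        assert vals[0] == pytest.approx(vals[1], rel=1e-9)
        assert vals[0] == pytest.approx(vals[2], rel=1e-9)

    def test_ma_equals_mm_limit_at_low_substrate(self, cyano_c2):
        mcb = configure_sink(cyano_c2, "PGA", "MMcb")
        law = mcb.get_reaction("SR_PGA").rate_law
        vm = mcb.parameters.get(law.vmax)
        km = mcb.parameters.get(dict(law.substrates)["PGA"])
        state = dict(cyano_c2.initial_state(), PGA=km * 1e-6)
        assert law.evaluate(state, mcb.parameters) == \
            pytest.approx(vm / km * state["PGA"], rel=1e-5)

    def test_mm_variant_is_inhibited_by_triose_phosphates(self, cyano_c2):
        m = configure_sink(cyano_c2, "PGA", "MM")
        law = m.get_reaction("SR_PGA").rate_law
        state = m.initial_state()
        v0 = law.evaluate(state, m.parameters)
        v1 = law.evaluate(dict(state, GAP=state["GAP"] * 5), m.parameters)
        assert v1 < v0


class TestLineage:
    def test_models_reconstruct_from_lineage_alone(self, cyano_c2):
        m = apply_patch(cyano_c2, PatchDescriptor("set_kE7", {"value": 10.0}))
        m = apply_patch(m, PatchDescriptor(
            "tk_modifier_mode", {"mode": "multiplicative_modifiers"}))
        rebuilt = rebuild_from_lineage(m)
        assert models_equal(m, rebuilt)

    def test_build_records_non_archival_provenance(self):
        m = build_model("zhu_A")
        assert m.lineage[0]["name"] == "build"
        assert "non-archival" in m.lineage[0]["note"]

    def test_serialization_round_trip_is_stable(self, cyano_c2):
        from cbckit.serialize import from_yaml, to_yaml
        text = to_yaml(cyano_c2)
        assert to_yaml(from_yaml(text)) == text


class TestDirectionOfEffect:
    def test_correcting_ke7_raises_f6p_and_s7p_monotonically(self, cyano_c2):
        """Lowering the transketolase equilibrium constant from the defective
        10 to the literature 0.076 raises steady F6P and S7P at every step."""
        values = [10.0, 1.0, 0.3, 0.076]
        f6p, s7p = [], []
        for v in values:
            ss = find_steady_state(apply_patch(
                cyano_c2, PatchDescriptor("set_kE7", {"value": v})))
            assert ss.converged
            f6p.append(ss.state["F6P"])
            s7p.append(ss.state["S7P"])
        assert all(a < b for a, b in zip(f6p, f6p[1:]))
        assert all(a < b for a, b in zip(s7p, s7p[1:]))
        # the corrected value recovers the design state
        assert f6p[-1] == pytest.approx(2.0, rel=1e-6)
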