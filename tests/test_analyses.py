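"""Diagnostic analyses: stability, energy scan, sink output, comparison
table and paired ratios."""

import math

import numpy as np
import pandas as pd
import pytest

from cbckit.analyses import (energy_charge_scan, paired_model_ratio,
                             sink_comparison_table, sink_output_analysis,
                             stability_test)
from cbckit.fixtures import (calvin_mini_fixture, pga_ec_fixture,
                             toy_cycle_fixture)
from cbckit.model_core import ModelSpec, ParameterSet, ReactionSpec, SpeciesSpec
from cbckit import rate_laws as rl
from cbckit.model_library import build_model, perturbed_initial_state
from cbckit.simulate import ClampSpec, integrate


class TestStabilityTest:
    def test_clamped_phosphate_prevents_suspension(self, toy_cycle):
        rep = stability_test(toy_cycle, knockout="RuBP", duration=4800.0)
        assert rep.results["flags"]["suspended"] is False

    def test_finite_phosphate_pool_suspends_with_atp_collapse(self):
        """With a small unclamped external phosphate pool, export sequesters
        phosphate, ATP synthesis stalls and the cycle suspends."""
        m = toy_cycle_fixture(clamp_external_phosphate=False,
                              phosphate_pool_scale=0.1)
        rep = stability_test(m, knockout="RuBP", duration=4800.0,
                             steady_state_clamps=ClampSpec(["Pi_ext"]))
        flags = rep.results["flags"]
        assert flags["suspended"] is True
        assert 0 < flags["atp_collapse_time"] < 4800.0

    def test_zero_knockout_equals_plain_simulation(self, toy_cycle):
        """Knocking out a species already at zero steady-state concentration
        is the same run as no knockout at all."""
        m = toy_cycle_fixture()
        m.species.append(SpeciesSpec("ghost", initial_concentration=0.0,
                                     carbons=0, phosphates=0))
        rep = stability_test(m, knockout="ghost", duration=50.0)
        traj = rep.results["trajectory"]
        from cbckit.simulate import find_steady_state
        ss = find_steady_state(m)
        plain = integrate(m, t_end=50.0, initial_state=ss.state)
        ref = plain.to_table()
        common = traj.columns.intersection(ref.columns)
        assert np.allclose(traj[common].iloc[-1], ref[common].iloc[-1],
                           rtol=1e-8, atol=1e-12)

    def test_requires_existing_species(self, toy_cycle):
        with pytest.raises(KeyError):
            stability_test(toy_cycle, knockout="unobtainium", duration=1.0)


class TestEnergyChargeScan:
    def test_pga_inversely_proportional_to_energy_charge(self):
        m = pga_ec_fixture(input_flux=0.1, k=0.2, adenylate_total=2.0)
        rep = energy_charge_scan(m, [0.25, 0.5, 1.0], ["PGA"])
        t = rep.results["scan"]
        # steady P* = J / (k * ec * total) -> P* * ec is constant
        prods = t["PGA"] * t["energy_charge"]
        assert np.allclose(prods, 0.1 / (0.2 * 2.0), rtol=1e-8)

    def test_zero_energy_charge_flags_divergence_and_scan_continues(self):
        m = pga_ec_fixture()
        rep = energy_charge_scan(m, [0.0, 0.5], ["PGA"], divergence_cap=100.0)
        t = rep.results["scan"]
        assert t.loc[0, "flag"].startswith("divergent: PGA")
        assert t.loc[1, "converged"]

    def test_row_count_is_grid_size(self, cyano_c2):
        rep = energy_charge_scan(cyano_c2, [0.7, 0.75], ["PGA", "F6P"])
        t = rep.results["scan"]
        assert t.shape[0] == 2
        assert {"PGA", "F6P"} <= set(t.columns)

    def test_out_of_range_pga_is_flagged(self):
        m = pga_ec_fixture()  # steady PGA ~ 0.25-1 mM, below 2.15
        rep = energy_charge_scan(m, [1.0], ["PGA"])
        assert "physiological" in rep.results["scan"].loc[0, "flag"]


class TestSinkOutputAnalysis:
    def test_closed_fixture_has_unit_fold_and_flat_starch(self):
        p = ParameterSet()
        p.set("kf", 1.0, "1/s")
        p.set("Keq", 2.0, "")
        # 2A <-> starch at chemical equilibrium (Keq = starch / A^2)
        m = ModelSpec("closed", [
            SpeciesSpec("A", initial_concentration=0.5, carbons=3, phosphates=0),
            SpeciesSpec("starch", initial_concentration=0.5, carbons=6,
                        phosphates=0),
        ], [ReactionSpec("iso", {"A": -2.0, "starch": 1.0},
                         rl.MassAction("kf", [("A", 2.0)], [("starch", 1.0)],
                                       keq="Keq"))], p)
        rep = sink_output_analysis(m, horizon=10.0)
        assert rep.results["sink_pool_fold"] == pytest.approx(1.0)
        assert rep.results["mass_production"] == pytest.approx(0.0, abs=1e-9)

    def test_original_starch_law_goes_negative_corrected_does_not(self):
        orig = sink_output_analysis(calvin_mini_fixture(starch_variant="original"),
                                    horizon=600.0)
        corr = sink_output_analysis(calvin_mini_fixture(starch_variant="corrected"),
                                    horizon=600.0)
        assert orig.results["starch_min"] < 0
        assert orig.results["starch_fold"] < 0
        assert corr.results["starch_min"] >= 0

    def test_sink_fold_grows_with_horizon(self, toy_cycle):
        short = sink_output_analysis(toy_cycle, horizon=5.0)
        long = sink_output_analysis(toy_cycle, horizon=50.0)
        assert long.results["sink_pool_fold"] > short.results["sink_pool_fold"] > 1.0


@pytest.fixture(scope="module")
def table():
    return sink_comparison_table(horizon=3600.0)


class TestSinkComparisonTable:
    def test_reference_cell_is_exactly_100(self, table):
        norm = table.results["normalized"]
        ref = table.normalization["reference"]
        assert list(norm.loc[ref]) == pytest.approx([100.0] * 4)

    def test_six_rows_four_columns(self, table):
        assert table.results["normalized"].shape == (6, 4)
        assert list(table.results["normalized"].columns) == \
            ["PGA sink", "Starch", "C-B pool", "Total mass"]

    def test_normalization_is_scale_invariant(self, table):
        raw = table.results["raw"]
        ref = table.normalization["reference"]
        scaled = raw * 7.3
        renorm = scaled / scaled.loc[ref] * 100.0
        assert np.allclose(renorm.to_numpy(),
                           table.results["normalized"].to_numpy())

    def test_sink_implementation_shifts_cycle_pool_more_than_export(self, table):
        """The export column varies far less across sink implementations than
        the cycle-content column — export is robust, the pool is not."""
        norm = table.results["normalized"]
        assert norm["PGA sink"].std() < norm["C-B pool"].std()


class TestPairedModelRatio:
    def test_self_ratio_is_identically_one(self, cyano_c2):
        rep = paired_model_ratio(cyano_c2, cyano_c2, ("PGA", "F6P"),
                                 horizon=100.0)
        t = rep.results["ratios"]
        assert np.allclose(t.to_numpy(), 1.0, rtol=1e-9)

    def test_c_pair_ratio_shows_transient_excursion(self):
        """C1/C2 differ only by folding ~1.3% of flux into the PGA sink, yet
        the ratio series departs from 1 transiently before settling."""
        c1, c2 = build_model("cyano_C1"), build_model("cyano_C2")
        rep = paired_model_ratio(c1, c2, ("sink_sum", "E4P"), horizon=10800.0)
        t = rep.results["ratios"]
        late = t.index > 1.0
        sink_ratio = t.loc[late, "sink_sum"]
        assert sink_ratio.max() > 1.005  # transient excursion
        assert abs(sink_ratio.iloc[-1] - 1.0) < abs(sink_ratio.max() - 1.0)
        e4p = t["E4P"]
        assert e4p.max() > 1.0 + 1e-4 or e4p.min() < 1.0 - 1e-4

    def test_zero_denominator_points_are_floored_and_flagged(self, cyano_c2):
        rep = paired_model_ratio(cyano_c2, cyano_c2, ("sink_sum",),
                                 horizon=10.0)
        # sinks start empty: the t = 0 ratio is flagged, not infinite
        assert rep.results["floored_points"]["sink_sum"] >= 1
        assert not np.isinf(rep.results["ratios"].to_numpy()).any()

    def test_deterministic_rerun_is_bit_identical(self):
        d1, d2 = build_model("cyano_D1"), build_model("cyano_D2")
        r1 = paired_model_ratio(d1, d2, ("total_mass",), horizon=600.0)
        r2 = paired_model_ratio(build_model("cyano_D1"), build_model("cyano_D2"),
                                ("total_mass",), horizon=600.0)
        a = r1.results["ratios"].to_numpy()
        b = r2.results["ratios"].to_numpy()
        assert np.array_equal(a[~np.isnan(a)], b[~np.isnan(b)])
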