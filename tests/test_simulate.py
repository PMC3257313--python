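"""Integration, steady-state detection, flux matching and conservation."""

import math

import numpy as np
import pytest
from scipy.optimize import root

from cbckit import rate_laws as rl
from cbckit.fixtures import (linear_chain_fixture, toy_cycle_fixture,
                             translocator_fixture)
from cbckit.model_core import (ModelSpec, ParameterSet, ReactionSpec,
                               SpeciesSpec, stoichiometry_matrix)
from cbckit.simulate import (ClampSpec, UnboundedAccumulation,
                             find_steady_state, integrate, match_flux,
                             time_to_steady_state)


def _decay_to(x_star: float, k: float = 0.7, x0: float = 5.0) -> ModelSpec:
    """dx/dt = -k (x - x*), built as source + first-order decay."""
    p = ParameterSet()
    p.set("J", k * x_star if x_star > 0 else 1e-300, "mM/s")
    p.set("k", k, "1/s")
    species = [SpeciesSpec("SRC", initial_concentration=1.0, clamped=True),
               SpeciesSpec("X", initial_concentration=x0),
               SpeciesSpec("OUT", accumulator=True)]
    reactions = [ReactionSpec("in", {"SRC": -1.0, "X": 1.0},
                              rl.MassAction("J", [("SRC", 1.0)])),
                 ReactionSpec("out", {"X": -1.0, "OUT": 1.0},
                              rl.MassAction("k", [("X", 1.0)]))]
    return ModelSpec("relax", species, reactions, p)


class TestIntegrate:
    def test_clamped_species_stay_constant(self, toy_cycle):
        traj = integrate(toy_cycle, t_end=50.0)
        for sid in ("CO2", "Pi_ext"):
            col = traj.concentrations[sid].to_numpy()
            assert np.all(col == col[0])

    def test_first_order_decay_matches_closed_form(self):
        m = _decay_to(0.0, k=0.7, x0=2.0)
        m.reactions = [m.reactions[1]]  # pure decay
        traj = integrate(m, t_end=5.0)
        expected = 2.0 * np.exp(-0.7 * traj.time)
        assert np.max(np.abs(traj.concentrations["X"].to_numpy() - expected)) < 1e-7

    def test_total_carbon_constant_on_closed_fixture(self):
        """With every species unclamped the fixture is carbon- and
        phosphate-closed; totals drift only at integrator tolerance."""
        m = toy_cycle_fixture()
        for s in m.species:
            s.clamped = False
        traj = integrate(m, t_end=20.0)
        for attr in ("carbons", "phosphates"):
            w = np.array([getattr(m.get_species(c), attr)
                          for c in traj.concentrations.columns], float)
            total = traj.concentrations.to_numpy() @ w
            assert np.max(np.abs(total - total[0])) < 1e-6 * total[0]

    def test_rhs_agrees_with_matrix_times_rates(self, toy_cycle):
        """Finite difference of a short step equals N v(X) to first order."""
        sm = stoichiometry_matrix(toy_cycle)
        state0 = toy_cycle.initial_state()
        rates = np.array([r.rate_law.evaluate(state0, toy_cycle.parameters)
                          for r in toy_cycle.reactions])
        nv = sm.matrix @ rates
        nv[sm.clamped] = 0.0
        dt = 1e-6
        traj = integrate(toy_cycle, t_end=dt, n_points=2)
        fd = (traj.concentrations.iloc[-1].to_numpy()
              - traj.concentrations.iloc[0].to_numpy()) / dt
        assert np.allclose(fd, nv, rtol=1e-4, atol=1e-10)

    def test_negative_excursions_reported_outside_diagnostic_mode(self):
        from cbckit.fixtures import calvin_mini_fixture
        m = calvin_mini_fixture(starch_variant="original")
        assert m.diagnostic_mode
        traj = integrate(m, t_end=600.0)
        assert traj.concentrations["starch"].min() < 0  # representable


class TestTimeToSteadyState:
    def test_already_steady_returns_first_grid_point(self, toy_cycle):
        traj = integrate(toy_cycle, t_end=10.0)
        assert time_to_steady_state(traj) == 0.0

    def test_linear_relaxation_matches_closed_form(self):
        k, x0, x_star, eps = 0.7, 5.0, 2.0, 1e-6
        m = _decay_to(x_star, k=k, x0=x0)
        traj = integrate(m, t_end=60.0)
        t = time_to_steady_state(traj, epsilon=eps)
        # |dx/dt|/x* < eps  ->  t* = ln(k |x0-x*| / (eps x*)) / k
        expected = math.log(k * abs(x0 - x_star) / (eps * x_star)) / k
        grid_step = np.max(np.diff(traj.time))
        assert abs(t - expected) <= grid_step

    def test_never_converging_trajectory_returns_nan(self):
        m = _decay_to(0.0, k=0.7, x0=2.0)
        m.reactions = [m.reactions[1]]
        traj = integrate(m, t_end=5.0)  # normalized derivative stays at k
        assert math.isnan(time_to_steady_state(traj))


class TestFindSteadyState:
    def test_linear_chain_analytic_solution(self):
        m = linear_chain_fixture(n=3, input_flux=2.0, seed=7)
        ss = find_steady_state(m)
        assert ss.converged
        for i in (1, 2, 3):
            k = m.parameters.get(f"k{i}")
            assert ss.state[f"X{i}"] == pytest.approx(2.0 / k, rel=1e-8)

    def test_toy_cycle_matches_brute_force_from_random_starts(self, toy_cycle,
                                                              toy_cycle_steady):
        """Brute-force nonlinear solve (conserved pools pinned) from 100
        seeded random starts agrees with the integrated steady state."""
        from _oracles import brute_force_steady_state, free_indices
        sm, free = free_indices(toy_cycle)
        base = np.array([toy_cycle.get_species(s).initial_concentration
                         for s in sm.species_ids])
        rng = np.random.default_rng(1234)
        target = np.array([toy_cycle_steady.state[sm.species_ids[i]] for i in free])
        hits = 0
        for _ in range(100):
            sol = brute_force_steady_state(
                toy_cycle, base[free] * rng.uniform(0.2, 5.0, len(free)),
                base, free, sm)
            if sol.success and np.all(sol.x > 0):
                assert np.max(np.abs(sol.x - target) / target) < 1e-6
                hits += 1
        assert hits >= 25  # starts that fail or go negative are discarded

    def test_all_clamped_model_is_trivially_steady(self, toy_cycle):
        ss = find_steady_state(toy_cycle,
                               ClampSpec([s.id for s in toy_cycle.species]))
        assert ss.converged and ss.time_to_steady_state == 0.0
        assert ss.state["PGA"] == toy_cycle.get_species("PGA").initial_concentration

    def test_missing_outflow_reports_unbounded_accumulation(self):
        m = linear_chain_fixture(n=2, input_flux=1.0, rate_constants=[1.0, 1e-12])
        with pytest.raises(UnboundedAccumulation, match="X2"):
            find_steady_state(m, divergence_cap=100.0)

    def test_sinkless_cycle_accumulates_product(self):
        m = toy_cycle_fixture(with_sink=False)
        with pytest.raises(UnboundedAccumulation):
            find_steady_state(m, divergence_cap=500.0)

    def test_fluxes_recomputable_from_state(self, toy_cycle, toy_cycle_steady):
        for r in toy_cycle.reactions:
            assert toy_cycle_steady.fluxes[r.id] == pytest.approx(
                r.rate_law.evaluate(toy_cycle_steady.state,
                                    toy_cycle.parameters))


class TestEnergyChargeClamp:
    def test_clamp_sets_and_holds_adenylates(self, toy_cycle):
        clamps = ClampSpec(energy_charge=0.8, adenylate_total=1.5)
        traj = integrate(toy_cycle, clamps, t_end=20.0)
        assert np.allclose(traj.concentrations["ATP"], 0.8 * 1.5)
        assert np.allclose(traj.concentrations["ADP"], 0.2 * 1.5)

    def test_requires_adenylate_species(self):
        m = linear_chain_fixture(n=1)
        with pytest.raises(KeyError):
            integrate(m, ClampSpec(energy_charge=0.5), t_end=1.0)


class TestMatchFlux:
    def test_identical_models_leave_knob_unchanged(self):
        m = linear_chain_fixture(n=2, input_flux=1.0, rate_constants=[1.0, 2.0])
        out = match_flux(m, m, "input", ["J"], 1e-9)
        assert out.parameters.get("J") == pytest.approx(1.0)

    def test_doubled_target_doubles_input_knob(self):
        a = linear_chain_fixture(n=2, input_flux=2.0, rate_constants=[1.0, 2.0])
        b = linear_chain_fixture(n=2, input_flux=1.0, rate_constants=[1.0, 2.0])
        out = match_flux(a, b, "input", ["J"], 1e-9)
        assert out.parameters.get("J") == pytest.approx(2.0, rel=1e-6)
        assert out.lineage[-1]["name"] == "match_flux"

    def test_cyano_pair_matches_at_stated_tolerance(self):
        from cbckit.model_library import build_model
        c1, c2 = build_model("cyano_C1"), build_model("cyano_C2")
        matched = match_flux(c1, c2, "CC_13", ["Vm_CC_1"], 5e-6)
        f1 = find_steady_state(c1).fluxes["CC_13"]
        f2 = find_steady_state(matched).fluxes["CC_13"]
        assert abs(f1 - f2) <= 5e-6


class TestTranslocatorSteadyState:
    @pytest.mark.parametrize("vm11", [0.3, 3.0, 30.0])
    def test_export_flux_is_set_by_supply_not_vm11(self, vm11):
        """Across two orders of magnitude of Vm11 the steady-state export
        equals the source flux — the translocator's maximal rate drops out."""
        m = translocator_fixture(with_relay_sink=True, vm11=vm11)
        ss = find_steady_state(m)
        assert ss.converged
        assert ss.fluxes["translocator"] == pytest.approx(0.05, rel=1e-6)

    def test_without_relay_sink_pga_accumulates(self):
        m = translocator_fixture(with_relay_sink=False)
        with pytest.raises(UnboundedAccumulation):
            find_steady_state(m, divergence_cap=200.0)
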