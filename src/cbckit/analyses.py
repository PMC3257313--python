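"""Diagnostic analyses: stability test, energy-charge scan, sink output,
sink-implementation comparison, and paired-model ratio series.

Conventions shared by the reports:

* "Total mass production" over a horizon is the carbon-weighted amount
  accumulated in the open product pools (export sinks plus starch).  Carbon
  weighting is the convention consistent with folding minor sinks by
  carbon-equivalent factors; a molar sum is selectable.
* The "Calvin-Benson pool" is the carbon-weighted sum of the cycle
  intermediates — every unclamped, non-accumulator species (cofactors carry
  zero cycle carbons by construction).
* Cycle suspension means the RuBP-synthesis flux has fallen below 1% of its
  steady value; ATP collapse means the energy charge ATP/(ATP+ADP) fell
  below 0.01.  Both thresholds are reported with every stability report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fixtures import physiological_parameter_table
from .model_core import ModelSpec
from .simulate import (ClampSpec, SteadyStateResult, Trajectory,
                       UnboundedAccumulation, find_steady_state, integrate)

__all__ = [
    "AnalysisReport", "stability_test", "energy_charge_scan",
    "sink_output_analysis", "sink_comparison_table", "paired_model_ratio",
    "SUSPENSION_THRESHOLD", "ATP_COLLAPSE_THRESHOLD",
]

SUSPENSION_THRESHOLD = 0.01    # fraction of the steady reference flux
ATP_COLLAPSE_THRESHOLD = 0.01  # energy charge


@dataclass
class AnalysisReport:
    kind: str
    inputs: Dict[str, object]
    results: Dict[str, object]
    normalization: Optional[Dict[str, object]] = None

    def table(self, name: str) -> pd.DataFrame:
        return self.results[name]


def _carbon_weights(model: ModelSpec) -> Dict[str, float]:
    return {s.id: float(s.carbons or 0) for s in model.species}


def _cycle_pool_species(model: ModelSpec) -> List[str]:
    return [s.id for s in model.species
            if not s.clamped and not s.accumulator and (s.carbons or 0) > 0]


def _accumulators(model: ModelSpec) -> List[str]:
    out = [s.id for s in model.species if s.accumulator]
    if model.has_species("starch") and "starch" not in out:
        out.append("starch")
    return out


def _mass_produced(model: ModelSpec, traj: Trajectory,
                   convention: str = "carbon") -> pd.Series:
    """Time series of mass accumulated in the open pools since t = 0."""
    w = _carbon_weights(model)
    total = None
    for sid in _accumulators(model):
        weight = w.get(sid, 0.0) if convention == "carbon" else 1.0
        series = (traj.concentrations[sid] - traj.concentrations[sid].iloc[0]) * weight
        total = series if total is None else total + series
    if total is None:
        total = pd.Series(np.zeros(traj.time.size), index=traj.time)
    return total


def _sink_sum(model: ModelSpec, traj: Trajectory,
              convention: str = "carbon") -> pd.Series:
    w = _carbon_weights(model)
    total = None
    for sid in _accumulators(model):
        if sid == "starch":
            continue  # the only accumulator that is not an export sink
        weight = w.get(sid, 0.0) if convention == "carbon" else 1.0
        series = (traj.concentrations[sid] - traj.concentrations[sid].iloc[0]) * weight
        total = series if total is None else total + series
    if total is None:
        total = pd.Series(np.zeros(traj.time.size), index=traj.time)
    return total


def stability_test(model: ModelSpec, knockout: str = "RuBP",
                   duration: float = 4800.0,
                   clamps: Optional[ClampSpec] = None,
                   steady_state_clamps: Optional[ClampSpec] = None) -> AnalysisReport:
    """Zero one species at an established steady state and watch the cycle.

    All other state variables start from the computed steady state;
    ``clamps`` applies to the perturbed run (so an external pool can be held
    fixed or left to deplete), ``steady_state_clamps`` (default: same) to
    the steady-state computation.
    """
    ss = find_steady_state(model, steady_state_clamps
                           if steady_state_clamps is not None else clamps)
    if not ss.converged:
        raise RuntimeError("no steady state available for the stability test")
    if not model.has_species(knockout):
        raise KeyError(f"knockout species {knockout!r} not in model")
    init = dict(ss.state)
    init[knockout] = 0.0
    traj = integrate(model, clamps, t_end=duration, initial_state=init)

    ref = model.reference_flux_id
    flags: Dict[str, object] = {"suspension_threshold": SUSPENSION_THRESHOLD,
                                "atp_collapse_threshold": ATP_COLLAPSE_THRESHOLD}
    if ref is not None:
        ref_ss = ss.fluxes[ref]
        ref_end = traj.fluxes[ref].iloc[-1]
        flags["reference_flux_id"] = ref
        flags["steady_reference_flux"] = ref_ss
        flags["final_reference_flux"] = ref_end
        flags["suspended"] = bool(abs(ref_end) < SUSPENSION_THRESHOLD * abs(ref_ss)) \
            if ref_ss != 0 else False

    atp_dynamic = (model.has_species("ATP") and model.has_species("ADP")
                   and not model.get_species("ATP").clamped
                   and (clamps is None or "ATP" not in clamps.fixed_species)
                   and (clamps is None or clamps.energy_charge is None))
    if atp_dynamic:
        ec = traj.concentrations["ATP"] / (
            traj.concentrations["ATP"] + traj.concentrations["ADP"])
        below = np.nonzero(ec.to_numpy() < ATP_COLLAPSE_THRESHOLD)[0]
        flags["atp_collapse_time"] = float(traj.time[below[0]]) if below.size else math.nan

    return AnalysisReport(
        kind="stability",
        inputs={"model": model.id, "lineage": list(model.lineage),
                "knockout": knockout, "duration": duration},
        results={"trajectory": traj.to_table(), "steady_state": ss.state,
                 "flags": flags})


def energy_charge_scan(model: ModelSpec, ec_values: Sequence[float],
                       observables: Sequence[str],
                       adenylate_total: Optional[float] = None,
                       divergence_cap: float = 1e6) -> AnalysisReport:
    """Steady-state observables as a function of the clamped energy charge
    ATP/(ADP+ATP).  Non-convergent grid points are flagged and the scan
    continues; PGA values outside the physiological range are flagged."""
    pga_lo, pga_hi = physiological_parameter_table()["PGA"]["range_mM"]
    rows = []
    for ec in ec_values:
        row: Dict[str, object] = {"energy_charge": ec}
        try:
            ss = find_steady_state(model, ClampSpec(
                energy_charge=ec, adenylate_total=adenylate_total),
                divergence_cap=divergence_cap)
            row["converged"] = ss.converged
            row["flag"] = "" if ss.converged else "not converged"
            for obs in observables:
                row[obs] = ss.state.get(obs, math.nan)
        except UnboundedAccumulation as exc:
            row["converged"] = False
            row["flag"] = f"divergent: {exc.species_id}"
            for obs in observables:
                row[obs] = math.nan
        if "PGA" in observables and row.get("converged") and \
                not (pga_lo <= row["PGA"] <= pga_hi):
            row["flag"] = (row["flag"] + "; " if row["flag"] else "") + \
                f"PGA outside physiological range ({pga_lo}-{pga_hi} mM)"
        rows.append(row)
    table = pd.DataFrame(rows)
    return AnalysisReport(
        kind="energy_scan",
        inputs={"model": model.id, "lineage": list(model.lineage),
                "ec_values": list(ec_values), "observables": list(observables)},
        results={"scan": table})


def sink_output_analysis(model: ModelSpec, horizon: float = 10.0,
                         pool: Optional[Sequence[str]] = None,
                         initial_state: Optional[Mapping[str, float]] = None,
                         convention: str = "carbon") -> AnalysisReport:
    """Output behavior with variable sinks and starch.

    Reports the fold by which the accumulated sink pools multiply the
    initial cycle pool at the horizon, the starch excursion (as a fold of
    the same pool — negative when the defective degradation law drives
    starch below zero), and the mass-production rate.
    """
    traj = integrate(model, t_end=horizon, initial_state=initial_state)
    w = _carbon_weights(model)
    pool_species = list(pool) if pool is not None else _cycle_pool_species(model)
    init = traj.concentrations.iloc[0]
    initial_pool = sum(init[s] * (w[s] if convention == "carbon" else 1.0)
                       for s in pool_species)
    if initial_pool <= 0:
        raise ValueError("initial cycle pool is empty; cannot normalize folds")

    sink_acc = _sink_sum(model, traj, convention)
    fold = 1.0 + float(sink_acc.iloc[-1]) / initial_pool

    starch_stats = {}
    if model.has_species("starch"):
        weight = w["starch"] if convention == "carbon" else 1.0
        st = traj.concentrations["starch"] * weight
        starch_stats = {
            "starch_min": float(st.min()), "starch_max": float(st.max()),
            "starch_fold": float(st.iloc[-1] - st.iloc[0]) / initial_pool,
        }
    mass = _mass_produced(model, traj, convention)
    results = {
        "trajectory": traj.to_table(),
        "sink_pool_fold": fold,
        "initial_cycle_pool": initial_pool,
        "mass_production": float(mass.iloc[-1]),
        "mass_production_rate": float(mass.iloc[-1]) / horizon,
        **starch_stats,
    }
    return AnalysisReport(
        kind="sink_output",
        inputs={"model": model.id, "lineage": list(model.lineage),
                "horizon": horizon, "convention": convention},
        results=results)


def sink_comparison_table(horizon: float = 10800.0,
                          variants: Sequence[str] = ("zhu_A", "zhu_S"),
                          kinetics: Sequence[str] = ("MA", "MM", "MMcb"),
                          reference: Tuple[str, str] = ("zhu_S", "MM"),
                          convention: str = "carbon",
                          models: Optional[Mapping[Tuple[str, str], ModelSpec]] = None
                          ) -> AnalysisReport:
    """Accumulation of key products under the six (model x PGA-sink
    kinetics) configurations, normalized to the reference cell = 100.

    Columns: PGA sink, starch, Calvin-Benson pool (at the horizon) and total
    mass production, all carbon-weighted by default.  Every configuration
    starts from the same out-of-steady-state initial concentrations.
    """
    from .model_library import configure_sink, build_model, perturbed_initial_state

    raw_rows = {}
    missing = []
    for variant in variants:
        for kin in kinetics:
            key = (variant, kin)
            if models is not None and key in models:
                m = models[key]
            else:
                m = configure_sink(build_model(variant), "PGA", kin)
            try:
                traj = integrate(m, t_end=horizon,
                                 initial_state=perturbed_initial_state(m))
            except (UnboundedAccumulation, RuntimeError) as exc:
                missing.append({"model": variant, "kinetics": kin, "reason": str(exc)})
                continue
            w = _carbon_weights(m)
            end = traj.concentrations.iloc[-1]
            pga_sink = (end["SINK_PGA"] - traj.concentrations["SINK_PGA"].iloc[0]) \
                * (w["SINK_PGA"] if convention == "carbon" else 1.0)
            starch = 0.0
            if m.has_species("starch"):
                starch = (end["starch"] - traj.concentrations["starch"].iloc[0]) \
                    * (w["starch"] if convention == "carbon" else 1.0)
            cb_pool = sum(end[s] * (w[s] if convention == "carbon" else 1.0)
                          for s in _cycle_pool_species(m))
            total = float(_mass_produced(m, traj, convention).iloc[-1])
            raw_rows[key] = {"PGA sink": float(pga_sink), "Starch": float(starch),
                             "C-B pool": float(cb_pool), "Total mass": float(total)}

    index = pd.MultiIndex.from_tuples(raw_rows.keys(), names=["model", "kinetics"])
    raw = pd.DataFrame(list(raw_rows.values()), index=index)
    if reference not in raw_rows:
        raise RuntimeError(f"reference configuration {reference} did not converge")
    normalized = raw / raw.loc[reference] * 100.0
    return AnalysisReport(
        kind="sink_table",
        inputs={"variants": list(variants), "kinetics": list(kinetics),
                "horizon": horizon, "convention": convention},
        results={"raw": raw, "normalized": normalized, "missing": missing},
        normalization={"reference": reference, "value": 100.0})


def paired_model_ratio(model_x: ModelSpec, model_y: ModelSpec,
                       observables: Sequence[str] = ("total_mass", "sink_sum"),
                       grid: Optional[np.ndarray] = None,
                       horizon: float = 10800.0,
                       initial_state: Optional[Mapping[str, float]] = None,
                       convention: str = "carbon",
                       floor: float = 1e-12) -> AnalysisReport:
    """Ratio series x/y for the requested observables on a shared time grid.

    Both models start from the same initial concentrations (species the two
    models share).  ``total_mass`` and ``sink_sum`` are the carbon-weighted
    accumulation observables; any other name is read as a species id.
    Ratios with |denominator| < floor are flagged and set to NaN.
    """
    if grid is None:
        grid = np.unique(np.concatenate([np.linspace(0.0, min(10.0, horizon), 51),
                                         np.geomspace(max(horizon * 1e-3, 1.0),
                                                      horizon, 200)]))
    if initial_state is None:
        from .model_library import perturbed_initial_state
        initial_state = perturbed_initial_state(model_x)
    shared = {sid: v for sid, v in initial_state.items() if model_y.has_species(sid)}

    traj_x = integrate(model_x, t_end=float(grid[-1]), t_eval=grid,
                       initial_state=initial_state)
    traj_y = integrate(model_y, t_end=float(grid[-1]), t_eval=grid,
                       initial_state=shared)

    def observable(model, traj, name) -> np.ndarray:
        if name == "total_mass":
            return _mass_produced(model, traj, convention).to_numpy()
        if name == "sink_sum":
            return _sink_sum(model, traj, convention).to_numpy()
        return traj.concentrations[name].to_numpy()

    data: Dict[str, np.ndarray] = {}
    flagged: Dict[str, int] = {}
    for name in observables:
        x = observable(model_x, traj_x, name)
        y = observable(model_y, traj_y, name)
        guarded = np.abs(y) < floor
        ratio = np.where(guarded, np.nan, x / np.where(guarded, 1.0, y))
        data[name] = ratio
        flagged[name] = int(guarded.sum())
    table = pd.DataFrame(data, index=grid)
    table.index.name = "time_s"
    return AnalysisReport(
        kind="ratio_series",
        inputs={"model_x": model_x.id, "model_y": model_y.id,
                "observables": list(observables), "horizon": float(grid[-1])},
        results={"ratios": table, "floored_points": flagged})
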