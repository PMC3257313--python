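"""ODE assembly, integration, steady-state detection and flux matching.

The system integrated is dX/dt = N v(X) with clamped rows zeroed.  Units are
mM for concentrations and s for time.  Steady state is detected on the
normalized derivative

    max_i |dX_i/dt| / max(|X_i|, floor)  <  epsilon      (default 1e-6 1/s)

taken over *balanced* species only, i.e. unclamped species that are not open
product pools (starch and sink accumulators grow at a constant rate in the
steady regime and would otherwise never satisfy any derivative criterion).
The criterion, epsilon and floor are recorded with every result; because the
choice of epsilon is a convention, time-to-steady-state is also reported for
a band of epsilon values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .model_core import ModelSpec, stoichiometry_matrix
from .rate_laws import evaluate_rate

__all__ = [
    "ClampSpec", "Trajectory", "SteadyStateResult", "UnboundedAccumulation",
    "integrate", "time_to_steady_state", "find_steady_state", "match_flux",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12
DEFAULT_EPSILON = 1e-6   # 1/s, steady-state criterion
DEFAULT_FLOOR = 1e-9     # mM
DIVERGENCE_CAP = 1e6     # mM
TIME_CAP = 1e5           # s


class UnboundedAccumulation(RuntimeError):
    """A species exceeded the divergence cap — the expected outcome when a
    necessary sink (typically the PGA sink) is missing."""

    def __init__(self, species_id: str, time: float, state: Dict[str, float]):
        super().__init__(f"unbounded accumulation of {species_id!r} at t = {time:.3g} s")
        self.species_id = species_id
        self.time = time
        self.state = state


@dataclass
class ClampSpec:
    """Concentration clamps applied on top of the model's own clamped flags.

    ``energy_charge`` holds ATP = ec * adenylate_total and
    ADP = (1 - ec) * adenylate_total constant, removing the adenylates from
    the ODE state (the ATP/(ADP+ATP) scan axis).
    """

    fixed_species: frozenset = frozenset()
    energy_charge: Optional[float] = None
    adenylate_total: Optional[float] = None  # mM; falls back to the model parameter

    def __init__(self, fixed_species: Sequence[str] = (),
                 energy_charge: Optional[float] = None,
                 adenylate_total: Optional[float] = None):
        object.__setattr__(self, "fixed_species", frozenset(fixed_species))
        object.__setattr__(self, "energy_charge", energy_charge)
        object.__setattr__(self, "adenylate_total", adenylate_total)


@dataclass
class Trajectory:
    time: np.ndarray
    concentrations: pd.DataFrame  # index: time, columns: species
    fluxes: pd.DataFrame          # index: time, columns: reactions
    model: ModelSpec
    clamps: ClampSpec
    balanced_species: Tuple[str, ...]
    negative_events: List[Tuple[float, str]] = field(default_factory=list)
    clip_count: int = 0

    def final_state(self) -> Dict[str, float]:
        return dict(self.concentrations.iloc[-1])

    def to_table(self) -> pd.DataFrame:
        conc = self.concentrations.add_prefix("conc:")
        flux = self.fluxes.add_prefix("flux:")
        return pd.concat([conc, flux], axis=1)


@dataclass
class SteadyStateResult:
    state: Dict[str, float]
    fluxes: Dict[str, float]
    converged: bool
    time_to_steady_state: float  # s (nan if not converged)
    criterion: Dict[str, object]
    residual: float  # max |dX/dt| over balanced species at the reported state
    diagnosis: str = ""


def _resolve_clamps(model: ModelSpec, clamps: Optional[ClampSpec]) -> Tuple[set, Dict[str, float]]:
    """Return (clamped species ids, overridden concentrations)."""
    clamped = {s.id for s in model.species if s.clamped}
    overrides: Dict[str, float] = {}
    if clamps is None:
        return clamped, overrides
    for sid in clamps.fixed_species:
        if not model.has_species(sid):
            raise KeyError(f"clamp names unknown species {sid!r}")
        clamped.add(sid)
    if clamps.energy_charge is not None:
        ec = clamps.energy_charge
        if not (0.0 <= ec <= 1.0):
            raise ValueError(f"energy charge must lie in [0, 1], got {ec}")
        if not (model.has_species("ATP") and model.has_species("ADP")):
            raise KeyError("energy-charge clamping requires ATP and ADP species")
        total = clamps.adenylate_total
        if total is None:
            total = model.parameters.get("adenylate_total") \
                if "adenylate_total" in model.parameters else \
                model.get_species("ATP").initial_concentration + \
                model.get_species("ADP").initial_concentration
        overrides["ATP"] = ec * total
        overrides["ADP"] = (1.0 - ec) * total
        clamped |= {"ATP", "ADP"}
    return clamped, overrides


def balanced_species_ids(model: ModelSpec, clamps: Optional[ClampSpec] = None) -> Tuple[str, ...]:
    clamped, _ = _resolve_clamps(model, clamps)
    return tuple(s.id for s in model.species
                 if s.id not in clamped and not s.accumulator)


class _System:
    """Compiled right-hand side N v(X) for one model + clamp combination."""

    def __init__(self, model: ModelSpec, clamps: Optional[ClampSpec],
                 diagnostic_mode: Optional[bool] = None):
        self.model = model
        self.clamps = clamps
        sm = stoichiometry_matrix(model)
        self.sm = sm
        self.species_ids = list(sm.species_ids)
        self.reaction_ids = list(sm.reaction_ids)
        self.index = {sid: i for i, sid in enumerate(self.species_ids)}
        clamped, overrides = _resolve_clamps(model, clamps)
        self.clamped_mask = np.array([sid in clamped for sid in self.species_ids])
        self.overrides = overrides
        self.n = sm.matrix.copy()
        self.n[self.clamped_mask, :] = 0.0
        self.diagnostic = (model.diagnostic_mode if diagnostic_mode is None
                           else diagnostic_mode)
        self.params = model.parameters
        self.clip_count = 0

    def initial_vector(self) -> np.ndarray:
        x0 = np.array([s.initial_concentration for s in self.model.species], float)
        for sid, v in self.overrides.items():
            x0[self.index[sid]] = v
        return x0

    def state_dict(self, y: np.ndarray) -> Dict[str, float]:
        state = {sid: y[i] for i, sid in enumerate(self.species_ids)}
        state.update(self.overrides)
        return state

    def rates(self, y: np.ndarray) -> np.ndarray:
        state = self.state_dict(y)
        if not self.diagnostic:
            clipped = {k: (v if v > 0.0 else 0.0) for k, v in state.items()}
            if any(v < 0.0 for v in state.values()):
                self.clip_count += 1
            state = clipped
        return np.array([r.rate_law.evaluate(state, self.params)
                         for r in self.model.reactions])

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.n @ self.rates(y)


def _time_grid(t_end: float, points_per_decade: int = 1000,
               n_points: Optional[int] = None) -> np.ndarray:
    """Dense output grid: linear below 1 s, log-spaced above (default 1000
    points per decade of simulated time, capped for memory)."""
    if n_points is not None:
        return np.linspace(0.0, t_end, n_points)
    if t_end <= 1.0:
        return np.linspace(0.0, t_end, 1001)
    decades = math.log10(t_end)
    n_log = min(int(points_per_decade * decades), 4000)
    head = np.linspace(0.0, 1.0, 201)
    tail = np.minimum(np.logspace(0.0, decades, n_log), t_end)
    return np.unique(np.concatenate([head, tail]))


def integrate(model: ModelSpec, clamps: Optional[ClampSpec] = None,
              t_end: float = 100.0, rtol: float = DEFAULT_RTOL,
              atol: float = DEFAULT_ATOL, n_points: Optional[int] = None,
              t_eval: Optional[np.ndarray] = None,
              initial_state: Optional[Mapping[str, float]] = None,
              divergence_cap: float = DIVERGENCE_CAP,
              method: str = "LSODA") -> Trajectory:
    """Integrate dX/dt = N v(X); stiff-capable (LSODA).

    Clamped species stay exactly constant.  Outside diagnostic mode,
    negative excursions are recorded as events (and rates are evaluated on
    concentrations floored at zero).  A species crossing ``divergence_cap``
    raises :class:`UnboundedAccumulation`.
    """
    sys_ = _System(model, clamps)
    x0 = sys_.initial_vector()
    if initial_state:
        for sid, v in initial_state.items():
            x0[sys_.index[sid]] = v
        for sid, v in sys_.overrides.items():
            x0[sys_.index[sid]] = v
    grid = t_eval if t_eval is not None else _time_grid(t_end, n_points=n_points)
    grid = np.asarray(grid, float)

    unclamped = ~sys_.clamped_mask

    def diverged(t, y):
        return divergence_cap - np.max(np.abs(y[unclamped])) if unclamped.any() \
            else 1.0
    diverged.terminal = True
    diverged.direction = -1

    sol = solve_ivp(sys_.rhs, (0.0, t_end), x0, method=method, t_eval=grid,
                    rtol=rtol, atol=atol, events=[diverged])
    if sol.t_events[0].size > 0:
        t_div = float(sol.t_events[0][0])
        y_div = sol.y_events[0][0]
        worst = sys_.species_ids[int(np.argmax(np.abs(y_div * unclamped)))]
        raise UnboundedAccumulation(worst, t_div, sys_.state_dict(y_div))
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message} "
                           f"(last valid t = {sol.t[-1] if sol.t.size else 0.0:.4g} s)")

    conc = pd.DataFrame(sol.y.T, index=sol.t, columns=sys_.species_ids)
    fluxes = pd.DataFrame(
        np.array([sys_.rates(y) for y in sol.y.T]),
        index=sol.t, columns=sys_.reaction_ids)

    negative_events: List[Tuple[float, str]] = []
    if not sys_.diagnostic:
        for sid in sys_.species_ids:
            col = conc[sid].to_numpy()
            bad = np.nonzero(col < -10 * atol)[0]
            if bad.size:
                negative_events.append((float(sol.t[bad[0]]), sid))

    return Trajectory(sol.t, conc, fluxes, model, clamps or ClampSpec(),
                      balanced_species_ids(model, clamps),
                      negative_events, sys_.clip_count)


def _criterion_series(traj: Trajectory, floor: float) -> np.ndarray:
    """Normalized-derivative criterion value at each grid time."""
    sys_ = _System(traj.model, traj.clamps)
    bal = [sys_.index[s] for s in traj.balanced_species]
    vals = np.empty(traj.time.size)
    y = traj.concentrations.to_numpy()
    for k in range(traj.time.size):
        dx = sys_.rhs(traj.time[k], y[k])
        if bal:
            denom = np.maximum(np.abs(y[k][bal]), floor)
            vals[k] = float(np.max(np.abs(dx[bal]) / denom))
        else:
            vals[k] = 0.0
    return vals


def time_to_steady_state(traj: Trajectory, epsilon: float = DEFAULT_EPSILON,
                         floor: float = DEFAULT_FLOOR) -> float:
    """First grid time after which the criterion stays below epsilon.

    Returns ``nan`` if the trajectory never satisfies the criterion for the
    rest of the recorded window.
    """
    vals = _criterion_series(traj, floor)
    below = vals < epsilon
    # first index from which every later point is also below epsilon
    ok_from = np.where(~below[::-1])[0]
    if ok_from.size == 0:
        return float(traj.time[0])
    first_bad_from_end = ok_from[0]
    idx = vals.size - first_bad_from_end
    if idx >= vals.size:
        return float("nan")
    return float(traj.time[idx])


def find_steady_state(model: ModelSpec, clamps: Optional[ClampSpec] = None,
                      t_cap: float = TIME_CAP, epsilon: float = DEFAULT_EPSILON,
                      floor: float = DEFAULT_FLOOR,
                      initial_state: Optional[Mapping[str, float]] = None,
                      refine: bool = True,
                      rtol: float = DEFAULT_RTOL, atol: float = DEFAULT_ATOL,
                      divergence_cap: float = DIVERGENCE_CAP) -> SteadyStateResult:
    """Long integration until the criterion holds, then damped root refinement
    of N v(X) restricted to the balanced species.

    All-clamped models are trivially steady at t = 0.  Divergent trajectories
    raise :class:`UnboundedAccumulation`.
    """
    sys_ = _System(model, clamps)
    bal_ids = balanced_species_ids(model, clamps)
    bal_idx = np.array([sys_.index[s] for s in bal_ids], dtype=int)

    x0 = sys_.initial_vector()
    if initial_state:
        for sid, v in initial_state.items():
            x0[sys_.index[sid]] = v
        for sid, v in sys_.overrides.items():
            x0[sys_.index[sid]] = v

    if bal_idx.size == 0:
        state = sys_.state_dict(x0)
        fluxes = dict(zip(sys_.reaction_ids, sys_.rates(x0)))
        return SteadyStateResult(state, fluxes, True, 0.0,
                                 {"epsilon": epsilon, "floor": floor,
                                  "rule": "normalized-derivative"}, 0.0)

    # chunked integration: grow the horizon geometrically until converged
    t_start = 0.0
    t_horizon = min(10.0, t_cap)
    y = x0
    traj: Optional[Trajectory] = None
    tss = float("nan")
    converged = False
    while True:
        traj = integrate(model, clamps, t_end=t_horizon - t_start,
                         rtol=rtol, atol=atol,
                         initial_state=sys_.state_dict(y) if t_start > 0 else
                         (initial_state or None),
                         divergence_cap=divergence_cap)
        y = traj.concentrations.iloc[-1].to_numpy()
        t_candidate = time_to_steady_state(traj, epsilon, floor)
        if not math.isnan(t_candidate) and t_candidate < traj.time[-1]:
            tss = t_start + t_candidate
            converged = True
            break
        if t_horizon >= t_cap:
            break
        t_start = t_horizon
        t_horizon = min(t_horizon * 10.0, t_cap)

    state_vec = y.copy()
    if converged and refine:
        base = state_vec.copy()

        def fun_from(x):
            z = base.copy()
            z[bal_idx] = x
            return (sys_.n @ sys_.rates(z))[bal_idx]

        sol = root(fun_from, state_vec[bal_idx], method="hybr")
        if sol.success and np.all(sol.x > -10 * atol):
            cand = np.maximum(sol.x, 0.0)
            old_res = np.max(np.abs(fun_from(state_vec[bal_idx])))
            new_res = np.max(np.abs(fun_from(cand)))
            if new_res <= old_res:
                state_vec[bal_idx] = cand

    dx = sys_.rhs(0.0, state_vec)
    residual = float(np.max(np.abs(dx[bal_idx])))
    state = sys_.state_dict(state_vec)
    fluxes = dict(zip(sys_.reaction_ids, sys_.rates(state_vec)))

    # epsilon-sensitivity band for the reported time
    band: Dict[str, float] = {}
    if traj is not None and converged:
        for eps in (1e-5, 1e-6, 1e-7):
            band[f"{eps:g}"] = time_to_steady_state(traj, eps, floor)

    criterion = {"rule": "normalized-derivative", "epsilon": epsilon,
                 "floor": floor, "epsilon_band": band}
    return SteadyStateResult(state, fluxes, converged, tss, criterion, residual,
                             "" if converged else "time cap reached before convergence")


def match_flux(model_a: ModelSpec, model_b: ModelSpec, reference_flux_id: str,
               knob_parameters: Sequence[str], delta_flux: float,
               clamps: Optional[ClampSpec] = None,
               scale_bounds: Tuple[float, float] = (0.02, 50.0)) -> ModelSpec:
    """Scale ``knob_parameters`` of model_b until its steady-state reference
    flux matches model_a's within ``delta_flux`` (absolute, mM/s).

    The adjustment is recorded in model_b's lineage.  Raises if no scale in
    ``scale_bounds`` brackets a match.
    """
    target = find_steady_state(model_a, clamps).fluxes[reference_flux_id]

    def mismatch(scale: float) -> float:
        m = _with_scaled_knobs(model_b, knob_parameters, scale)
        return find_steady_state(m, clamps).fluxes[reference_flux_id] - target

    f0 = mismatch(1.0)
    if abs(f0) <= delta_flux:
        out = _with_scaled_knobs(model_b, knob_parameters, 1.0)
        out.append_lineage("match_flux", {"reference": reference_flux_id,
                                          "knobs": list(knob_parameters),
                                          "scale": 1.0, "delta_flux": delta_flux})
        return out

    lo, hi = scale_bounds
    flo, fhi = mismatch(lo), mismatch(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"no knob scale in [{lo}, {hi}] matches flux {reference_flux_id!r} "
            f"(mismatch {flo:.3g} .. {fhi:.3g})")
    scale = brentq(mismatch, lo, hi, xtol=1e-10, rtol=1e-10)
    # tighten: brentq guarantees a root of the smooth mismatch
    out = _with_scaled_knobs(model_b, knob_parameters, scale)
    achieved = find_steady_state(out, clamps).fluxes[reference_flux_id]
    if abs(achieved - target) > delta_flux:
        raise ValueError(
            f"flux matching stalled: |{achieved:.6g} - {target:.6g}| > {delta_flux}")
    out.append_lineage("match_flux", {"reference": reference_flux_id,
                                      "knobs": list(knob_parameters),
                                      "scale": scale, "delta_flux": delta_flux})
    return out


def _with_scaled_knobs(model: ModelSpec, knobs: Sequence[str], scale: float) -> ModelSpec:
    from .serialize import clone_model
    out = clone_model(model)
    for name in knobs:
        if name not in out.parameters:
            raise KeyError(f"knob parameter {name!r} not in model")
        out.parameters.set(name, out.parameters.get(name) * scale,
                           out.parameters.unit(name))
    return out
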