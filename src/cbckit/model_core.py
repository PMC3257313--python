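"""Reaction-network data model for Calvin-Benson cycle kinetics.

The cycle is treated as a plain reaction network: species with carbon and
phosphate counts, reactions with real-valued stoichiometric coefficients, and
a named parameter set with unit tags.  Non-integer coefficients are
first-class because the lumped carboxylation/oxygenation reaction

    RuBP + CO2 -> A*PGA + B*PGCA

distributes the two three-carbon-equivalent products of a RuBisCO turnover
between 3-phosphoglycerate and 2-phosphoglycolate according to the
oxygenation fraction.  Element bookkeeping is reported, never silently
"fixed": the printed lump is not exactly carbon-closed and the toolkit must
say so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

from . import rate_laws as _rl

__all__ = [
    "SpeciesSpec", "ReactionSpec", "Parameter", "ParameterSet", "ModelSpec",
    "Diagnostic", "validate_model", "stoichiometry_matrix", "StoichiometryMatrix",
    "element_balance", "lumped_carboxylation_stoichiometry",
    "carbon_conversion_factor",
]


@dataclass
class SpeciesSpec:
    """One chemical species.

    ``clamped`` species keep a constant concentration during simulation
    (SBML boundary condition).  ``accumulator`` species are open product
    pools (starch, sink pools) that grow without bound at steady state and
    are therefore excluded from steady-state detection.
    """

    id: str
    name: str = ""
    compartment: str = "cell"
    initial_concentration: float = 0.0  # mM
    carbons: Optional[int] = None
    phosphates: Optional[int] = None
    clamped: bool = False
    accumulator: bool = False


@dataclass
class ReactionSpec:
    """A reaction: stoichiometry map (reactants negative, products positive),
    modifier species entering the rate law only, and a rate law."""

    id: str
    stoichiometry: Dict[str, float]
    rate_law: "_rl.RateLaw"
    modifiers: List[str] = field(default_factory=list)
    reversible: bool = False
    name: str = ""


@dataclass
class Parameter:
    value: float
    unit: str = ""  # e.g. "mM", "mM/s", "1/s", "dimensionless"


class ParameterSet:
    """Named parameters with unit tags.

    Reserved names used across the library include ``kE7`` (transketolase
    equilibrium constant), ``kM103`` (Michaelis constant of the Ri5P modifier
    term in the F6P transketolase reaction), ``Vm11`` and the translocator
    Michaelis constants, the starch-phosphorylase constants, the oxygenase
    constants, ``f_oxygenation`` and ``adenylate_total``.
    """

    def __init__(self, values: Optional[Mapping[str, Parameter]] = None):
        self._params: Dict[str, Parameter] = dict(values or {})

    @classmethod
    def from_dict(cls, values: Mapping[str, Tuple[float, str]]) -> "ParameterSet":
        return cls({k: Parameter(float(v), u) for k, (v, u) in values.items()})

    def set(self, name: str, value: float, unit: str = "") -> None:
        self._params[name] = Parameter(float(value), unit)

    def get(self, name: str) -> float:
        return self._params[name].value

    def unit(self, name: str) -> str:
        return self._params[name].unit

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __getitem__(self, name: str) -> float:
        return self.get(name)

    def __iter__(self):
        return iter(self._params)

    def items(self):
        return self._params.items()

    def values_dict(self) -> Dict[str, float]:
        return {k: p.value for k, p in self._params.items()}

    def copy(self) -> "ParameterSet":
        return ParameterSet({k: Parameter(p.value, p.unit) for k, p in self._params.items()})

    def __eq__(self, other) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return self._params == other._params

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParameterSet({len(self._params)} parameters)"


@dataclass
class ModelSpec:
    """A complete reaction network with variant lineage metadata.

    ``lineage`` is an append-only list of ``(base-or-patch name, arguments)``
    descriptors; a model is reconstructible from its base variant plus the
    recorded patches.  ``diagnostic_mode`` flags deliberate reproductions of
    documented defects (e.g. the uncorrected starch law), in which negative
    concentrations are representable.
    """

    id: str
    species: List[SpeciesSpec]
    reactions: List[ReactionSpec]
    parameters: ParameterSet
    lineage: List[dict] = field(default_factory=list)
    compartment_volume_l: float = 1.0
    diagnostic_mode: bool = False
    reference_flux_id: Optional[str] = None  # the RuBP-synthesis reaction, if any
    notes: str = ""

    # -- convenience accessors -------------------------------------------------
    def species_ids(self) -> List[str]:
        return [s.id for s in self.species]

    def get_species(self, sid: str) -> SpeciesSpec:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def get_reaction(self, rid: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def has_species(self, sid: str) -> bool:
        return any(s.id == sid for s in self.species)

    def initial_state(self) -> Dict[str, float]:
        return {s.id: s.initial_concentration for s in self.species}

    def append_lineage(self, name: str, arguments: Optional[dict] = None,
                       note: str = "") -> None:
        entry = {"name": name, "arguments": dict(arguments or {})}
        if note:
            entry["note"] = note
        self.lineage.append(entry)


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "error" | "warning"
    location: str  # species/reaction/parameter id or "model"
    message: str

    def is_error(self) -> bool:
        return self.severity == "error"


# --- unit expectations per rate-law family slot ------------------------------
# Keyed by (family, role-prefix); validation only checks that a unit tag is
# present and, where the family fixes it, that it matches.
_EXPECTED_UNITS = {
    "vmax": "mM/s",
    "km": "mM",
    "ki": "mM",
    "keq": "",  # dimension depends on stoichiometry; only presence is required
}


def validate_model(model: ModelSpec) -> List[Diagnostic]:
    """Check type invariants and rate-law resolvability.

    Returns an empty list iff the model is well-formed.  Problems are
    reported as diagnostics (never raised): a model that deliberately
    reproduces a documented defect must remain representable.
    """
    out: List[Diagnostic] = []
    ids = [s.id for s in model.species]
    seen = set()
    for sid in ids:
        if sid in seen:
            out.append(Diagnostic("error", sid, "duplicate species id"))
        seen.add(sid)

    for s in model.species:
        if s.initial_concentration < 0 and not model.diagnostic_mode:
            out.append(Diagnostic(
                "error", s.id,
                f"negative initial concentration {s.initial_concentration} mM "
                "outside diagnostic-reproduction mode"))

    known = set(ids)
    rseen = set()
    for r in model.reactions:
        if r.id in rseen:
            out.append(Diagnostic("error", r.id, "duplicate reaction id"))
        rseen.add(r.id)
        if not any(c != 0 for c in r.stoichiometry.values()):
            out.append(Diagnostic("error", r.id, "all stoichiometric coefficients are zero"))
        for sid in r.stoichiometry:
            if sid not in known:
                out.append(Diagnostic("error", r.id, f"stoichiometry references unknown species {sid!r}"))
        for sid in r.modifiers:
            if sid not in known:
                out.append(Diagnostic("error", r.id, f"modifier references unknown species {sid!r}"))
        out.extend(_validate_rate_law(model, r))

    # parameter positivity and unit tags
    for name, p in model.parameters.items():
        if name == "f_oxygenation":
            if not (0.0 <= p.value <= 0.5):
                out.append(Diagnostic("error", name, "f_oxygenation must lie in [0, 0.5]"))
            continue
        if p.value <= 0 and not model.diagnostic_mode:
            out.append(Diagnostic("error", name, f"parameter must be strictly positive, got {p.value}"))

    out.extend(_physiology_warnings(model))
    return out


def _validate_rate_law(model: ModelSpec, r: ReactionSpec) -> List[Diagnostic]:
    out: List[Diagnostic] = []
    law = r.rate_law
    known = set(model.species_ids())
    for sid in law.species_symbols():
        if sid not in known:
            out.append(Diagnostic("error", r.id, f"rate law references unknown species {sid!r}"))
    for pname in law.parameter_symbols():
        if pname not in model.parameters:
            out.append(Diagnostic("error", r.id, f"rate law references undefined parameter {pname!r}"))
        else:
            unit = model.parameters.unit(pname)
            if unit == "":
                out.append(Diagnostic("warning", r.id, f"parameter {pname!r} carries no unit tag"))
    # Km = 0 would allow division by zero at S = 0
    for pname in law.parameter_symbols():
        if pname in model.parameters and model.parameters.get(pname) == 0:
            out.append(Diagnostic("error", r.id, f"parameter {pname!r} is zero (division hazard)"))
    if isinstance(law, _rl.Transketolase) and law.modifier_mode == "multiplicative_modifiers":
        out.append(Diagnostic(
            "warning", r.id,
            "modifier saturation terms are multiplied; the dimensionally "
            "consistent convention adds them (additive_modifiers)"))
    return out


def _physiology_warnings(model: ModelSpec) -> List[Diagnostic]:
    out: List[Diagnostic] = []
    # a transketolase modifier constant below 0.06 mM destabilises the
    # appendix-form (multiplicative-modifier) network
    if "kM103" in model.parameters and model.parameters.get("kM103") < 0.06:
        if any(isinstance(r.rate_law, _rl.Transketolase)
               and r.rate_law.modifier_mode == "multiplicative_modifiers"
               for r in model.reactions):
            out.append(Diagnostic(
                "warning", "kM103",
                f"kM103 = {model.parameters.get('kM103')} mM: the multiplicative-"
                "modifier transketolase network is unstable below 0.06 mM"))
    return out


@dataclass(frozen=True)
class StoichiometryMatrix:
    matrix: np.ndarray  # species x reactions
    species_ids: Tuple[str, ...]
    reaction_ids: Tuple[str, ...]
    clamped: np.ndarray  # boolean mask over species rows

    def column(self, reaction_id: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(reaction_id)]

    def row(self, species_id: str) -> np.ndarray:
        return self.matrix[self.species_ids.index(species_id), :]


def stoichiometry_matrix(model: ModelSpec) -> StoichiometryMatrix:
    """Species-by-reactions coefficient matrix.

    Clamped species keep their rows (flux accounting still needs them); the
    simulator zeroes their time derivatives instead.
    """
    sids = model.species_ids()
    index = {sid: i for i, sid in enumerate(sids)}
    mat = np.zeros((len(sids), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for sid, coef in r.stoichiometry.items():
            mat[index[sid], j] = coef
    clamped = np.array([s.clamped for s in model.species], dtype=bool)
    return StoichiometryMatrix(mat, tuple(sids), tuple(r.id for r in model.reactions), clamped)


def element_balance(model: ModelSpec, element: str) -> Dict[str, float]:
    """Per-reaction element imbalance, in atoms per reaction event.

    ``element`` is ``"carbon"`` or ``"phosphate"``.  Zero means balanced.
    Species without a declared count raise a ``ValueError`` naming them.
    """
    if element not in ("carbon", "phosphate"):
        raise ValueError(f"unknown element {element!r}")
    attr = "carbons" if element == "carbon" else "phosphates"
    counts: Dict[str, Optional[int]] = {s.id: getattr(s, attr) for s in model.species}
    out: Dict[str, float] = {}
    for r in model.reactions:
        total = 0.0
        for sid, coef in r.stoichiometry.items():
            n = counts[sid]
            if n is None:
                raise ValueError(f"species {sid!r} has no declared {element} count")
            total += coef * n
        out[r.id] = 0.0 if abs(total) < 1e-12 else total
    return out


def lumped_carboxylation_stoichiometry(
        f_oxygenation: float,
        convention: str = "product_pair") -> Tuple[float, float]:
    """PGA and PGCA coefficients (A, B) of the lumped RuBisCO reaction.

    Each RuBP turnover yields two three-carbon-equivalent product slots; an
    oxygenation fraction ``f`` diverts ``2*f`` of them to 2-phosphoglycolate:
    ``B = 2*f`` and ``A = 2 - 2*f`` (so ``f = 0.042`` gives the pair
    ``(1.916, 0.084)``).  The alternative reading, one PGCA per oxygenation
    event (``B = f``), is selectable with ``convention="event_fraction"``.
    """
    if not (0.0 <= f_oxygenation <= 0.5):
        raise ValueError(f"f_oxygenation must lie in [0, 0.5], got {f_oxygenation}")
    if convention == "product_pair":
        b = 2.0 * f_oxygenation
    elif convention == "event_fraction":
        b = float(f_oxygenation)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return 2.0 - b, b


def carbon_conversion_factor(source_carbons: int, target_carbons: int) -> float:
    """Carbon-equivalent conversion factor between two species.

    Folding a minor sink into the PGA sink multiplies its flux by
    ``source_carbons / target_carbons`` (e.g. a 5-carbon species folded into
    the 3-carbon PGA sink gives 5/3 = 1.67).  Full precision is returned;
    round only for display.
    """
    if source_carbons <= 0 or target_carbons <= 0:
        raise ValueError("carbon counts must be positive integers")
    return source_carbons / target_carbons
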