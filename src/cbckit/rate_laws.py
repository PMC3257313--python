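"""Rate-law families for Calvin-Benson cycle models.

Every family is a pure function of (state, parameters).  Besides plain mass
action and (reversible) Michaelis-Menten forms, the module carries the
special forms that Calvin-cycle models use or got wrong:

* ``Transketolase`` — two-substrate reversible form whose equilibrium
  constant multiplies the *forward* term, ``v = Vm*(kE*S1*S2 - P1*P2)/D``.
  With the mis-set value kE7 = 10 instead of the literature 0.076 this
  overdrives the forward rate ~130-fold, which is exactly the defect class
  the corrected models repair.  The modifier saturation factor (E4P and Ri5P
  terms) is additive in the dimensionally consistent convention; the variant
  that multiplies the terms instead is selectable because a published model
  encodes it that way.
* ``Translocator`` — the chloroplast phosphate-translocator PGA export law
  (V_PGAout): antisymmetric exchange between stromal and cytosolic
  phosphate/PGA/triose-phosphate pools.
* ``Oxygenase`` — RuBisCO O2 fixation with competitive CO2 and
  sugar-phosphate inhibition.
* ``StarchPhosphorylase`` — starch degradation; the ``original`` variant
  reproduces the documented defect of using stromal phosphate in the
  substrate position, which lets degradation run at zero starch and drives
  the starch concentration negative.  The ``corrected`` variant substitutes
  starch itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from . import expr as _expr
from .expr import Expr, parse_expression

__all__ = [
    "RateLaw", "MassAction", "MichaelisMenten", "ReversibleMM", "Transketolase",
    "Translocator", "Oxygenase", "StarchPhosphorylase", "GenericExpression",
    "evaluate_rate", "transketolase_rate", "translocator_rate",
    "oxygenase_rate", "starch_phosphorylase_rate",
]


def _get(params, name: str) -> float:
    """Parameter lookup accepting ParameterSet or a plain mapping."""
    try:
        return float(params[name])
    except (KeyError, TypeError):
        raise KeyError(f"unresolved parameter {name!r}") from None


def _conc(state: Mapping[str, float], sid: str) -> float:
    try:
        return float(state[sid])
    except KeyError:
        raise KeyError(f"unresolved species {sid!r}") from None


@dataclass
class MassAction:
    """k * prod(reactants^order), optionally minus (k/Keq) * prod(products)."""

    k: str
    reactants: List[Tuple[str, float]]
    products: List[Tuple[str, float]] = field(default_factory=list)
    keq: Optional[str] = None

    family = "mass_action"

    def species_symbols(self) -> List[str]:
        return [s for s, _ in self.reactants] + [s for s, _ in self.products]

    def parameter_symbols(self) -> List[str]:
        return [self.k] + ([self.keq] if self.keq else [])

    def evaluate(self, state, params) -> float:
        k = _get(params, self.k)
        fwd = k
        for sid, order in self.reactants:
            fwd *= _conc(state, sid) ** order
        if self.keq is None:
            return fwd
        rev = k / _get(params, self.keq)
        for sid, order in self.products:
            rev *= _conc(state, sid) ** order
        return fwd - rev

    def to_expression(self) -> Expr:
        def prod(terms):
            parts = [f"{s}^{o:g}" if o != 1 else s for s, o in terms]
            return " * ".join(parts) if parts else "1"
        text = f"{self.k} * {prod(self.reactants)}"
        if self.keq is not None:
            text += f" - {self.k} / {self.keq} * {prod(self.products)}"
        return parse_expression(text)


@dataclass
class MichaelisMenten:
    """Irreversible MM; competitive inhibitors raise the first substrate's Km:
    v = Vmax * prod_i S_i/(S_i + Km_i * (1 + sum_j I_j/Ki_j  [i = 0]))."""

    vmax: str
    substrates: List[Tuple[str, str]]  # (species, km parameter)
    inhibitors: List[Tuple[str, str]] = field(default_factory=list)  # (species, ki parameter)

    family = "michaelis_menten"

    def species_symbols(self) -> List[str]:
        return [s for s, _ in self.substrates] + [s for s, _ in self.inhibitors]

    def parameter_symbols(self) -> List[str]:
        return [self.vmax] + [k for _, k in self.substrates] + [k for _, k in self.inhibitors]

    def evaluate(self, state, params) -> float:
        v = _get(params, self.vmax)
        for i, (sid, km) in enumerate(self.substrates):
            s = _conc(state, sid)
            keff = _get(params, km)
            if i == 0 and self.inhibitors:
                keff *= 1.0 + sum(_conc(state, isid) / _get(params, ki)
                                  for isid, ki in self.inhibitors)
            v *= s / (s + keff)
        return v

    def to_expression(self) -> Expr:
        parts = []
        for i, (sid, km) in enumerate(self.substrates):
            keff = km
            if i == 0 and self.inhibitors:
                inh = " + ".join(f"{isid} / {ki}" for isid, ki in self.inhibitors)
                keff = f"{km} * (1 + {inh})"
            parts.append(f"{sid} / ({sid} + {keff})")
        return parse_expression(f"{self.vmax} * " + " * ".join(parts))


@dataclass
class ReversibleMM:
    """Reversible MM: v = Vm*(prod S - prod P / Keq) / D with a saturating
    denominator D = prod Km_S * prod(1 + S/Km_S) * prod(1 + P/Km_P)."""

    vmax: str
    substrates: List[Tuple[str, str]]
    products: List[Tuple[str, str]]
    keq: str

    family = "reversible_mm"

    def species_symbols(self) -> List[str]:
        return [s for s, _ in self.substrates] + [s for s, _ in self.products]

    def parameter_symbols(self) -> List[str]:
        return ([self.vmax, self.keq]
                + [k for _, k in self.substrates] + [k for _, k in self.products])

    def evaluate(self, state, params) -> float:
        fwd = 1.0
        denom = 1.0
        for sid, km in self.substrates:
            s, k = _conc(state, sid), _get(params, km)
            fwd *= s
            denom *= k * (1.0 + s / k)
        rev = 1.0 / _get(params, self.keq)
        for sid, km in self.products:
            p, k = _conc(state, sid), _get(params, km)
            rev *= p
            denom *= 1.0 + p / k
        return _get(params, self.vmax) * (fwd - rev) / denom

    def to_expression(self) -> Expr:
        fwd = " * ".join(s for s, _ in self.substrates)
        rev = " * ".join(s for s, _ in self.products) or "1"
        denom = " * ".join([f"{km}" for _, km in self.substrates]
                           + [f"(1 + {s} / {km})" for s, km in self.substrates]
                           + [f"(1 + {p} / {km})" for p, km in self.products])
        return parse_expression(
            f"{self.vmax} * ({fwd} - {rev} / {self.keq}) / ({denom})")


@dataclass
class Transketolase:
    """Transketolase-type reversible two/two form with shared modifier factor.

    v = Vm * (kE*S1*S2 - P1*P2) / (Km1*Km2*(1 + S1/Km1)*(1 + S2/Km2)*TEMP)

    TEMP combines the modifier saturation terms:
      additive_modifiers:        1 + sum_m M/Km_m        (consistent form)
      multiplicative_modifiers:  prod_m (1 + M/Km_m)     (documented defect)
    The rate vanishes exactly when P1*P2 = kE * S1*S2 (detailed balance).
    """

    vmax: str
    s1: str
    s2: str
    p1: str
    p2: str
    km_s1: str
    km_s2: str
    keq: str = "kE7"
    modifiers: List[Tuple[str, str]] = field(default_factory=list)  # (species, km parameter)
    modifier_mode: str = "additive_modifiers"

    family = "transketolase"

    def species_symbols(self) -> List[str]:
        return [self.s1, self.s2, self.p1, self.p2] + [m for m, _ in self.modifiers]

    def parameter_symbols(self) -> List[str]:
        return [self.vmax, self.keq, self.km_s1, self.km_s2] + [k for _, k in self.modifiers]

    def modifier_factor(self, state, params) -> float:
        if self.modifier_mode == "multiplicative_modifiers":
            out = 1.0
            for sid, km in self.modifiers:
                out *= 1.0 + _conc(state, sid) / _get(params, km)
            return out
        return 1.0 + sum(_conc(state, sid) / _get(params, km)
                         for sid, km in self.modifiers)

    def evaluate(self, state, params) -> float:
        s1, s2 = _conc(state, self.s1), _conc(state, self.s2)
        p1, p2 = _conc(state, self.p1), _conc(state, self.p2)
        k1, k2 = _get(params, self.km_s1), _get(params, self.km_s2)
        if _get(params, self.km_s2) <= 0 or k1 <= 0:
            raise ValueError("transketolase Michaelis constants must be positive")
        num = _get(params, self.keq) * s1 * s2 - p1 * p2
        denom = k1 * k2 * (1.0 + s1 / k1) * (1.0 + s2 / k2) * self.modifier_factor(state, params)
        return _get(params, self.vmax) * num / denom

    def to_expression(self) -> Expr:
        if self.modifier_mode == "multiplicative_modifiers":
            temp = " * ".join(f"(1 + {m} / {km})" for m, km in self.modifiers) or "1"
        else:
            terms = " + ".join(f"{m} / {km}" for m, km in self.modifiers)
            temp = f"(1 + {terms})" if terms else "1"
        return parse_expression(
            f"{self.vmax} * ({self.keq} * {self.s1} * {self.s2} - {self.p1} * {self.p2})"
            f" / ({self.km_s1} * {self.km_s2} * (1 + {self.s1} / {self.km_s1})"
            f" * (1 + {self.s2} / {self.km_s2}) * {temp})")


# role -> (species symbol default, Km parameter) for the translocator
_TRANSLOCATOR_ROLES = ("OP", "PGA", "GAP", "DHAP", "OPc", "PGAc", "GAPc", "DHAPc")


@dataclass
class Translocator:
    """Phosphate-translocator PGA export law (V_PGAout).

    With stromal saturation sum  T_s = OP/KmOP + PGA/KmPGA + (GAP+DHAP)/KmT3P
    and the cytosolic sum T_c defined analogously,

        v = Vm11 * (T_c * PGA/KmPGA - T_s * PGAc/KmPGAc) / (T_s + T_c + T_s*T_c)

    Positive v is net stromal -> cytosolic PGA export.  The law is
    antisymmetric under exchange of the stromal and cytosolic compositions.
    No idle-carrier "+1" term is added to the denominator: the form follows
    the source equation exactly.
    """

    vmax: str = "Vm11"
    species: Dict[str, str] = field(default_factory=lambda: {r: r for r in _TRANSLOCATOR_ROLES})

    family = "translocator"

    def species_symbols(self) -> List[str]:
        return [self.species[r] for r in _TRANSLOCATOR_ROLES]

    def parameter_symbols(self) -> List[str]:
        return [self.vmax, "KmOP", "KmPGA", "KmT3P", "KmOPc", "KmPGAc", "KmT3Pc"]

    def _sums(self, state, params) -> Tuple[float, float]:
        sp = self.species
        t_s = (_conc(state, sp["OP"]) / _get(params, "KmOP")
               + _conc(state, sp["PGA"]) / _get(params, "KmPGA")
               + (_conc(state, sp["GAP"]) + _conc(state, sp["DHAP"])) / _get(params, "KmT3P"))
        t_c = (_conc(state, sp["OPc"]) / _get(params, "KmOPc")
               + _conc(state, sp["PGAc"]) / _get(params, "KmPGAc")
               + (_conc(state, sp["GAPc"]) + _conc(state, sp["DHAPc"])) / _get(params, "KmT3Pc"))
        return t_s, t_c

    def evaluate(self, state, params) -> float:
        t_s, t_c = self._sums(state, params)
        denom = t_s + t_c + t_s * t_c
        if denom == 0.0:
            return 0.0
        sp = self.species
        num = (t_c * _conc(state, sp["PGA"]) / _get(params, "KmPGA")
               - t_s * _conc(state, sp["PGAc"]) / _get(params, "KmPGAc"))
        return _get(params, self.vmax) * num / denom

    def to_expression(self) -> Expr:
        sp = self.species
        ts = f"({sp['OP']} / KmOP + {sp['PGA']} / KmPGA + ({sp['GAP']} + {sp['DHAP']}) / KmT3P)"
        tc = f"({sp['OPc']} / KmOPc + {sp['PGAc']} / KmPGAc + ({sp['GAPc']} + {sp['DHAPc']}) / KmT3Pc)"
        return parse_expression(
            f"{self.vmax} * ({tc} * {sp['PGA']} / KmPGA - {ts} * {sp['PGAc']} / KmPGAc)"
            f" / ({ts} + {tc} + {ts} * {tc})")


@dataclass
class Oxygenase:
    """RuBisCO O2-fixation rate:

    v = RuBP*Vo*O2 / (O2 + Ko*(1 + CO2/Kc))
        / (RuBP + Kr*(1 + PGA/KI11 + FBP/KI12 + SBP/KI13 + Pi/KI14 + NADPH/KI15))
    """

    vmax: str = "Vo"
    species: Dict[str, str] = field(default_factory=lambda: {
        r: r for r in ("RuBP", "O2", "CO2", "PGA", "FBP", "SBP", "Pi", "NADPH")})

    family = "oxygenase"

    def species_symbols(self) -> List[str]:
        return list(self.species.values())

    def parameter_symbols(self) -> List[str]:
        return [self.vmax, "Ko", "Kc", "Kr", "KI11", "KI12", "KI13", "KI14", "KI15"]

    def evaluate(self, state, params) -> float:
        sp = self.species
        rubp = _conc(state, sp["RuBP"])
        o2 = _conc(state, sp["O2"])
        o2_sat = o2 / (o2 + _get(params, "Ko") * (1.0 + _conc(state, sp["CO2"]) / _get(params, "Kc")))
        inhib = (1.0
                 + _conc(state, sp["PGA"]) / _get(params, "KI11")
                 + _conc(state, sp["FBP"]) / _get(params, "KI12")
                 + _conc(state, sp["SBP"]) / _get(params, "KI13")
                 + _conc(state, sp["Pi"]) / _get(params, "KI14")
                 + _conc(state, sp["NADPH"]) / _get(params, "KI15"))
        return rubp * _get(params, self.vmax) * o2_sat / (rubp + _get(params, "Kr") * inhib)

    def to_expression(self) -> Expr:
        sp = self.species
        inhib = (f"(1 + {sp['PGA']} / KI11 + {sp['FBP']} / KI12 + {sp['SBP']} / KI13"
                 f" + {sp['Pi']} / KI14 + {sp['NADPH']} / KI15)")
        return parse_expression(
            f"{sp['RuBP']} * {self.vmax} * {sp['O2']}"
            f" / ({sp['O2']} + Ko * (1 + {sp['CO2']} / Kc))"
            f" / ({sp['RuBP']} + Kr * {inhib})")


@dataclass
class StarchPhosphorylase:
    """Starch degradation (E17-type law).

    corrected: v = VM * starch / (starch + km*(1 + G1P/kiG1P))   -> 0 at starch = 0
    original:  v = VM * Pi     / (Pi     + km*(1 + G1P/kiG1P))   -> can degrade
               non-existent starch, driving its concentration negative.
    """

    variant: str = "corrected"  # "corrected" | "original"
    vmax: str = "StPase_VM"
    km: str = "StPase_km"
    ki_g1p: str = "StPase_kiG1P"
    starch: str = "starch"
    pi: str = "Pi"
    g1p: str = "G1P"

    family = "starch_phosphorylase"

    def species_symbols(self) -> List[str]:
        return [self.starch, self.pi, self.g1p]

    def parameter_symbols(self) -> List[str]:
        return [self.vmax, self.km, self.ki_g1p]

    def evaluate(self, state, params) -> float:
        sub = _conc(state, self.pi if self.variant == "original" else self.starch)
        keff = _get(params, self.km) * (1.0 + _conc(state, self.g1p) / _get(params, self.ki_g1p))
        return _get(params, self.vmax) * sub / (sub + keff)

    def to_expression(self) -> Expr:
        sub = self.pi if self.variant == "original" else self.starch
        return parse_expression(
            f"{self.vmax} * {sub} / ({sub} + {self.km} * (1 + {self.g1p} / {self.ki_g1p}))")


@dataclass
class GenericExpression:
    """An arbitrary kinetic law kept as a parsed expression tree (typically an
    imported SBML law that matches no named family)."""

    expression: Expr
    parameters: List[str] = field(default_factory=list)  # symbols that are parameters
    species: List[str] = field(default_factory=list)     # symbols that are species

    family = "generic_expression"

    @classmethod
    def from_text(cls, text: str, species: Sequence[str] = (),
                  parameters: Sequence[str] = ()) -> "GenericExpression":
        e = parse_expression(text)
        syms = _expr.symbols(e)
        sp = [s for s in syms if s in set(species)]
        pars = [s for s in syms if s in set(parameters)] if parameters else \
            [s for s in syms if s not in set(species)]
        return cls(e, sorted(pars), sorted(sp))

    def species_symbols(self) -> List[str]:
        return list(self.species)

    def parameter_symbols(self) -> List[str]:
        return list(self.parameters)

    def evaluate(self, state, params) -> float:
        env: Dict[str, float] = {}
        for s in self.species:
            env[s] = _conc(state, s)
        for p in self.parameters:
            env[p] = _get(params, p)
        return _expr.evaluate(self.expression, env)

    def to_expression(self) -> Expr:
        return self.expression


RateLaw = Union[MassAction, MichaelisMenten, ReversibleMM, Transketolase,
                Translocator, Oxygenase, StarchPhosphorylase, GenericExpression]

FAMILIES = {cls.family: cls for cls in
            (MassAction, MichaelisMenten, ReversibleMM, Transketolase,
             Translocator, Oxygenase, StarchPhosphorylase, GenericExpression)}


def evaluate_rate(law: RateLaw, state: Mapping[str, float], params,
                  clip_negative: bool = False) -> float:
    """Evaluate a rate law at a concentration state (mM -> mM/s).

    ``clip_negative=True`` evaluates on concentrations floored at zero —
    the default simulation mode outside diagnostic reproductions.
    """
    if clip_negative:
        state = {k: (v if v > 0.0 else 0.0) for k, v in state.items()}
    return law.evaluate(state, params)


# --- convenience functional forms (fixed conventional species names) ---------

def transketolase_rate(state, params, variant: str = "additive_modifiers",
                       reaction: str = "v7") -> float:
    """Transketolase rate with the conventional species names.

    ``reaction="v7"``:  S7P + GAP = Ri5P + Xu5P   (Km names kM71, kM72)
    ``reaction="v10"``: F6P + GAP = E4P + Xu5P    (Km names kM101, kM104)
    Both share the equilibrium constant kE7 and the modifier factor with the
    E4P (kM102) and Ri5P (kM103) terms.
    """
    if reaction == "v7":
        law = Transketolase("Vm7", "S7P", "GAP", "Ri5P", "Xu5P", "kM71", "kM72",
                            keq="kE7",
                            modifiers=[("E4P", "kM102"), ("Ri5P", "kM103")],
                            modifier_mode=variant)
    elif reaction == "v10":
        law = Transketolase("Vm10", "F6P", "GAP", "E4P", "Xu5P", "kM101", "kM104",
                            keq="kE7",
                            modifiers=[("E4P", "kM102"), ("Ri5P", "kM103")],
                            modifier_mode=variant)
    else:
        raise ValueError(f"unknown transketolase reaction {reaction!r}")
    return law.evaluate(state, params)


def translocator_rate(state, params) -> float:
    """Net stromal -> cytosolic PGA export (V_PGAout) with conventional names."""
    return Translocator().evaluate(state, params)


def oxygenase_rate(state, params) -> float:
    """RuBisCO O2-fixation rate with conventional species names."""
    return Oxygenase().evaluate(state, params)


def starch_phosphorylase_rate(state, params, variant: str = "corrected") -> float:
    """Starch degradation rate; ``variant="original"`` reproduces the defect."""
    return StarchPhosphorylase(variant=variant).evaluate(state, params)
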