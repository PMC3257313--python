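"""Calvin-Benson cycle model variants and recorded, reversible corrections.

The library builds a one-compartment cyanobacterial Calvin-cycle network —
13 cycle reactions (CC_1..CC_13), 3 starch-synthesis reactions (SS_1..SS_3)
and a configurable set of export sinks (SR_*) — plus the defect-bearing
configurations the corrections repair:

* ``zhu_A`` / ``zhu_S`` — the two published transketolase encodings of the
  same C3 model (appendix-equation form with multiplied modifier terms, and
  supplement-encoded form with added modifier terms), both with the
  uncorrected kE7 = 10.
* ``cyano_C1`` / ``cyano_C2`` — no oxygenase; the 2-phosphoglycolate drain
  is folded into the PGA sink.  C1 also folds the minor sinks (DHAP, E4P,
  Ri5P); C2 declares them explicitly.
* ``cyano_D1`` / ``cyano_D2`` — photorespiration carried as O2 fixation via
  the lumped carboxylation stoichiometry RuBP + CO2 -> A*PGA + B*PGCA.
* ``hahn`` — a compact mass-action network with dynamic adenylates and a
  finite phosphate pool (the phosphate-depletion behavior class).

Quantitative parameterisations of the historical models are not printed in
the source literature available here; every variant is therefore built on a
designed fixture parameterisation (tagged ``non-archival`` in the lineage):
Michaelis constants sit at the design concentrations and maximal rates are
solved so that each reaction carries its design flux at the design state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import rate_laws as rl
from .model_core import (ModelSpec, Parameter, ParameterSet, ReactionSpec,
                         SpeciesSpec, lumped_carboxylation_stoichiometry)
from .serialize import clone_model

__all__ = [
    "PatchDescriptor", "SinkConfig", "build_model", "apply_patch",
    "configure_sink", "aggregate_minor_sinks", "default_sink_config",
    "rebuild_from_lineage", "perturbed_initial_state",
    "MINOR_SINK_FRACTIONS", "PGCA_FLUX_FRACTION", "F6P_FLUX_FRACTION",
    "REFERENCE_FLUX", "DESIGN_STATE",
]

# --- study conditions --------------------------------------------------------
# Flux fractions of the RuBP-synthesis flux, from the flux-balance analysis
# of the cyanobacterial network (consumed as printed constants).
MINOR_SINK_FRACTIONS: Dict[str, float] = {"Ri5P": 0.007, "DHAP": 0.0032, "E4P": 0.0031}
PGCA_FLUX_FRACTION = 0.042
F6P_FLUX_FRACTION = 0.024
STARCH_FLUX_FRACTION = 0.02     # designed starch-synthesis share
REFERENCE_FLUX = 0.1            # mM/s, design RuBP-synthesis flux

# printed carbon-equivalent factors for folding minor sinks into the PGA sink
_PRINTED_Q = {"Ri5P": 5.0 / 3.0, "DHAP": 1.0, "E4P": 4.0 / 3.0, "PGCA": 1.66}

# design steady state of the template (mM); Michaelis constants anchor here
DESIGN_STATE: Dict[str, float] = {
    "RuBP": 2.0, "PGA": 5.0, "BPGA": 0.3, "GAP": 0.5, "DHAP": 2.5,
    "FBP": 0.7, "F6P": 2.0, "E4P": 0.15, "Xu5P": 0.25, "SBP": 0.6,
    "S7P": 1.5, "Ri5P": 0.12, "Ru5P": 0.3, "G6P": 3.0, "G1P": 0.2,
    "starch": 0.0, "ATP": 1.5, "ADP": 0.5, "NADPH": 0.5, "NADP": 0.5,
    "CO2": 0.2, "O2": 0.25, "Pi": 5.0, "PGCA": 0.05,
}

_CARBONS = {
    "RuBP": 5, "PGA": 3, "BPGA": 3, "GAP": 3, "DHAP": 3, "FBP": 6, "F6P": 6,
    "E4P": 4, "Xu5P": 5, "SBP": 7, "S7P": 7, "Ri5P": 5, "Ru5P": 5, "G6P": 6,
    "G1P": 6, "starch": 6, "ATP": 0, "ADP": 0, "NADPH": 0, "NADP": 0,
    "CO2": 1, "O2": 0, "Pi": 0, "PGCA": 2,
}
_PHOSPHATES = {
    "RuBP": 2, "PGA": 1, "BPGA": 2, "GAP": 1, "DHAP": 1, "FBP": 2, "F6P": 1,
    "E4P": 1, "Xu5P": 1, "SBP": 2, "S7P": 1, "Ri5P": 1, "Ru5P": 1, "G6P": 1,
    "G1P": 1, "starch": 0, "ATP": 3, "ADP": 2, "NADPH": 0, "NADP": 0,
    "CO2": 0, "O2": 0, "Pi": 1, "PGCA": 1,
}

_CLAMPED = ("ATP", "ADP", "NADPH", "NADP", "CO2", "O2", "Pi")

# out-of-steady-state initial condition used by the comparative analyses
_PERTURBATION = {"PGA": 3.0, "RuBP": 0.5, "F6P": 0.5, "S7P": 2.0,
                 "GAP": 1.5, "DHAP": 0.8}


@dataclass
class PatchDescriptor:
    """A named correction with arguments and a free-text provenance note."""

    name: str
    arguments: Dict[str, object] = field(default_factory=dict)
    provenance: str = ""


@dataclass
class SinkConfig:
    """Which export reactions exist and with which kinetics.

    ``sinks`` maps species id -> (kinetics in {MA, MM, MMcb}, flux fraction
    of the reference RuBP-synthesis flux).  ``lumped_into_pga`` lists species
    whose fractions are folded into the PGA sink with carbon-equivalent
    factors q instead of getting their own reaction.
    """

    sinks: Dict[str, Tuple[str, float]]
    lumped_into_pga: Dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for sid, (kin, frac) in self.sinks.items():
            if kin not in ("MA", "MM", "MMcb"):
                raise ValueError(f"unknown sink kinetics {kin!r} for {sid}")
            if not (0.0 < frac < 1.0):
                raise ValueError(f"sink fraction for {sid} must lie in (0, 1)")
        dup = set(self.sinks) & set(self.lumped_into_pga)
        if dup:
            raise ValueError(f"species both explicit and lumped: {sorted(dup)}")


def aggregate_minor_sinks(fractions: Mapping[str, float],
                          q_rule: str = "printed_166_for_PGCA",
                          carbons: Optional[Mapping[str, int]] = None) -> float:
    """Added PGA-sink fraction from folding minor sinks: sum of q_i * f_i.

    ``q_rule``:
      * ``printed_166_for_PGCA`` (default): q(Ri5P)=5/3, q(DHAP)=1,
        q(E4P)=4/3, q(PGCA)=1.66.
      * ``carbon_ratio``: q = carbons(species) / 3 (declared counts needed).
      * ``unit``: q = 1 for all species (the raw fraction sum).
    """
    total = 0.0
    for sid, f in fractions.items():
        if f <= 0:
            raise ValueError(f"fraction for {sid} must be positive")
        if q_rule == "printed_166_for_PGCA":
            try:
                q = _PRINTED_Q[sid]
            except KeyError:
                c = (carbons or _CARBONS).get(sid)
                if c is None:
                    raise ValueError(f"no folding factor known for {sid!r}")
                q = c / 3.0
        elif q_rule == "carbon_ratio":
            c = (carbons or _CARBONS).get(sid)
            if c is None:
                raise ValueError(f"species {sid!r} has no declared carbon count")
            q = c / 3.0
        elif q_rule == "unit":
            q = 1.0
        else:
            raise ValueError(f"unknown q_rule {q_rule!r}")
        total += q * f
    return total


def default_sink_config(variant: str) -> SinkConfig:
    """The study-condition sink layout for each variant."""
    minors = dict(MINOR_SINK_FRACTIONS)
    f6p = ("MMcb", F6P_FLUX_FRACTION)
    if variant in ("zhu_A", "zhu_S", "cyano_C2"):
        sinks = {"PGA": ("MMcb", _design_pga_fraction("explicit_minors", pgca_folded=True)),
                 "F6P": f6p,
                 "DHAP": ("MMcb", minors["DHAP"]),
                 "E4P": ("MMcb", minors["E4P"]),
                 "Ri5P": ("MMcb", minors["Ri5P"])}
        return SinkConfig(sinks)
    if variant == "cyano_C1":
        sinks = {"PGA": ("MMcb", _design_pga_fraction("folded_minors", pgca_folded=True)),
                 "F6P": f6p}
        lumped = dict(minors)
        lumped["PGCA"] = PGCA_FLUX_FRACTION
        return SinkConfig(sinks, lumped)
    if variant == "cyano_D2":
        sinks = {"PGA": ("MMcb", _design_pga_fraction("explicit_minors", pgca_folded=False)),
                 "F6P": f6p,
                 "DHAP": ("MMcb", minors["DHAP"]),
                 "E4P": ("MMcb", minors["E4P"]),
                 "Ri5P": ("MMcb", minors["Ri5P"]),
                 "PGCA": ("MMcb", 2 * PGCA_FLUX_FRACTION)}
        return SinkConfig(sinks)
    if variant == "cyano_D1":
        sinks = {"PGA": ("MMcb", _design_pga_fraction("folded_minors", pgca_folded=False)),
                 "F6P": f6p,
                 "PGCA": ("MMcb", 2 * PGCA_FLUX_FRACTION)}
        return SinkConfig(sinks, dict(minors))
    if variant == "hahn":
        return SinkConfig({})
    raise ValueError(f"unknown variant {variant!r}")


# --- design flux bookkeeping -------------------------------------------------

def _design_fluxes(a_pga: float, explicit_minors: bool) -> Dict[str, float]:
    """Steady-state design fluxes (units of the reference flux F = 1).

    Solves the species balances of the template network for the internal
    fluxes given the sink fractions; the PGA sink fraction is whatever the
    carbon balance leaves over.
    """
    s_f6p = F6P_FLUX_FRACTION
    st = STARCH_FLUX_FRACTION
    if explicit_minors:
        s_dhap = MINOR_SINK_FRACTIONS["DHAP"]
        s_e4p = MINOR_SINK_FRACTIONS["E4P"]
        s_r5p = MINOR_SINK_FRACTIONS["Ri5P"]
    else:
        s_dhap = s_e4p = s_r5p = 0.0
    vt2 = (1.0 + s_r5p - s_e4p) / 3.0
    vt1 = vt2 + s_e4p
    vs = vt2
    vr1 = vt2 - s_r5p
    vr2 = vt1 + vt2
    vf = vt1 + st + s_f6p
    vd = vf + vs + s_dhap
    vb = vd + vf + vt1 + vt2
    s_pga = a_pga - vb
    if s_pga <= 0:
        raise ValueError("design has no room for a PGA sink")
    return {
        "CC_1": 1.0, "CC_2": vb, "CC_3": vb, "CC_4": vd, "CC_5": vf,
        "CC_6": vf, "CC_7": vt1, "CC_8": vs, "CC_9": vs, "CC_10": vt2,
        "CC_11": vr1, "CC_12": vr2, "CC_13": 1.0,
        "SS_1": st, "SS_2": st, "SS_3": st,
        "SR_PGA": s_pga, "SR_F6P": s_f6p, "SR_DHAP": s_dhap,
        "SR_E4P": s_e4p, "SR_Ri5P": s_r5p,
    }


def _design_pga_fraction(minors: str, pgca_folded: bool) -> float:
    f = _design_fluxes(2.0 if pgca_folded else 1.916,
                       explicit_minors=(minors == "explicit_minors"))
    return f["SR_PGA"]


# --- template construction ---------------------------------------------------

def _template_species(include_pgca: bool) -> List[SpeciesSpec]:
    out = []
    for sid, conc in DESIGN_STATE.items():
        if sid == "PGCA" and not include_pgca:
            continue
        out.append(SpeciesSpec(
            id=sid, name=sid, compartment="cell", initial_concentration=conc,
            carbons=_CARBONS[sid], phosphates=_PHOSPHATES[sid],
            clamped=sid in _CLAMPED, accumulator=(sid == "starch")))
    return out


def _rev(vmax, subs, prods, keq):
    return rl.ReversibleMM(vmax, subs, prods, keq)


def _template_reactions(params: ParameterSet, lump: Optional[Tuple[float, float]],
                        modifier_mode: str) -> List[ReactionSpec]:
    tk_mod = [("E4P", "kM102"), ("Ri5P", "kM103")]
    if lump is None:
        carbox_stoich = {"RuBP": -1.0, "CO2": -1.0, "PGA": 2.0}
    else:
        a, b = lump
        carbox_stoich = {"RuBP": -1.0, "CO2": -1.0, "PGA": a, "PGCA": b}
    reactions = [
        # product inhibition (PGA/FBP/SBP) is the negative feedback that keeps
        # the autocatalytic cycle off the collapse/blow-up knife edge
        ReactionSpec("CC_1", carbox_stoich,
                     rl.MichaelisMenten("Vm_CC_1", [("RuBP", "Km_CC_1_RuBP"),
                                                    ("CO2", "Km_CC_1_CO2")],
                                        inhibitors=[("PGA", "Ki_CC_1_PGA"),
                                                    ("FBP", "Ki_CC_1_FBP"),
                                                    ("SBP", "Ki_CC_1_SBP")]),
                     modifiers=["PGA", "FBP", "SBP"],
                     name="RuBisCO carboxylation"),
        ReactionSpec("CC_2", {"PGA": -1.0, "ATP": -1.0, "BPGA": 1.0, "ADP": 1.0},
                     rl.MichaelisMenten("Vm_CC_2", [("PGA", "Km_CC_2_PGA"),
                                                    ("ATP", "Km_CC_2_ATP")]),
                     name="PGA kinase"),
        ReactionSpec("CC_3", {"BPGA": -1.0, "NADPH": -1.0, "GAP": 1.0,
                              "NADP": 1.0, "Pi": 1.0},
                     rl.MichaelisMenten("Vm_CC_3", [("BPGA", "Km_CC_3_BPGA"),
                                                    ("NADPH", "Km_CC_3_NADPH")]),
                     name="GAP dehydrogenase"),
        ReactionSpec("CC_4", {"GAP": -1.0, "DHAP": 1.0},
                     _rev("Vm_CC_4", [("GAP", "Km_CC_4_GAP")],
                          [("DHAP", "Km_CC_4_DHAP")], "Keq_CC_4"),
                     reversible=True, name="triose-phosphate isomerase"),
        ReactionSpec("CC_5", {"GAP": -1.0, "DHAP": -1.0, "FBP": 1.0},
                     _rev("Vm_CC_5", [("GAP", "Km_CC_5_GAP"), ("DHAP", "Km_CC_5_DHAP")],
                          [("FBP", "Km_CC_5_FBP")], "Keq_CC_5"),
                     reversible=True, name="FBP aldolase"),
        ReactionSpec("CC_6", {"FBP": -1.0, "F6P": 1.0, "Pi": 1.0},
                     rl.MichaelisMenten("Vm_CC_6", [("FBP", "Km_CC_6_FBP")]),
                     name="FBPase"),
        ReactionSpec("CC_7", {"F6P": -1.0, "GAP": -1.0, "E4P": 1.0, "Xu5P": 1.0},
                     rl.Transketolase("Vm10", "F6P", "GAP", "E4P", "Xu5P",
                                      "kM101", "kM104", keq="kE7",
                                      modifiers=list(tk_mod),
                                      modifier_mode=modifier_mode),
                     modifiers=["E4P", "Ri5P"], reversible=True,
                     name="transketolase (F6P)"),
        ReactionSpec("CC_8", {"E4P": -1.0, "DHAP": -1.0, "SBP": 1.0},
                     _rev("Vm_CC_8", [("E4P", "Km_CC_8_E4P"), ("DHAP", "Km_CC_8_DHAP")],
                          [("SBP", "Km_CC_8_SBP")], "Keq_CC_8"),
                     reversible=True, name="SBP aldolase"),
        ReactionSpec("CC_9", {"SBP": -1.0, "S7P": 1.0, "Pi": 1.0},
                     rl.MichaelisMenten("Vm_CC_9", [("SBP", "Km_CC_9_SBP")]),
                     name="SBPase"),
        ReactionSpec("CC_10", {"S7P": -1.0, "GAP": -1.0, "Ri5P": 1.0, "Xu5P": 1.0},
                     rl.Transketolase("Vm7", "S7P", "GAP", "Ri5P", "Xu5P",
                                      "kM71", "kM72", keq="kE7",
                                      modifiers=list(tk_mod),
                                      modifier_mode=modifier_mode),
                     modifiers=["E4P", "Ri5P"], reversible=True,
                     name="transketolase (S7P)"),
        ReactionSpec("CC_11", {"Ri5P": -1.0, "Ru5P": 1.0},
                     _rev("Vm_CC_11", [("Ri5P", "Km_CC_11_Ri5P")],
                          [("Ru5P", "Km_CC_11_Ru5P")], "Keq_CC_11"),
                     reversible=True, name="ribose-5-phosphate isomerase"),
        ReactionSpec("CC_12", {"Xu5P": -1.0, "Ru5P": 1.0},
                     _rev("Vm_CC_12", [("Xu5P", "Km_CC_12_Xu5P")],
                          [("Ru5P", "Km_CC_12_Ru5P")], "Keq_CC_12"),
                     reversible=True, name="ribulose-5-phosphate epimerase"),
        ReactionSpec("CC_13", {"Ru5P": -1.0, "ATP": -1.0, "RuBP": 1.0, "ADP": 1.0},
                     rl.MichaelisMenten("Vm_CC_13", [("Ru5P", "Km_CC_13_Ru5P"),
                                                     ("ATP", "Km_CC_13_ATP")]),
                     name="phosphoribulokinase (RuBP synthesis)"),
        ReactionSpec("SS_1", {"F6P": -1.0, "G6P": 1.0},
                     _rev("Vm_SS_1", [("F6P", "Km_SS_1_F6P")],
                          [("G6P", "Km_SS_1_G6P")], "Keq_SS_1"),
                     reversible=True, name="phosphoglucose isomerase"),
        ReactionSpec("SS_2", {"G6P": -1.0, "G1P": 1.0},
                     _rev("Vm_SS_2", [("G6P", "Km_SS_2_G6P")],
                          [("G1P", "Km_SS_2_G1P")], "Keq_SS_2"),
                     reversible=True, name="phosphoglucomutase"),
        ReactionSpec("SS_3", {"G1P": -1.0, "ATP": -1.0, "starch": 1.0,
                              "ADP": 1.0, "Pi": 2.0},
                     rl.MichaelisMenten("Vm_SS_3", [("G1P", "Km_SS_3_G1P"),
                                                    ("ATP", "Km_SS_3_ATP")]),
                     name="starch synthesis (ADP-glucose lump)"),
    ]
    return reactions


_TEMPLATE_KEQ = {
    # Keq = 3 * mass-action ratio at the design state (forward-driven)
    "Keq_CC_4": 15.0, "Keq_CC_5": 1.68, "Keq_CC_8": 4.8, "Keq_CC_11": 7.5,
    "Keq_CC_12": 3.6, "Keq_SS_1": 4.5, "Keq_SS_2": 0.2,
}

# the corrected transketolase constants the maximal rates are anchored to
_TK_DESIGN = {"kE7": 0.076, "kM71": 1.5, "kM72": 0.5, "kM101": 2.0,
              "kM104": 0.5, "kM102": 0.4, "kM103": 0.06}


def _sink_reaction(species: str, kinetics: str, fraction: float,
                   params: ParameterSet, design_state: Mapping[str, float]) -> ReactionSpec:
    """Build an export reaction SR_<species> carrying fraction*F at design."""
    rid = f"SR_{species}"
    target = fraction * REFERENCE_FLUX
    conc = design_state[species]
    if conc <= 0:
        conc = 1.0  # anchor for species starting empty (e.g. relay pools)
    stoich = {species: -1.0, f"SINK_{species}": 1.0}
    if _PHOSPHATES.get(species, 0) > 0:
        stoich["Pi"] = float(_PHOSPHATES[species])
    if kinetics == "MA":
        k = f"k_{rid}"
        params.set(k, target / conc, "1/s")
        law: rl.RateLaw = rl.MassAction(k, [(species, 1.0)])
    elif kinetics == "MMcb":
        # Km above the operating point: the sink responds near-linearly and
        # keeps capacity headroom (4x the design flux)
        vm, km = f"Vm_{rid}", f"Km_{rid}"
        params.set(km, 3.0 * conc, "mM")
        params.set(vm, 4.0 * target, "mM/s")
        law = rl.MichaelisMenten(vm, [(species, km)])
    elif kinetics == "MM":
        vm, km = f"Vm_{rid}", f"Km_{rid}"
        inhibitors = [("GAP", f"Ki_{rid}_GAP"), ("DHAP", f"Ki_{rid}_DHAP"),
                      ("Pi", f"Ki_{rid}_Pi")]
        params.set(km, conc, "mM")
        for isid, ki in inhibitors:
            params.set(ki, 2.0 * design_state[isid], "mM")
        law = rl.MichaelisMenten(vm, [(species, km)], inhibitors)
        params.set(vm, 1.0, "mM/s")
        val = law.evaluate(design_state, params)
        params.set(vm, target / val, "mM/s")
    else:
        raise ValueError(f"unknown sink kinetics {kinetics!r}")
    return ReactionSpec(rid, stoich, law, name=f"{species} sink ({kinetics})")


def _build_template(variant: str, sink_config: SinkConfig,
                    modifier_mode: str, lump: Optional[Tuple[float, float]],
                    tk_overrides: Mapping[str, float]) -> ModelSpec:
    include_pgca = lump is not None or "PGCA" in sink_config.sinks
    species = _template_species(include_pgca)
    params = ParameterSet()
    for name, v in _TK_DESIGN.items():
        params.set(name, v, "" if name == "kE7" else "mM")
    for name, v in _TEMPLATE_KEQ.items():
        params.set(name, v, "")
    params.set("adenylate_total", DESIGN_STATE["ATP"] + DESIGN_STATE["ADP"], "mM")
    params.set("f_oxygenation", PGCA_FLUX_FRACTION, "")

    reactions = _template_reactions(params, lump, modifier_mode)

    # Michaelis constants anchored at the design state; inhibition constants
    # at twice it (inhibition factor 1 + sum(conc/Ki) ~ 2.5 for RuBisCO)
    design = dict(DESIGN_STATE)
    for r in reactions:
        law = r.rate_law
        if isinstance(law, rl.MichaelisMenten):
            for sid, km in law.substrates:
                params.set(km, design[sid], "mM")
            for sid, ki in law.inhibitors:
                params.set(ki, 2.0 * design[sid], "mM")
        elif isinstance(law, rl.ReversibleMM):
            for sid, km in law.substrates + law.products:
                params.set(km, design[sid], "mM")

    # maximal rates solved so each reaction carries its design flux
    explicit = "DHAP" in sink_config.sinks
    fluxes = _design_fluxes(2.0 if lump is None else lump[0], explicit)
    for r in reactions:
        vmax_name = r.rate_law.vmax
        params.set(vmax_name, 1.0, "mM/s")
        val = r.rate_law.evaluate(design, params)
        target = fluxes[r.id] * REFERENCE_FLUX
        if val <= 0:
            raise RuntimeError(f"design state does not drive {r.id} forward")
        params.set(vmax_name, target / val, "mM/s")

    # export sinks
    sink_config.validate()
    for sid, (kin, frac) in sink_config.sinks.items():
        reactions.append(_sink_reaction(sid, kin, frac, params, design))
        species.append(SpeciesSpec(
            id=f"SINK_{sid}", name=f"{sid} export pool",
            initial_concentration=0.0, carbons=_CARBONS[sid], phosphates=0,
            accumulator=True))

    # the uncorrected transketolase constants where the variant asks for them
    for name, v in tk_overrides.items():
        params.set(name, v, params.unit(name) if name in params else "mM")

    model = ModelSpec(id=variant, species=species, reactions=reactions,
                      parameters=params, reference_flux_id="CC_13",
                      notes="fixture-parameterised Calvin-Benson network")
    model.append_lineage("build", {"variant": variant},
                         note="non-archival fixture parameterisation")
    return model


def build_model(variant: str, params: Optional[Mapping[str, float]] = None,
                sink_config: Optional[SinkConfig] = None) -> ModelSpec:
    """Build a named model variant.

    ``params`` overrides individual parameter values after construction
    (e.g. ``{"kM103": 0.015}``); ``sink_config`` replaces the variant's
    default sink layout (rejected where inconsistent with the variant).
    """
    if variant == "hahn":
        from .fixtures import toy_cycle_fixture
        model = toy_cycle_fixture()
        model.id = "hahn"
        model.lineage = []
        model.append_lineage("build", {"variant": "hahn"},
                             note="non-archival mass-action parameterisation")
        _apply_overrides(model, params)
        return model

    cfg = sink_config or default_sink_config(variant)
    if variant in ("cyano_C1", "cyano_D1"):
        extra = set(cfg.sinks) & set(MINOR_SINK_FRACTIONS)
        if extra:
            raise ValueError(
                f"{variant} folds the minor sinks into the PGA sink; explicit "
                f"sinks for {sorted(extra)} are inconsistent with it")
    if variant in ("zhu_A", "zhu_S"):
        mode = ("multiplicative_modifiers" if variant == "zhu_A"
                else "additive_modifiers")
        model = _build_template(variant, cfg, mode, lump=None,
                                tk_overrides={"kE7": 10.0, "kM103": 0.46})
    elif variant in ("cyano_C1", "cyano_C2"):
        model = _build_template(variant, cfg, "additive_modifiers", lump=None,
                                tk_overrides={})
    elif variant in ("cyano_D1", "cyano_D2"):
        lump = lumped_carboxylation_stoichiometry(PGCA_FLUX_FRACTION)
        model = _build_template(variant, cfg, "additive_modifiers", lump=lump,
                                tk_overrides={})
    else:
        raise ValueError(f"unknown variant {variant!r}")
    _apply_overrides(model, params)
    return model


def _apply_overrides(model: ModelSpec, params: Optional[Mapping[str, float]]) -> None:
    if not params:
        return
    for name, value in params.items():
        unit = model.parameters.unit(name) if name in model.parameters else ""
        model.parameters.set(name, value, unit)
    model.append_lineage("parameter_overrides", dict(params))


def perturbed_initial_state(model: ModelSpec) -> Dict[str, float]:
    """The out-of-steady-state starting point of the comparative analyses:
    the design concentrations with a fixed multiplicative perturbation."""
    state = model.initial_state()
    for sid, factor in _PERTURBATION.items():
        if sid in state:
            state[sid] *= factor
    return state


# --- patches -----------------------------------------------------------------

def configure_sink(model: ModelSpec, species: str = "PGA", kinetics: str = "MMcb",
                   params: Optional[Mapping[str, float]] = None) -> ModelSpec:
    """Replace the export reaction for ``species`` with the requested
    kinetics family, preserving its flux at the model's initial state."""
    if not model.has_species(species):
        raise KeyError(f"species {species!r} not in model")
    out = clone_model(model)
    rid = f"SR_{species}"
    state = out.initial_state()
    try:
        old = out.get_reaction(rid)
        target = old.rate_law.evaluate(state, out.parameters)
        out.reactions = [r for r in out.reactions if r.id != rid]
    except KeyError:
        target = 0.05 * REFERENCE_FLUX
    if not any(s.id == f"SINK_{species}" for s in out.species):
        out.species.append(SpeciesSpec(
            id=f"SINK_{species}", name=f"{species} export pool",
            initial_concentration=0.0,
            carbons=_CARBONS.get(species), phosphates=0, accumulator=True))
    new = _sink_reaction(species, kinetics, target / REFERENCE_FLUX,
                         out.parameters, state)
    if params:
        for name, value in params.items():
            out.parameters.set(name, value,
                               out.parameters.unit(name) if name in out.parameters else "")
    out.reactions.append(new)
    out.append_lineage("sink_impl", {"species": species, "kinetics": kinetics,
                                     **(dict(params) if params else {})})
    return out


def _find_tk_laws(model: ModelSpec) -> List[ReactionSpec]:
    return [r for r in model.reactions if isinstance(r.rate_law, rl.Transketolase)]


def apply_patch(model: ModelSpec, patch: PatchDescriptor) -> ModelSpec:
    """Apply a named correction; only the targeted reactions/parameters
    change, the prior values are recorded in the lineage entry."""
    name, args = patch.name, dict(patch.arguments)
    out = clone_model(model)
    prior: Dict[str, object] = {}

    if name in ("set_kE7", "set_kM103"):
        pname = name[4:]
        value = float(args["value"])
        prior[pname] = out.parameters.get(pname) if pname in out.parameters else None
        out.parameters.set(pname, value, "" if pname == "kE7" else "mM")

    elif name == "tk_modifier_mode":
        mode = args["mode"]
        if mode not in ("additive_modifiers", "multiplicative_modifiers"):
            raise ValueError(f"unknown modifier mode {mode!r}")
        laws = _find_tk_laws(out)
        if not laws:
            raise KeyError("no transketolase reaction in model")
        prior["modes"] = {r.id: r.rate_law.modifier_mode for r in laws}
        for r in laws:
            r.rate_law.modifier_mode = mode

    elif name == "starch_fix":
        targets = [r for r in out.reactions
                   if isinstance(r.rate_law, rl.StarchPhosphorylase)]
        if not targets:
            raise KeyError("no starch-phosphorylase reaction in model")
        prior["variants"] = {r.id: r.rate_law.variant for r in targets}
        for r in targets:
            r.rate_law.variant = "corrected"

    elif name == "lump_oxygenation":
        f = float(args.get("f", out.parameters.get("f_oxygenation")
                  if "f_oxygenation" in out.parameters else PGCA_FLUX_FRACTION))
        a, b = lumped_carboxylation_stoichiometry(f)
        carbox = out.get_reaction("CC_1")
        prior["stoichiometry"] = dict(carbox.stoichiometry)
        had_ox = any(r.id == "CC_1ox" for r in out.reactions)
        if had_ox:
            vmax = carbox.rate_law.vmax
            prior["carbox_vmax"] = out.parameters.get(vmax)
            out.parameters.set(vmax, out.parameters.get(vmax) / (1.0 - b), "mM/s")
            out.reactions = [r for r in out.reactions if r.id != "CC_1ox"]
        _ensure_pgca(out)
        carbox = out.get_reaction("CC_1")
        carbox.stoichiometry = {"RuBP": -1.0, "CO2": -1.0, "PGA": a, "PGCA": b}
        out.parameters.set("f_oxygenation", f, "")

    elif name == "split_oxygenation":
        from .simulate import find_steady_state
        carbox = out.get_reaction("CC_1")
        b = carbox.stoichiometry.get("PGCA", 0.0)
        if b <= 0:
            raise KeyError("split_oxygenation requires a lumped carboxylation")
        ss = find_steady_state(out)
        v_l = ss.fluxes["CC_1"]
        prior["stoichiometry"] = dict(carbox.stoichiometry)
        vmax = carbox.rate_law.vmax
        prior["carbox_vmax"] = out.parameters.get(vmax)
        carbox.stoichiometry = {"RuBP": -1.0, "CO2": -1.0, "PGA": 2.0}
        out.parameters.set(vmax, out.parameters.get(vmax) * (1.0 - b), "mM/s")
        ox_law = rl.Oxygenase()
        for pname, v in (("Ko", 0.5), ("Kc", 0.2), ("Kr", 2.0), ("KI11", 10.0),
                         ("KI12", 2.0), ("KI13", 2.0), ("KI14", 10.0), ("KI15", 2.0)):
            if pname not in out.parameters:
                out.parameters.set(pname, v, "mM")
        out.parameters.set("Vo", 1.0, "mM/s")
        val = ox_law.evaluate(ss.state, out.parameters)
        out.parameters.set("Vo", b * v_l / val, "mM/s")
        out.reactions.append(ReactionSpec(
            "CC_1ox", {"RuBP": -1.0, "O2": -1.0, "PGA": 1.0, "PGCA": 1.0},
            ox_law, name="RuBisCO oxygenation"))

    elif name == "add_relay_sink":
        kin = args.get("kinetics", "MMcb")
        target_sp = args.get("species", "PGAc" if model.has_species("PGAc") else "PGA")
        return configure_sink(out, target_sp, kin)

    elif name == "sink_impl":
        return configure_sink(out, args.get("species", "PGA"),
                              args.get("kinetics", "MMcb"))

    else:
        raise ValueError(f"unknown patch {name!r}")

    out.append_lineage(name, args, note=patch.provenance or "")
    out.lineage[-1]["prior"] = prior
    return out


def _ensure_pgca(model: ModelSpec) -> None:
    if not model.has_species("PGCA"):
        model.species.append(SpeciesSpec(
            id="PGCA", name="2-phosphoglycolate",
            initial_concentration=DESIGN_STATE["PGCA"],
            carbons=_CARBONS["PGCA"], phosphates=_PHOSPHATES["PGCA"]))
    if not any(r.id == "SR_PGCA" for r in model.reactions):
        if not any(s.id == "SINK_PGCA" for s in model.species):
            model.species.append(SpeciesSpec(
                id="SINK_PGCA", name="PGCA export pool", initial_concentration=0.0,
                carbons=_CARBONS["PGCA"], phosphates=0, accumulator=True))
        model.reactions.append(_sink_reaction(
            "PGCA", "MMcb", 2 * PGCA_FLUX_FRACTION, model.parameters,
            dict(DESIGN_STATE)))


def rebuild_from_lineage(model: ModelSpec) -> ModelSpec:
    """Reconstruct a model from (base variant, recorded patches) alone."""
    if not model.lineage or model.lineage[0]["name"] != "build":
        raise ValueError("model lineage does not start with a build record")
    base_args = model.lineage[0]["arguments"]
    out = build_model(base_args["variant"])
    for entry in model.lineage[1:]:
        name, args = entry["name"], entry.get("arguments", {})
        if name == "parameter_overrides":
            _apply_overrides(out, args)
        elif name == "match_flux":
            from .simulate import _with_scaled_knobs
            out = _with_scaled_knobs(out, args.get("knobs", []), args["scale"]) \
                if args.get("knobs") else out
            out.append_lineage("match_flux", dict(args))
        else:
            out = apply_patch(out, PatchDescriptor(name, dict(args)))
    return out
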