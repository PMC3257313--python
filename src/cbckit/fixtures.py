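"""Synthetic fixture networks with known analytic behavior.

These small models exist so that every simulator and analysis operation is
exercisable without any external model file:

* ``linear_chain_fixture`` — source -> X1 -> ... -> Xn -> sink with mass
  action steps; the steady state is x_i* = J / k_i in closed form.
* ``toy_cycle_fixture`` — a miniature autocatalytic Calvin analogue:
  a 5-carbon acceptor consumed by a carboxylation-like step that the cycle
  regenerates, ATP-coupled steps with finite adenylate and phosphate pools,
  and a triose-like export sink.  Its parameters are solved from a designed
  steady state, so the fixture has a known answer; shrinking or unclamping
  the external phosphate pool reproduces the phosphate-depletion /
  cycle-suspension behavior class.
* ``calvin_mini_fixture`` — the toy cycle plus a starch branch carrying a
  starch-phosphorylase degradation law in either the corrected or the
  defective (``original``) variant, which degrades non-existent starch and
  drives its concentration negative.
* ``translocator_fixture`` — a two-compartment PGA export fixture around
  the phosphate-translocator law, with or without the stabilising relay
  sink.
* ``pga_ec_fixture`` — a 2-species fixture whose PGA-like steady state is
  exactly proportional to 1/energy-charge.

Fixtures claim known answers, not biological realism.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from . import rate_laws as rl
from .model_core import ModelSpec, ParameterSet, ReactionSpec, SpeciesSpec

__all__ = [
    "linear_chain_fixture", "toy_cycle_fixture", "calvin_mini_fixture",
    "translocator_fixture", "pga_ec_fixture", "physiological_parameter_table",
]


def linear_chain_fixture(n: int = 3, input_flux: float = 1.0,
                         rate_constants: Optional[Sequence[float]] = None,
                         seed: int = 0) -> ModelSpec:
    """source -> X1 -> ... -> Xn -> sink, all mass action.

    Analytic steady state: x_i* = input_flux / k_i.  Without
    ``rate_constants`` the k_i are drawn log-uniformly from [0.2, 5] with the
    given seed (identical seed, identical model).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rate_constants is None:
        rng = np.random.default_rng(seed)
        rate_constants = list(np.exp(rng.uniform(np.log(0.2), np.log(5.0), n)))
    if len(rate_constants) != n or any(k < 0 for k in rate_constants):
        raise ValueError("need n non-negative rate constants")

    params = ParameterSet()
    params.set("J", input_flux, "mM/s")
    species = [SpeciesSpec("SRC", "source", initial_concentration=1.0, clamped=True,
                           carbons=1, phosphates=0)]
    reactions = [ReactionSpec("input", {"SRC": -1.0, "X1": 1.0},
                              rl.MassAction("J", [("SRC", 1.0)]))]
    for i in range(1, n + 1):
        species.append(SpeciesSpec(f"X{i}", initial_concentration=0.0,
                                   carbons=1, phosphates=0))
        kname = f"k{i}"
        params.set(kname, float(rate_constants[i - 1]), "1/s")
        product = f"X{i + 1}" if i < n else "SINK"
        reactions.append(ReactionSpec(f"step{i}", {f"X{i}": -1.0, product: 1.0},
                                      rl.MassAction(kname, [(f"X{i}", 1.0)])))
    species.append(SpeciesSpec("SINK", "sink pool", initial_concentration=0.0,
                               carbons=1, phosphates=0, accumulator=True))
    model = ModelSpec("linear_chain", species, reactions, params,
                      reference_flux_id="input")
    model.append_lineage("build", {"variant": "linear_chain", "n": n,
                                   "input_flux": input_flux, "seed": seed})
    return model


# designed steady state of the toy cycle (mM)
_TOY_DESIGN = {"RuBP": 1.0, "PGA": 2.0, "TP": 1.5, "Ru5P": 0.5,
               "ATP": 1.0, "ADP": 0.5, "Pi": 2.0, "Pi_ext": 10.0, "CO2": 1.0}
_TOY_FLUX = 0.1  # mM/s carboxylation flux at design


def toy_cycle_fixture(seed: int = 0, phosphate_pool_scale: float = 1.0,
                      clamp_external_phosphate: bool = True,
                      with_sink: bool = True,
                      jitter: float = 0.0) -> ModelSpec:
    """Miniature autocatalytic Calvin analogue.

    Species: RuBP-like acceptor, PGA-like product, triose-like pool TP,
    Ru5P-like regeneration intermediate, adenylates, free stromal phosphate
    and an external phosphate pool.  Reactions::

        carbox:   RuBP + CO2        -> 2 PGA               (mass action)
        reduce:   PGA + ATP         -> TP + ADP + Pi       (MM, PGA-saturated)
        regen:    TP                -> 0.6 Ru5P + 0.4 Pi   (MM, TP-saturated)
        prk:      Ru5P + ATP        -> RuBP + ADP          (mass action)
        export:   TP                -> TP_ext              (MM in TP; the
                  exported triose keeps its phosphate)
        pga_leak: PGA               -> PGA_waste           (first order)
        import:   Pi_ext            -> Pi                  (first order)
        synthase: ADP + Pi          -> ATP                 (mass action)
        upkeep:   ATP               -> ADP + Pi            (first order)

    Rate constants are solved so the designed concentrations are a steady
    state; ``jitter > 0`` multiplies each constant by a seeded log-normal
    factor (distinct seeds give distinct draws).  Two design constraints
    shape the kinetics: the first-order PGA drain and ATP upkeep pin the
    steady state to an isolated point (all-bilinear variants of this cycle
    carry flux-preserving degeneracy manifolds along which ATP trades
    against its co-substrates), and the biosynthetic steps run
    substrate-saturated while the drains are near-linear, so the
    autocatalytic gain exceeds one at low concentrations and the cycle
    recovers from an acceptor knockout when energy supply holds.  With the
    external phosphate clamped the cycle is stable; with a finite
    (unclamped) pool the exports sequester phosphate until ATP synthesis
    stalls and the cycle suspends.  ``with_sink=False`` removes the
    exports, which makes the PGA-like pool grow without bound.
    """
    d = dict(_TOY_DESIGN)
    d["Pi_ext"] *= phosphate_pool_scale
    f = _TOY_FLUX

    upkeep = 0.05 * f   # maintenance ATP turnover
    leak = 0.1 * f      # direct PGA drain
    export = 2 * f - leak - (5 * f / 3)  # triose left for export
    km_r_pga = d["PGA"] / 3.0   # reduction 75% saturated in PGA
    km_r_atp = d["ATP"]         # half-saturated in ATP
    km_regen = d["TP"] / 3.0    # regeneration 75% saturated
    sat = lambda s, km: s / (s + km)
    k = {
        "k_carbox": f / (d["RuBP"] * d["CO2"]),
        "Vm_reduce": (2 * f - leak) / (sat(d["PGA"], km_r_pga)
                                       * sat(d["ATP"], km_r_atp)),
        "Km_reduce_PGA": km_r_pga,
        "Km_reduce_ATP": km_r_atp,
        "Vm_regen": (5 * f / 3) / sat(d["TP"], km_regen),
        "Km_regen": km_regen,
        "k_prk": f / (d["Ru5P"] * d["ATP"]),
        "Vm_export": 2 * export,  # Km_export = design TP: half-saturated
        "Km_export": d["TP"],
        "k_pga_leak": leak / d["PGA"],
        "k_import": (export + leak) / d["Pi_ext"],
        "k_synthase": (2 * f - leak + f + upkeep) / (d["ADP"] * d["Pi"]),
        "k_upkeep": upkeep / d["ATP"],
    }
    if jitter > 0:
        rng = np.random.default_rng(seed)
        for name in k:
            if not name.startswith("Km"):
                k[name] *= float(np.exp(rng.normal(0.0, jitter)))

    params = ParameterSet()
    units = {"k_upkeep": "1/s", "k_import": "1/s", "k_pga_leak": "1/s",
             "Vm_export": "mM/s", "Vm_reduce": "mM/s", "Vm_regen": "mM/s",
             "Km_export": "mM", "Km_reduce_PGA": "mM", "Km_reduce_ATP": "mM",
             "Km_regen": "mM"}
    for name, v in k.items():
        params.set(name, v, units.get(name, "1/(mM*s)"))
    params.set("adenylate_total", d["ATP"] + d["ADP"], "mM")

    def sp(sid, carbons, phosphates, clamped=False, accumulator=False):
        return SpeciesSpec(sid, sid, initial_concentration=d.get(sid, 0.0),
                           carbons=carbons, phosphates=phosphates,
                           clamped=clamped, accumulator=accumulator)

    species = [
        sp("RuBP", 5, 2), sp("PGA", 3, 1), sp("TP", 3, 1), sp("Ru5P", 5, 1),
        sp("ATP", 0, 3), sp("ADP", 0, 2), sp("Pi", 0, 1),
        sp("Pi_ext", 0, 1, clamped=clamp_external_phosphate),
        sp("CO2", 1, 0, clamped=True),
        SpeciesSpec("TP_ext", "exported triose", initial_concentration=0.0,
                    carbons=3, phosphates=1, accumulator=True),
        SpeciesSpec("PGA_waste", "drained PGA", initial_concentration=0.0,
                    carbons=3, phosphates=1, accumulator=True),
    ]
    reactions = [
        ReactionSpec("carbox", {"RuBP": -1.0, "CO2": -1.0, "PGA": 2.0},
                     rl.MassAction("k_carbox", [("RuBP", 1.0), ("CO2", 1.0)])),
        ReactionSpec("reduce", {"PGA": -1.0, "ATP": -1.0, "TP": 1.0,
                                "ADP": 1.0, "Pi": 1.0},
                     rl.MichaelisMenten("Vm_reduce", [("PGA", "Km_reduce_PGA"),
                                                      ("ATP", "Km_reduce_ATP")])),
        ReactionSpec("regen", {"TP": -1.0, "Ru5P": 0.6, "Pi": 0.4},
                     rl.MichaelisMenten("Vm_regen", [("TP", "Km_regen")])),
        ReactionSpec("prk", {"Ru5P": -1.0, "ATP": -1.0, "RuBP": 1.0, "ADP": 1.0},
                     rl.MassAction("k_prk", [("Ru5P", 1.0), ("ATP", 1.0)])),
        ReactionSpec("import", {"Pi_ext": -1.0, "Pi": 1.0},
                     rl.MassAction("k_import", [("Pi_ext", 1.0)])),
        ReactionSpec("synthase", {"ADP": -1.0, "Pi": -1.0, "ATP": 1.0},
                     rl.MassAction("k_synthase", [("ADP", 1.0), ("Pi", 1.0)])),
        ReactionSpec("upkeep", {"ATP": -1.0, "ADP": 1.0, "Pi": 1.0},
                     rl.MassAction("k_upkeep", [("ATP", 1.0)])),
    ]
    if with_sink:
        reactions.insert(4, ReactionSpec(
            "export", {"TP": -1.0, "TP_ext": 1.0},
            rl.MichaelisMenten("Vm_export", [("TP", "Km_export")])))
        reactions.insert(5, ReactionSpec(
            "pga_leak", {"PGA": -1.0, "PGA_waste": 1.0},
            rl.MassAction("k_pga_leak", [("PGA", 1.0)])))

    model = ModelSpec("toy_cycle", species, reactions, params,
                      reference_flux_id="prk")
    model.append_lineage("build", {"variant": "toy_cycle", "seed": seed,
                                   "phosphate_pool_scale": phosphate_pool_scale,
                                   "clamp_external_phosphate": clamp_external_phosphate,
                                   "with_sink": with_sink})
    return model


def calvin_mini_fixture(seed: int = 0, starch_variant: str = "corrected",
                        clamp_external_phosphate: bool = True) -> ModelSpec:
    """Toy cycle extended by a starch branch with a switchable
    starch-phosphorylase law.

    Branch reactions::

        g1p_syn:  TP          -> 0.5 G1P + 0.5 Pi
        st_syn:   G1P + ATP   -> starch + ADP + 2 Pi
        st_deg:   starch + Pi -> G1P          (StarchPhosphorylase law)
        g1p_out:  G1P         -> G1P_ext + Pi

    With ``starch_variant="original"`` degradation keeps running at zero
    starch (the substrate slot holds free phosphate) and the starch
    concentration goes negative; the model is flagged diagnostic so that the
    pathology is representable.
    """
    if starch_variant not in ("corrected", "original"):
        raise ValueError(f"unknown starch variant {starch_variant!r}")
    model = toy_cycle_fixture(seed=seed,
                              clamp_external_phosphate=clamp_external_phosphate)
    model.id = "calvin_mini"
    model.lineage = []
    model.append_lineage("build", {"variant": "calvin_mini", "seed": seed,
                                   "starch_variant": starch_variant,
                                   "clamp_external_phosphate": clamp_external_phosphate})

    d = dict(_TOY_DESIGN, G1P=0.5, starch=0.05)
    p = model.parameters
    v_branch = 0.02 * _TOY_FLUX  # small diversion from the triose pool
    p.set("k_g1p_syn", v_branch / d["TP"], "1/s")
    p.set("k_st_syn", 0.25 * v_branch / (d["G1P"] * d["ATP"]), "1/(mM*s)")
    p.set("k_g1p_out", 0.75 * v_branch / d["G1P"], "1/s")
    p.set("StPase_VM", 0.5 * v_branch, "mM/s")
    p.set("StPase_km", 1.0, "mM")
    p.set("StPase_kiG1P", 1.0, "mM")

    model.species.extend([
        SpeciesSpec("G1P", "G1P-like hexose", initial_concentration=d["G1P"],
                    carbons=6, phosphates=1),
        SpeciesSpec("starch", "starch pool", initial_concentration=d["starch"],
                    carbons=6, phosphates=0),
        SpeciesSpec("G1P_ext", "exported hexose", initial_concentration=0.0,
                    carbons=6, phosphates=0, accumulator=True),
    ])
    model.reactions.extend([
        ReactionSpec("g1p_syn", {"TP": -1.0, "G1P": 0.5, "Pi": 0.5},
                     rl.MassAction("k_g1p_syn", [("TP", 1.0)])),
        ReactionSpec("st_syn", {"G1P": -1.0, "ATP": -1.0, "starch": 1.0,
                                "ADP": 1.0, "Pi": 2.0},
                     rl.MassAction("k_st_syn", [("G1P", 1.0), ("ATP", 1.0)])),
        ReactionSpec("st_deg", {"starch": -1.0, "Pi": -1.0, "G1P": 1.0},
                     rl.StarchPhosphorylase(variant=starch_variant)),
        ReactionSpec("g1p_out", {"G1P": -1.0, "G1P_ext": 1.0, "Pi": 1.0},
                     rl.MassAction("k_g1p_out", [("G1P", 1.0)])),
    ])
    if starch_variant == "original":
        model.diagnostic_mode = True
    return model


def translocator_fixture(with_relay_sink: bool = False, source_flux: float = 0.05,
                         vm11: float = 1.0) -> ModelSpec:
    """Stroma/cytosol PGA export through the phosphate-translocator law.

    A constant source produces stromal PGA; the translocator exchanges it
    with the cytosolic pool.  Without the relay sink the cytosolic (and then
    the stromal) PGA accumulates without bound; ``with_relay_sink=True``
    adds PGA_cyt -> sink and the system has a steady state whose export flux
    equals the source flux regardless of Vm11.
    """
    params = ParameterSet()
    params.set("J", source_flux, "mM/s")
    params.set("Vm11", vm11, "mM/s")
    for name in ("KmOP", "KmPGA", "KmT3P", "KmOPc", "KmPGAc", "KmT3Pc"):
        params.set(name, 1.0, "mM")

    def sp(sid, conc, clamped=False, accumulator=False, compartment="stroma"):
        return SpeciesSpec(sid, sid, compartment=compartment,
                           initial_concentration=conc, carbons=3 if "PGA" in sid else 0,
                           phosphates=1, clamped=clamped, accumulator=accumulator)

    species = [
        sp("SRC", 1.0, clamped=True),
        sp("PGA", 1.0), sp("OP", 2.0, clamped=True),
        sp("GAP", 0.3, clamped=True), sp("DHAP", 0.5, clamped=True),
        sp("PGAc", 0.2, compartment="cytosol"),
        sp("OPc", 2.0, clamped=True, compartment="cytosol"),
        sp("GAPc", 0.3, clamped=True, compartment="cytosol"),
        sp("DHAPc", 0.5, clamped=True, compartment="cytosol"),
        SpeciesSpec("SINK_PGAc", "PGA sink pool", initial_concentration=0.0,
                    carbons=3, phosphates=0, accumulator=True),
    ]
    reactions = [
        ReactionSpec("source", {"SRC": -1.0, "PGA": 1.0},
                     rl.MassAction("J", [("SRC", 1.0)])),
        ReactionSpec("translocator", {"PGA": -1.0, "PGAc": 1.0},
                     rl.Translocator(), reversible=True),
    ]
    if with_relay_sink:
        params.set("Vm_relay", 4 * source_flux, "mM/s")
        params.set("Km_relay", 1.0, "mM")
        reactions.append(ReactionSpec(
            "SR_PGAc", {"PGAc": -1.0, "SINK_PGAc": 1.0},
            rl.MichaelisMenten("Vm_relay", [("PGAc", "Km_relay")])))
    model = ModelSpec("translocator_fixture", species, reactions, params,
                      reference_flux_id="source")
    model.append_lineage("build", {"variant": "translocator_fixture",
                                   "with_relay_sink": with_relay_sink,
                                   "source_flux": source_flux, "vm11": vm11})
    return model


def pga_ec_fixture(input_flux: float = 0.1, k: float = 0.2,
                   adenylate_total: float = 2.0) -> ModelSpec:
    """Source -> P; P + ATP -> out.  Steady P* = J / (k * ec * total): the
    PGA-like pool is exactly inversely proportional to the energy charge."""
    params = ParameterSet()
    params.set("J", input_flux, "mM/s")
    params.set("k", k, "1/(mM*s)")
    params.set("adenylate_total", adenylate_total, "mM")
    species = [
        SpeciesSpec("SRC", initial_concentration=1.0, clamped=True, carbons=3,
                    phosphates=0),
        SpeciesSpec("PGA", initial_concentration=1.0, carbons=3, phosphates=1),
        SpeciesSpec("ATP", initial_concentration=1.0, carbons=0, phosphates=3,
                    clamped=True),
        SpeciesSpec("ADP", initial_concentration=1.0, carbons=0, phosphates=2,
                    clamped=True),
        SpeciesSpec("OUT", initial_concentration=0.0, carbons=3, phosphates=0,
                    accumulator=True),
    ]
    reactions = [
        ReactionSpec("source", {"SRC": -1.0, "PGA": 1.0},
                     rl.MassAction("J", [("SRC", 1.0)])),
        ReactionSpec("consume", {"PGA": -1.0, "OUT": 1.0},
                     rl.MassAction("k", [("PGA", 1.0), ("ATP", 1.0)])),
    ]
    model = ModelSpec("pga_ec_fixture", species, reactions, params,
                      reference_flux_id="source")
    model.append_lineage("build", {"variant": "pga_ec_fixture"})
    return model


def physiological_parameter_table() -> Dict[str, dict]:
    """Reference ranges and literature values used by validation warnings and
    the energy-charge scan flags."""
    return {
        "PGA": {"range_mM": (2.15, 11.7),
                "note": "reported steady-state chloroplast PGA range"},
        "kE7": {"literature_values": (0.076, 0.1),
                "note": "transketolase equilibrium constant; 10 is the "
                        "uncorrected model value"},
        "kM103": {"values_mM": (0.015, 0.06, 0.46),
                  "note": "0.015 original, >= 0.06 needed for stability of the "
                          "appendix-form network, 0.46 transaldolase-derived"},
        "transketolase_vmax": {"proposed_mmol_per_s": 0.1,
                               "measured_mmol_per_s": 0.36,
                               "note": "plausibility ceiling for transketolase flux"},
        "poolman_tk_rate_constant": {"value": 5e8, "unit": "l/(mmol*s)",
                                     "note": "fast-equilibrium rate constant in "
                                             "the repository model"},
    }
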