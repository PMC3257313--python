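"""Native structured-text (YAML) serialization of models.

One document per model: species, reactions (with tagged rate laws),
parameters, lineage.  The dump is canonical (stable key order, full-precision
floats) so that serialize -> parse -> serialize is bit-stable, which is what
makes lineage-based model reconstruction checkable.
"""

from __future__ import annotations

from typing import Dict, List

import yaml

from . import rate_laws as rl
from .expr import parse_expression, to_text
from .model_core import ModelSpec, Parameter, ParameterSet, ReactionSpec, SpeciesSpec

__all__ = ["model_to_dict", "model_from_dict", "to_yaml", "from_yaml",
           "save_model", "load_model", "clone_model", "models_equal"]


def _law_to_dict(law: rl.RateLaw) -> dict:
    d: dict = {"family": law.family}
    if isinstance(law, rl.MassAction):
        d.update(k=law.k, reactants=[list(t) for t in law.reactants],
                 products=[list(t) for t in law.products], keq=law.keq)
    elif isinstance(law, rl.MichaelisMenten):
        d.update(vmax=law.vmax, substrates=[list(t) for t in law.substrates],
                 inhibitors=[list(t) for t in law.inhibitors])
    elif isinstance(law, rl.ReversibleMM):
        d.update(vmax=law.vmax, substrates=[list(t) for t in law.substrates],
                 products=[list(t) for t in law.products], keq=law.keq)
    elif isinstance(law, rl.Transketolase):
        d.update(vmax=law.vmax, s1=law.s1, s2=law.s2, p1=law.p1, p2=law.p2,
                 km_s1=law.km_s1, km_s2=law.km_s2, keq=law.keq,
                 modifiers=[list(t) for t in law.modifiers],
                 modifier_mode=law.modifier_mode)
    elif isinstance(law, rl.Translocator):
        d.update(vmax=law.vmax, species=dict(law.species))
    elif isinstance(law, rl.Oxygenase):
        d.update(vmax=law.vmax, species=dict(law.species))
    elif isinstance(law, rl.StarchPhosphorylase):
        d.update(variant=law.variant, vmax=law.vmax, km=law.km,
                 ki_g1p=law.ki_g1p, starch=law.starch, pi=law.pi, g1p=law.g1p)
    elif isinstance(law, rl.GenericExpression):
        d.update(expression=to_text(law.expression),
                 parameters=list(law.parameters), species=list(law.species))
    else:  # pragma: no cover
        raise TypeError(f"unknown rate-law type {type(law)!r}")
    return d


def _law_from_dict(d: dict) -> rl.RateLaw:
    fam = d["family"]
    if fam == "mass_action":
        return rl.MassAction(d["k"], [tuple(t) for t in d["reactants"]],
                             [tuple(t) for t in d.get("products", [])],
                             d.get("keq"))
    if fam == "michaelis_menten":
        return rl.MichaelisMenten(d["vmax"], [tuple(t) for t in d["substrates"]],
                                  [tuple(t) for t in d.get("inhibitors", [])])
    if fam == "reversible_mm":
        return rl.ReversibleMM(d["vmax"], [tuple(t) for t in d["substrates"]],
                               [tuple(t) for t in d["products"]], d["keq"])
    if fam == "transketolase":
        return rl.Transketolase(d["vmax"], d["s1"], d["s2"], d["p1"], d["p2"],
                                d["km_s1"], d["km_s2"], d.get("keq", "kE7"),
                                [tuple(t) for t in d.get("modifiers", [])],
                                d.get("modifier_mode", "additive_modifiers"))
    if fam == "translocator":
        return rl.Translocator(d.get("vmax", "Vm11"), dict(d["species"]))
    if fam == "oxygenase":
        return rl.Oxygenase(d.get("vmax", "Vo"), dict(d["species"]))
    if fam == "starch_phosphorylase":
        return rl.StarchPhosphorylase(d.get("variant", "corrected"),
                                      d.get("vmax", "StPase_VM"),
                                      d.get("km", "StPase_km"),
                                      d.get("ki_g1p", "StPase_kiG1P"),
                                      d.get("starch", "starch"),
                                      d.get("pi", "Pi"), d.get("g1p", "G1P"))
    if fam == "generic_expression":
        return rl.GenericExpression(parse_expression(d["expression"]),
                                    list(d.get("parameters", [])),
                                    list(d.get("species", [])))
    raise ValueError(f"unknown rate-law family {fam!r}")


def model_to_dict(model: ModelSpec) -> dict:
    return {
        "id": model.id,
        "compartment_volume_l": model.compartment_volume_l,
        "diagnostic_mode": model.diagnostic_mode,
        "reference_flux_id": model.reference_flux_id,
        "notes": model.notes,
        "species": [
            {"id": s.id, "name": s.name, "compartment": s.compartment,
             "initial_concentration": s.initial_concentration,
             "carbons": s.carbons, "phosphates": s.phosphates,
             "clamped": s.clamped, "accumulator": s.accumulator}
            for s in model.species],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
             "modifiers": list(r.modifiers), "reversible": r.reversible,
             "rate_law": _law_to_dict(r.rate_law)}
            for r in model.reactions],
        "parameters": {name: {"value": p.value, "unit": p.unit}
                       for name, p in sorted(model.parameters.items())},
        "lineage": [dict(e) for e in model.lineage],
    }


def model_from_dict(d: dict) -> ModelSpec:
    species = [SpeciesSpec(**s) for s in d["species"]]
    reactions = [ReactionSpec(id=r["id"], stoichiometry=dict(r["stoichiometry"]),
                              rate_law=_law_from_dict(r["rate_law"]),
                              modifiers=list(r.get("modifiers", [])),
                              reversible=r.get("reversible", False),
                              name=r.get("name", ""))
                 for r in d["reactions"]]
    params = ParameterSet({name: Parameter(v["value"], v.get("unit", ""))
                           for name, v in d.get("parameters", {}).items()})
    return ModelSpec(id=d["id"], species=species, reactions=reactions,
                     parameters=params, lineage=[dict(e) for e in d.get("lineage", [])],
                     compartment_volume_l=d.get("compartment_volume_l", 1.0),
                     diagnostic_mode=d.get("diagnostic_mode", False),
                     reference_flux_id=d.get("reference_flux_id"),
                     notes=d.get("notes", ""))


def to_yaml(model: ModelSpec) -> str:
    return yaml.safe_dump(model_to_dict(model), sort_keys=False,
                          default_flow_style=False)


def from_yaml(text: str) -> ModelSpec:
    return model_from_dict(yaml.safe_load(text))


def save_model(model: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_yaml(model))


def load_model(path) -> ModelSpec:
    with open(path) as fh:
        return from_yaml(fh.read())


def clone_model(model: ModelSpec) -> ModelSpec:
    """Deep copy through the serialized form (guarantees the copy only holds
    what serialization preserves)."""
    return model_from_dict(model_to_dict(model))


def models_equal(a: ModelSpec, b: ModelSpec, ignore_lineage: bool = False) -> bool:
    """Structural equality through the canonical dict form."""
    da, db = model_to_dict(a), model_to_dict(b)
    if ignore_lineage:
        da.pop("lineage")
        db.pop("lineage")
    return da == db
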