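"""SBML Level 2 read/write for the model library.

The exchange dialect is SBML L2V4 with content MathML kinetic laws.  The
writer emits every rate law as explicit MathML plus a small annotation (own
namespace) carrying the structured rate-law description and model lineage,
so that a round trip restores the exact internal representation.  The
reader accepts Level 2 versions 1-4 from any source: boundary/constant
species map to clamped species, kinetic-law math becomes a generic
expression tree unless it matches a named family structurally or an
annotation tags it, and reaction-local parameters are namespaced as
``<reaction id>_<parameter id>``.

Unsupported constructs (events, algebraic/rate rules) are rejected and
reported.  Units: concentrations are taken as mM and time as s; documents
without unit definitions are imported with a warning note in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml
from lxml import etree

from . import expr as ex
from . import rate_laws as rl
from .model_core import ModelSpec, Parameter, ParameterSet, ReactionSpec, SpeciesSpec
from .serialize import _law_from_dict, _law_to_dict, model_to_dict

__all__ = ["ImportReport", "read_sbml", "write_sbml", "read_sbml_file",
           "write_sbml_file"]

SBML_L2 = "http://www.sbml.org/sbml/level2"
SBML_L2V = {1: SBML_L2, 2: SBML_L2 + "/version2", 3: SBML_L2 + "/version3",
            4: SBML_L2 + "/version4"}
MATHML = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "https://cbckit.invalid/sbml-annotations"


@dataclass
class ImportReport:
    species_mapped: int = 0
    clamped_species: List[str] = field(default_factory=list)
    named_family_laws: Dict[str, str] = field(default_factory=dict)
    generic_laws: List[str] = field(default_factory=list)
    local_parameters: Dict[str, List[str]] = field(default_factory=dict)
    unit_notes: List[str] = field(default_factory=list)
    unresolved: List[str] = field(default_factory=list)


# --- MathML ------------------------------------------------------------------

_MATHML_OPS = {"plus": "+", "minus": "-", "times": "*", "divide": "/",
               "power": "^"}


def expr_to_mathml(e: ex.Expr) -> etree._Element:
    def build(node) -> etree._Element:
        if isinstance(node, ex.Num):
            el = etree.Element(f"{{{MATHML}}}cn")
            v = node.value
            if v == int(v) and abs(v) < 1e15:
                el.set("type", "integer")
                el.text = str(int(v))
            else:
                el.text = repr(v)
            return el
        if isinstance(node, ex.Sym):
            el = etree.Element(f"{{{MATHML}}}ci")
            el.text = f" {node.name} "
            return el
        if isinstance(node, ex.Neg):
            ap = etree.Element(f"{{{MATHML}}}apply")
            ap.append(etree.Element(f"{{{MATHML}}}minus"))
            ap.append(build(node.operand))
            return ap
        if isinstance(node, ex.BinOp):
            opname = {v: k for k, v in _MATHML_OPS.items()}[node.op]
            ap = etree.Element(f"{{{MATHML}}}apply")
            ap.append(etree.Element(f"{{{MATHML}}}{opname}"))
            ap.append(build(node.left))
            ap.append(build(node.right))
            return ap
        if isinstance(node, ex.Call):
            ap = etree.Element(f"{{{MATHML}}}apply")
            ap.append(etree.Element(f"{{{MATHML}}}{node.func}"))
            for a in node.args:
                ap.append(build(a))
            return ap
        raise TypeError(f"not an expression node: {node!r}")

    math = etree.Element(f"{{{MATHML}}}math")
    math.append(build(e))
    return math


def mathml_to_expr(math: etree._Element) -> ex.Expr:
    def local(el) -> str:
        return etree.QName(el).localname

    def convert(el) -> ex.Expr:
        name = local(el)
        if name == "cn":
            ctype = el.get("type", "real")
            if ctype == "e-notation":
                parts = [t.strip() for t in el.itertext() if t.strip()]
                mantissa, exponent = float(parts[0]), float(parts[1])
                return ex.Num(mantissa * 10.0 ** exponent)
            if ctype == "rational":
                parts = [t.strip() for t in el.itertext() if t.strip()]
                return ex.Num(float(parts[0]) / float(parts[1]))
            return ex.Num(float(el.text.strip()))
        if name == "ci":
            return ex.Sym(el.text.strip())
        if name == "apply":
            children = [c for c in el if isinstance(c.tag, str)]
            op = local(children[0])
            args = [convert(c) for c in children[1:]]
            if op == "minus" and len(args) == 1:
                return ex.Neg(args[0])
            if op in _MATHML_OPS:
                sym = _MATHML_OPS[op]
                out = args[0]
                for a in args[1:]:
                    out = ex.BinOp(sym, out, a)
                return out
            if op in ("min", "max"):
                return ex.Call(op, tuple(args))
            if op == "root":
                # degree defaults to a square root
                return ex.BinOp("^", args[-1], ex.Num(0.5))
            raise ValueError(f"unsupported MathML operator <{op}>")
        raise ValueError(f"unsupported MathML element <{name}>")

    children = [c for c in math if isinstance(c.tag, str)]
    if len(children) != 1:
        raise ValueError("expected a single MathML root expression")
    return convert(children[0])


# --- writer ------------------------------------------------------------------

def write_sbml(model: ModelSpec) -> bytes:
    """Serialize to an SBML L2V4 document (UTF-8 bytes)."""
    ns = SBML_L2V[4]
    nsmap = {None: ns, "cbk": ANNOT_NS}
    sbml = etree.Element(f"{{{ns}}}sbml", nsmap=nsmap)
    sbml.set("level", "2")
    sbml.set("version", "4")
    mdl = etree.SubElement(sbml, f"{{{ns}}}model")
    mdl.set("id", _sanitize(model.id))

    annot = etree.SubElement(mdl, f"{{{ns}}}annotation")
    meta = etree.SubElement(annot, f"{{{ANNOT_NS}}}model")
    lineage = etree.SubElement(meta, f"{{{ANNOT_NS}}}lineage")
    lineage.text = yaml.safe_dump(model.lineage, sort_keys=False)
    flags = etree.SubElement(meta, f"{{{ANNOT_NS}}}flags")
    flags.set("diagnostic_mode", str(model.diagnostic_mode).lower())
    if model.reference_flux_id:
        flags.set("reference_flux_id", model.reference_flux_id)
    flags.set("compartment_volume_l", repr(model.compartment_volume_l))
    if model.notes:
        flags.set("notes", model.notes)

    comps = etree.SubElement(mdl, f"{{{ns}}}listOfCompartments")
    for cname in sorted({s.compartment for s in model.species}):
        c = etree.SubElement(comps, f"{{{ns}}}compartment")
        c.set("id", _sanitize(cname))
        c.set("size", repr(model.compartment_volume_l))

    sps = etree.SubElement(mdl, f"{{{ns}}}listOfSpecies")
    for s in model.species:
        el = etree.SubElement(sps, f"{{{ns}}}species")
        el.set("id", s.id)
        if s.name:
            el.set("name", s.name)
        el.set("compartment", _sanitize(s.compartment))
        el.set("initialConcentration", repr(s.initial_concentration))
        el.set("boundaryCondition", "true" if s.clamped else "false")
        sannot = etree.SubElement(el, f"{{{ns}}}annotation")
        sm = etree.SubElement(sannot, f"{{{ANNOT_NS}}}species")
        if s.carbons is not None:
            sm.set("carbons", str(s.carbons))
        if s.phosphates is not None:
            sm.set("phosphates", str(s.phosphates))
        sm.set("accumulator", str(s.accumulator).lower())

    pars = etree.SubElement(mdl, f"{{{ns}}}listOfParameters")
    for name, p in sorted(model.parameters.items()):
        el = etree.SubElement(pars, f"{{{ns}}}parameter")
        el.set("id", name)
        el.set("value", repr(p.value))
        if p.unit:
            pannot = etree.SubElement(el, f"{{{ns}}}annotation")
            pm = etree.SubElement(pannot, f"{{{ANNOT_NS}}}parameter")
            pm.set("unit", p.unit)

    rxns = etree.SubElement(mdl, f"{{{ns}}}listOfReactions")
    for r in model.reactions:
        el = etree.SubElement(rxns, f"{{{ns}}}reaction")
        el.set("id", r.id)
        if r.name:
            el.set("name", r.name)
        el.set("reversible", "true" if r.reversible else "false")
        rannot = etree.SubElement(el, f"{{{ns}}}annotation")
        rm = etree.SubElement(rannot, f"{{{ANNOT_NS}}}rateLaw")
        rm.set("family", r.rate_law.family)
        rm.text = yaml.safe_dump(_law_to_dict(r.rate_law), sort_keys=False)

        reactants = [(sid, -c) for sid, c in r.stoichiometry.items() if c < 0]
        products = [(sid, c) for sid, c in r.stoichiometry.items() if c > 0]
        if reactants:
            lo = etree.SubElement(el, f"{{{ns}}}listOfReactants")
            for sid, c in sorted(reactants):
                sr = etree.SubElement(lo, f"{{{ns}}}speciesReference")
                sr.set("species", sid)
                sr.set("stoichiometry", repr(float(c)))
        if products:
            lo = etree.SubElement(el, f"{{{ns}}}listOfProducts")
            for sid, c in sorted(products):
                sr = etree.SubElement(lo, f"{{{ns}}}speciesReference")
                sr.set("species", sid)
                sr.set("stoichiometry", repr(float(c)))
        if r.modifiers:
            lo = etree.SubElement(el, f"{{{ns}}}listOfModifiers")
            for sid in r.modifiers:
                sr = etree.SubElement(lo, f"{{{ns}}}modifierSpeciesReference")
                sr.set("species", sid)
        kl = etree.SubElement(el, f"{{{ns}}}kineticLaw")
        kl.append(expr_to_mathml(r.rate_law.to_expression()))

    return etree.tostring(sbml, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)


def _sanitize(name: str) -> str:
    out = "".join(ch if ch.isalnum() or ch == "_" else "_" for ch in name)
    return out if out and not out[0].isdigit() else f"m_{out}"


# --- reader ------------------------------------------------------------------

def read_sbml(document: bytes) -> Tuple[ModelSpec, ImportReport]:
    """Parse an SBML Level 2 document into a model plus an import report."""
    root = etree.fromstring(document)
    qname = etree.QName(root)
    if qname.localname != "sbml":
        raise ValueError("not an SBML document")
    level = root.get("level")
    if level != "2":
        raise ValueError(f"only SBML Level 2 is supported (got level {level})")
    ns = qname.namespace

    def f(parent, name):
        return parent.findall(f"{{{ns}}}{name}")

    def f1(parent, name):
        found = parent.find(f"{{{ns}}}{name}")
        return found

    mdl = f1(root, "model")
    if mdl is None:
        raise ValueError("document has no <model>")
    report = ImportReport()

    for bad in ("listOfEvents", "listOfRules", "listOfConstraints"):
        el = f1(mdl, bad)
        if el is not None and len(el):
            report.unresolved.append(bad)
    if report.unresolved:
        raise ValueError(f"unsupported SBML constructs: {report.unresolved}")

    if f1(mdl, "listOfUnitDefinitions") is None:
        report.unit_notes.append(
            "document declares no units; assuming concentrations in mM and time in s")

    comp_sizes = {}
    comps = f1(mdl, "listOfCompartments")
    if comps is not None:
        for c in f(comps, "compartment"):
            comp_sizes[c.get("id")] = float(c.get("size", "1"))
    volume = next(iter(comp_sizes.values()), 1.0)

    species: List[SpeciesSpec] = []
    sp_list = f1(mdl, "listOfSpecies")
    if sp_list is not None:
        for s in f(sp_list, "species"):
            clamped = (s.get("boundaryCondition", "false") == "true"
                       or s.get("constant", "false") == "true")
            conc = s.get("initialConcentration")
            if conc is None:
                amount = float(s.get("initialAmount", "0"))
                size = comp_sizes.get(s.get("compartment"), 1.0)
                conc = amount / size if size else amount
            carbons = phosphates = None
            accumulator = False
            meta = s.find(f"{{{ns}}}annotation/{{{ANNOT_NS}}}species")
            if meta is not None:
                if meta.get("carbons") is not None:
                    carbons = int(meta.get("carbons"))
                if meta.get("phosphates") is not None:
                    phosphates = int(meta.get("phosphates"))
                accumulator = meta.get("accumulator", "false") == "true"
            species.append(SpeciesSpec(
                id=s.get("id"), name=s.get("name", ""),
                compartment=s.get("compartment", "cell"),
                initial_concentration=float(conc),
                carbons=carbons, phosphates=phosphates,
                clamped=clamped, accumulator=accumulator))
            if clamped:
                report.clamped_species.append(s.get("id"))
    report.species_mapped = len(species)
    species_ids = {s.id for s in species}

    params = ParameterSet()
    par_list = f1(mdl, "listOfParameters")
    if par_list is not None:
        for p in f(par_list, "parameter"):
            unit = ""
            meta = p.find(f"{{{ns}}}annotation/{{{ANNOT_NS}}}parameter")
            if meta is not None:
                unit = meta.get("unit", "")
            params.set(p.get("id"), float(p.get("value", "0")), unit)

    reactions: List[ReactionSpec] = []
    rxn_list = f1(mdl, "listOfReactions")
    if rxn_list is not None:
        for r in f(rxn_list, "reaction"):
            rid = r.get("id")
            stoich: Dict[str, float] = {}
            for tag, sign in (("listOfReactants", -1.0), ("listOfProducts", 1.0)):
                lo = f1(r, tag)
                if lo is None:
                    continue
                for sr in f(lo, "speciesReference"):
                    c = sign * float(sr.get("stoichiometry", "1"))
                    sid = sr.get("species")
                    stoich[sid] = stoich.get(sid, 0.0) + c
            modifiers = []
            lo = f1(r, "listOfModifiers")
            if lo is not None:
                modifiers = [sr.get("species")
                             for sr in f(lo, "modifierSpeciesReference")]

            kl = f1(r, "kineticLaw")
            if kl is None:
                raise ValueError(f"reaction {rid!r} has no kinetic law")
            # reaction-local parameters, namespaced by the reaction id
            rename: Dict[str, str] = {}
            for lp_tag in ("listOfParameters", "listOfLocalParameters"):
                lo = f1(kl, lp_tag)
                if lo is None:
                    continue
                for p in list(f(lo, "parameter")) + list(f(lo, "localParameter")):
                    local_id = p.get("id")
                    global_id = f"{rid}_{local_id}"
                    params.set(global_id, float(p.get("value", "0")), "")
                    rename[local_id] = global_id
                    report.local_parameters.setdefault(rid, []).append(local_id)

            law = None
            meta = r.find(f"{{{ns}}}annotation/{{{ANNOT_NS}}}rateLaw")
            if meta is not None and meta.text:
                law = _law_from_dict(yaml.safe_load(meta.text))
                report.named_family_laws[rid] = law.family
            else:
                math = kl.find(f"{{{MATHML}}}math")
                if math is None:
                    raise ValueError(f"reaction {rid!r} kinetic law carries no math")
                tree = mathml_to_expr(math)
                if rename:
                    tree = _rename_symbols(tree, rename)
                law = _match_family(tree, species_ids, params)
                if isinstance(law, rl.GenericExpression):
                    report.generic_laws.append(rid)
                else:
                    report.named_family_laws[rid] = law.family

            reactions.append(ReactionSpec(
                id=rid, stoichiometry=stoich, rate_law=law,
                modifiers=modifiers,
                reversible=r.get("reversible", "true") == "true",
                name=r.get("name", "")))

    lineage: List[dict] = []
    diagnostic = False
    reference_flux = None
    notes = ""
    meta = mdl.find(f"{{{ns}}}annotation/{{{ANNOT_NS}}}model")
    if meta is not None:
        lin = meta.find(f"{{{ANNOT_NS}}}lineage")
        if lin is not None and lin.text:
            lineage = yaml.safe_load(lin.text) or []
        flags = meta.find(f"{{{ANNOT_NS}}}flags")
        if flags is not None:
            diagnostic = flags.get("diagnostic_mode", "false") == "true"
            reference_flux = flags.get("reference_flux_id")
            volume = float(flags.get("compartment_volume_l", repr(volume)))
            notes = flags.get("notes", "")

    model = ModelSpec(id=mdl.get("id", "imported"), species=species,
                      reactions=reactions, parameters=params,
                      lineage=lineage, compartment_volume_l=volume,
                      diagnostic_mode=diagnostic,
                      reference_flux_id=reference_flux, notes=notes)
    return model, report


def _rename_symbols(tree: ex.Expr, rename: Dict[str, str]) -> ex.Expr:
    if isinstance(tree, ex.Sym):
        return ex.Sym(rename.get(tree.name, tree.name))
    if isinstance(tree, ex.Num):
        return tree
    if isinstance(tree, ex.Neg):
        return ex.Neg(_rename_symbols(tree.operand, rename))
    if isinstance(tree, ex.BinOp):
        return ex.BinOp(tree.op, _rename_symbols(tree.left, rename),
                        _rename_symbols(tree.right, rename))
    if isinstance(tree, ex.Call):
        return ex.Call(tree.func, tuple(_rename_symbols(a, rename)
                                        for a in tree.args))
    raise TypeError(f"not an expression node: {tree!r}")


def _match_family(tree: ex.Expr, species_ids: set, params: ParameterSet):
    """Recognise a plain mass-action product k * S1 * S2 ...; anything else
    stays a generic expression."""
    factors: List[ex.Expr] = []

    def flatten(node) -> bool:
        if isinstance(node, ex.BinOp) and node.op == "*":
            return flatten(node.left) and flatten(node.right)
        factors.append(node)
        return isinstance(node, (ex.Sym, ex.Num))

    if flatten(tree):
        syms = [n for n in factors if isinstance(n, ex.Sym)]
        nums = [n for n in factors if isinstance(n, ex.Num)]
        sp = [n.name for n in syms if n.name in species_ids]
        pars = [n.name for n in syms if n.name not in species_ids]
        if len(pars) == 1 and not nums and sp and all(p in params for p in pars):
            orders: Dict[str, float] = {}
            for sid in sp:
                orders[sid] = orders.get(sid, 0.0) + 1.0
            return rl.MassAction(pars[0], sorted(orders.items()))
    syms = ex.symbols(tree)
    return rl.GenericExpression(
        tree,
        parameters=sorted(s for s in syms if s not in species_ids),
        species=sorted(s for s in syms if s in species_ids))


def read_sbml_file(path) -> Tuple[ModelSpec, ImportReport]:
    with open(path, "rb") as fh:
        return read_sbml(fh.read())


def write_sbml_file(model: ModelSpec, path) -> None:
    with open(path, "wb") as fh:
        fh.write(write_sbml(model))
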