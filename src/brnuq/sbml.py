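"""SBML Level 2/3 core-subset reader and writer.

Covers the plain-ODE model class: compartments, species with initial
concentrations (or initial assignments in theta), global parameters, and
reactions with reactant/product/modifier lists and kinetic-law MathML.
Anything outside that subset (events, algebraic or assignment rules, delays,
function definitions, constraints) raises :class:`UnsupportedSBMLError` —
content is never silently dropped.  Reversible reactions are split into two
irreversible ones at import, so fluxes stay nonnegative.
"""
from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Mapping

import sympy as sp

from .expressions import GeneralRate, classify_rate_law, sym
from .model import BRNModel, ModelError, Reaction, Species

SBML_L2 = "http://www.sbml.org/sbml/level2"
SBML_NS_PREFIXES = (
    "http://www.sbml.org/sbml/level2",
    "http://www.sbml.org/sbml/level3",
)
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
WRITE_NS = "http://www.sbml.org/sbml/level2/version4"


class SBMLParseError(ValueError):
    pass


class UnsupportedSBMLError(SBMLParseError):
    pass


# ---------------------------------------------------------------------------
# content MathML <-> sympy

def _tag(el: ET.Element) -> str:
    return el.tag.rsplit("}", 1)[-1]


def mathml_to_sympy(el: ET.Element) -> sp.Expr:
    tag = _tag(el)
    if tag == "math":
        children = list(el)
        if len(children) != 1:
            raise SBMLParseError("<math> must hold exactly one expression")
        return mathml_to_sympy(children[0])
    if tag == "ci":
        return sym("".join(el.itertext()).strip())
    if tag == "cn":
        return _parse_cn(el)
    if tag == "csymbol":
        name = "".join(el.itertext()).strip()
        if el.get("definitionURL", "").endswith("/time") or name == "time":
            return sym("t")
        raise UnsupportedSBMLError(f"unsupported csymbol {name!r}")
    if tag == "apply":
        children = list(el)
        op = _tag(children[0])
        args = [mathml_to_sympy(c) for c in children[1:]]
        if op == "plus":
            return sp.Add(*args) if args else sp.Integer(0)
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            if len(args) == 2:
                return args[0] - args[1]
            raise SBMLParseError("<minus> takes one or two arguments")
        if op == "times":
            return sp.Mul(*args) if args else sp.Integer(1)
        if op == "divide":
            if len(args) != 2:
                raise SBMLParseError("<divide> takes two arguments")
            return args[0] / args[1]
        if op == "power":
            if len(args) != 2:
                raise SBMLParseError("<power> takes two arguments")
            return args[0] ** args[1]
        if op == "exp":
            return sp.exp(args[0])
        if op == "ln":
            return sp.log(args[0])
        if op == "log":
            base = sp.Integer(10)
            if _tag(children[1]) == "logbase":
                base = mathml_to_sympy(list(children[1])[0])
                args = [mathml_to_sympy(c) for c in children[2:]]
            return sp.log(args[0], base)
        raise UnsupportedSBMLError(f"unsupported MathML operator <{op}>")
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    raise UnsupportedSBMLError(f"unsupported MathML element <{tag}>")


def _parse_cn(el: ET.Element) -> sp.Expr:
    ctype = el.get("type", "real")
    parts = [t.strip() for t in el.itertext() if t.strip()]
    if ctype in ("real", "integer", "double"):
        text = parts[0]
        if ctype == "integer":
            return sp.Integer(int(text))
        val = float(text)
        return sp.Integer(int(val)) if val.is_integer() else sp.Float(text)
    if ctype == "e-notation":
        return sp.Float(float(parts[0]) * 10 ** float(parts[1]))
    if ctype == "rational":
        return sp.Rational(int(parts[0]), int(parts[1]))
    raise UnsupportedSBMLError(f"unsupported <cn type={ctype!r}>")


def sympy_to_mathml(expr: sp.Expr) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(_emit(sp.sympify(expr)))
    return math


def _apply(op: str, *children: ET.Element) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}apply")
    el.append(ET.Element(f"{{{MATHML_NS}}}{op}"))
    el.extend(children)
    return el


def _leaf(tag: str, text: str) -> ET.Element:
    el = ET.Element(f"{{{MATHML_NS}}}{tag}")
    el.text = text
    return el


def _emit(expr: sp.Expr) -> ET.Element:
    if isinstance(expr, sp.Symbol):
        return _leaf("ci", expr.name)
    if isinstance(expr, sp.Integer):
        return _leaf("cn", str(int(expr)))
    if isinstance(expr, sp.Rational):
        return _apply("divide", _leaf("cn", str(expr.p)), _leaf("cn", str(expr.q)))
    if isinstance(expr, sp.Float):
        return _leaf("cn", repr(float(expr)))
    if isinstance(expr, sp.Add):
        return _apply("plus", *(_emit(a) for a in expr.args))
    if isinstance(expr, sp.Mul):
        num, den = sp.fraction(sp.together(expr))
        if den != 1:
            return _apply("divide", _emit(num), _emit(den))
        factors = [_emit(a) for a in expr.args]
        return _apply("times", *factors)
    if isinstance(expr, sp.Pow):
        base, exponent = expr.args
        if exponent.is_number and exponent.is_negative:
            return _apply("divide", _leaf("cn", "1"), _emit(base ** (-exponent)))
        return _apply("power", _emit(base), _emit(exponent))
    if isinstance(expr, sp.exp):
        return _apply("exp", _emit(expr.args[0]))
    if isinstance(expr, sp.log):
        return _apply("ln", _emit(expr.args[0]))
    raise ModelError(f"cannot serialize expression node {type(expr).__name__}: {expr}")


# ---------------------------------------------------------------------------
# reading

_UNSUPPORTED_LISTS = (
    "listOfEvents",
    "listOfConstraints",
    "listOfFunctionDefinitions",
)


def parse_sbml(path: str | Path) -> BRNModel:
    """Parse an SBML file into a :class:`BRNModel`.

    Kinetic laws structurally matching mass-action or Michaelis-Menten form
    are classified as such; anything else becomes a general rate expression.
    """
    path = Path(path)
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:  # position carries (line, column)
        raise SBMLParseError(f"malformed XML in {path.name} at line {exc.position[0]}: {exc.msg}") from exc
    root = tree.getroot()
    ns = root.tag.split("}")[0].strip("{")
    if not any(ns.startswith(p) for p in SBML_NS_PREFIXES):
        raise SBMLParseError(f"not an SBML Level 2/3 document (namespace {ns!r})")

    def q(tag: str) -> str:
        return f"{{{ns}}}{tag}"

    model_el = root.find(q("model"))
    if model_el is None:
        raise SBMLParseError("no <model> element")
    for bad in _UNSUPPORTED_LISTS:
        el = model_el.find(q(bad))
        if el is not None and len(el):
            raise UnsupportedSBMLError(f"unsupported SBML construct <{bad}>")
    rules = model_el.find(q("listOfRules"))
    if rules is not None and len(rules):
        raise UnsupportedSBMLError("unsupported SBML construct <listOfRules>")

    params: list[str] = []
    inputs: list[str] = []
    param_values: dict[str, float] = {}
    for p in model_el.iterfind(f"{q('listOfParameters')}/{q('parameter')}"):
        pid = p.get("id")
        # non-constant global parameters are experiment input channels u(t),
        # whose time courses live in the sidecar experiment file
        if p.get("constant", "true").lower() == "false":
            inputs.append(pid)
            continue
        params.append(pid)
        if p.get("value") is not None:
            param_values[pid] = float(p.get("value"))

    initial_assignments: dict[str, sp.Expr] = {}
    for ia in model_el.iterfind(f"{q('listOfInitialAssignments')}/{q('initialAssignment')}"):
        math = ia.find(f"{{{MATHML_NS}}}math")
        if math is None:
            raise SBMLParseError("initialAssignment without <math>")
        initial_assignments[ia.get("symbol")] = mathml_to_sympy(math)

    species: list[Species] = []
    for s in model_el.iterfind(f"{q('listOfSpecies')}/{q('species')}"):
        sid = s.get("id")
        if sid in initial_assignments:
            init: sp.Expr | float = initial_assignments[sid]
        elif s.get("initialConcentration") is not None:
            init = float(s.get("initialConcentration"))
        elif s.get("initialAmount") is not None:
            init = float(s.get("initialAmount"))
        else:
            init = 0.0
        species.append(Species(id=sid, name=s.get("name") or sid, initial=init))
    species_ids = [s.id for s in species]

    reactions: list[Reaction] = []
    for r in model_el.iterfind(f"{q('listOfReactions')}/{q('reaction')}"):
        rid = r.get("id")
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        for ref in r.iterfind(f"{q('listOfReactants')}/{q('speciesReference')}"):
            reactants[ref.get("species")] = reactants.get(ref.get("species"), 0) + int(float(ref.get("stoichiometry", "1")))
        for ref in r.iterfind(f"{q('listOfProducts')}/{q('speciesReference')}"):
            products[ref.get("species")] = products.get(ref.get("species"), 0) + int(float(ref.get("stoichiometry", "1")))
        modifiers = frozenset(
            ref.get("species")
            for ref in r.iterfind(f"{q('listOfModifiers')}/{q('modifierSpeciesReference')}")
        )
        kl = r.find(q("kineticLaw"))
        if kl is None:
            raise UnsupportedSBMLError(f"reaction {rid!r} has no kinetic law")
        for list_tag in ("listOfLocalParameters", "listOfParameters"):
            local = kl.find(q(list_tag))
            if local is None:
                continue
            for p in local:
                pid = p.get("id")
                scoped = f"{rid}__{pid}"
                params.append(scoped)
                if p.get("value") is not None:
                    param_values[scoped] = float(p.get("value"))
        math = kl.find(f"{{{MATHML_NS}}}math")
        if math is None:
            raise SBMLParseError(f"reaction {rid!r}: kinetic law without <math>")
        expr = mathml_to_sympy(math)
        # rescope local parameter symbols
        expr = expr.subs({sym(p.rsplit("__", 1)[1]): sym(p) for p in params if p.startswith(f"{rid}__")})
        reversible = r.get("reversible", "false").lower() == "true"
        if reversible:
            fwd, back = _split_reversible(expr)
            reactions.append(_make_reaction(rid + "_fwd", reactants, products, modifiers, fwd, species_ids, params))
            if back is not None:
                reactions.append(_make_reaction(rid + "_rev", products, reactants, modifiers, back, species_ids, params))
        else:
            reactions.append(_make_reaction(rid, reactants, products, modifiers, expr, species_ids, params))

    name = model_el.get("id") or model_el.get("name") or path.stem
    model = BRNModel(
        species=tuple(species),
        reactions=tuple(reactions),
        parameters=tuple(params),
        inputs=tuple(inputs),
        name=name,
    )
    model._cache["parameter_values"] = param_values
    return model


def _make_reaction(rid, reactants, products, modifiers, expr, species_ids, params) -> Reaction:
    free = {s.name for s in expr.free_symbols}
    modifiers = frozenset(m for m in modifiers if m in free)
    law = classify_rate_law(expr, reactants, species_ids, params)
    return Reaction(
        id=rid,
        reactant_stoich=dict(reactants),
        product_stoich=dict(products),
        modifiers=modifiers,
        rate_law=law,
    )


def _split_reversible(expr: sp.Expr) -> tuple[sp.Expr, sp.Expr | None]:
    """Split a net rate a - b into forward a and backward b.

    Terms with negative numeric coefficient form the backward flux; if none
    exist the reaction is effectively irreversible.
    """
    pos, neg = [], []
    for term in sp.Add.make_args(sp.expand(expr)):
        coeff = term.as_coeff_Mul()[0]
        (neg if coeff.is_negative else pos).append(term)
    fwd = sp.Add(*pos) if pos else sp.Integer(0)
    back = -sp.Add(*neg) if neg else None
    return fwd, back


# ---------------------------------------------------------------------------
# writing (fixtures round-trip subset)


def write_sbml(model: BRNModel, path: str | Path, parameter_values: Mapping[str, float] | None = None) -> None:
    """Write the model as SBML Level 2 Version 4 (the round-trip subset).

    ``parameter_values`` fills the value attribute of global parameters
    (defaults to 1.0, which SBML requires to be numeric for our reader's
    convenience).  Non-numeric species initials are emitted as initial
    assignments.
    """
    ET.register_namespace("", WRITE_NS)
    ET.register_namespace("math", MATHML_NS)
    values = dict(parameter_values or {})
    root = ET.Element(f"{{{WRITE_NS}}}sbml", level="2", version="4")
    m = ET.SubElement(root, f"{{{WRITE_NS}}}model", id=model.name)
    lc = ET.SubElement(m, f"{{{WRITE_NS}}}listOfCompartments")
    ET.SubElement(lc, f"{{{WRITE_NS}}}compartment", id="cell", size="1")
    ls = ET.SubElement(m, f"{{{WRITE_NS}}}listOfSpecies")
    assignments: list[tuple[str, sp.Expr]] = []
    for s in model.species:
        attrs = {"id": s.id, "name": s.name or s.id, "compartment": "cell"}
        init = s.initial_expr
        if init.is_number:
            attrs["initialConcentration"] = repr(float(init))
        else:
            attrs["initialConcentration"] = "0"
            assignments.append((s.id, init))
        ET.SubElement(ls, f"{{{WRITE_NS}}}species", **attrs)
    lp = ET.SubElement(m, f"{{{WRITE_NS}}}listOfParameters")
    for p in model.parameters:
        ET.SubElement(lp, f"{{{WRITE_NS}}}parameter", id=p, value=repr(float(values.get(p, 1.0))))
    for c in model.inputs:
        ET.SubElement(lp, f"{{{WRITE_NS}}}parameter", id=c, value="0", constant="false")
    if assignments:
        la = ET.SubElement(m, f"{{{WRITE_NS}}}listOfInitialAssignments")
        for sid, expr in assignments:
            ia = ET.SubElement(la, f"{{{WRITE_NS}}}initialAssignment", symbol=sid)
            ia.append(sympy_to_mathml(expr))
    lr = ET.SubElement(m, f"{{{WRITE_NS}}}listOfReactions")
    for r in model.reactions:
        re_el = ET.SubElement(lr, f"{{{WRITE_NS}}}reaction", id=r.id, reversible="false")
        if r.reactant_stoich:
            lre = ET.SubElement(re_el, f"{{{WRITE_NS}}}listOfReactants")
            for sid, c in r.reactant_stoich.items():
                ET.SubElement(lre, f"{{{WRITE_NS}}}speciesReference", species=sid, stoichiometry=str(int(c)))
        if r.product_stoich:
            lpr = ET.SubElement(re_el, f"{{{WRITE_NS}}}listOfProducts")
            for sid, c in r.product_stoich.items():
                ET.SubElement(lpr, f"{{{WRITE_NS}}}speciesReference", species=sid, stoichiometry=str(int(c)))
        if r.modifiers:
            lm = ET.SubElement(re_el, f"{{{WRITE_NS}}}listOfModifiers")
            for sid in sorted(r.modifiers):
                ET.SubElement(lm, f"{{{WRITE_NS}}}modifierSpeciesReference", species=sid)
        kl = ET.SubElement(re_el, f"{{{WRITE_NS}}}kineticLaw")
        kl.append(sympy_to_mathml(r.rate_expr()))
    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="unicode")
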