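"""Translation of a regulatory map into a Boolean logical model.

The translation template follows the published CaSQ convention for
process-description maps: for a target ``t`` with activating reactions
``r1..rk`` (each with one or more sources) and inhibiting regulators
``i1..im``::

    f(t) = (AND(sources of r1) OR ... OR AND(sources of rk))
           AND NOT (i1 OR ... OR im)

Species with no incoming signed reaction are model *inputs* and keep their
value (identity rule).  A target with inhibitors but no activators is
constitutively ON unless repressed: ``f(t) = NOT(i1 OR ... OR im)``.
Transport and dissociation reactions (neutral sign) propagate their source as
an activation of the destination form.  Degradation sinks are dropped.

The model can be round-tripped through SBML-qual Level 3 Version 1 with
binary qualitative species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from lxml import etree

from .map_model import MapFormatError, MapParseError, RegulatoryMap, validate_map

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATH_NS = "http://www.w3.org/1998/Math/MathML"


class InvalidMapError(ValueError):
    """infer_rules refuses a map that fails validate_map."""


class UnsupportedMultilevelError(MapFormatError):
    """SBML-qual species with max level > 1 are outside the binary contract."""


# ---------------------------------------------------------------------------
# expression trees


@dataclass(frozen=True)
class Lit:
    name: str


@dataclass(frozen=True)
class Not:
    child: "LogicExpr"


@dataclass(frozen=True)
class And:
    children: tuple["LogicExpr", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["LogicExpr", ...]


LogicExpr = Lit | Not | And | Or


def expr_literals(expr: LogicExpr) -> set[str]:
    if isinstance(expr, Lit):
        return {expr.name}
    if isinstance(expr, Not):
        return expr_literals(expr.child)
    out: set[str] = set()
    for child in expr.children:
        out |= expr_literals(child)
    return out


def eval_expr(expr: LogicExpr, state: Mapping[str, int]) -> int:
    if isinstance(expr, Lit):
        return int(state[expr.name])
    if isinstance(expr, Not):
        return 1 - eval_expr(expr.child, state)
    if isinstance(expr, And):
        return int(all(eval_expr(c, state) for c in expr.children))
    return int(any(eval_expr(c, state) for c in expr.children))


def _flat(op: type, children: Sequence[LogicExpr]) -> LogicExpr:
    """Build AND/OR, flattening singletons (operators need >= 2 children)."""
    if len(children) == 1:
        return children[0]
    return op(tuple(children))


@dataclass(frozen=True)
class LogicRule:
    target: str
    expr: LogicExpr
    is_input: bool = False


@dataclass
class LogicModel:
    rules: dict[str, LogicRule]
    node_order: list[str]
    inputs: set[str] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    def rule(self, node: str) -> LogicRule:
        return self.rules[node]


# ---------------------------------------------------------------------------
# rule inference


def infer_rules(map_: RegulatoryMap, drop_degradation: bool = True) -> LogicModel:
    """Translate a validated map into one Boolean rule per species."""
    issues = validate_map(map_)
    if issues:
        detail = "; ".join(f"{i.rule}:{i.offender}" for i in issues[:5])
        raise InvalidMapError(
            f"map has {len(issues)} validation issue(s) ({detail}); fix them before inference"
        )
    kinds = {s.id: s.kind for s in map_.species}
    nodes = [s.id for s in map_.species]
    if drop_degradation:
        nodes = [n for n in nodes if kinds[n] != "degradation"]
    node_set = set(nodes)

    rules: dict[str, LogicRule] = {}
    inputs: set[str] = set()
    for node in nodes:
        activating: list[LogicExpr] = []
        inhibitors: list[str] = []
        for inter in map_.interactions:
            if inter.target != node:
                continue
            sources = [s for s in inter.sources if s in node_set]
            if not sources:
                continue
            if inter.sign == "inhibition":
                inhibitors.extend(sources)
            else:
                # activation, logical activation, and neutral transport /
                # dissociation all propagate the source as an activator
                activating.append(_flat(And, [Lit(s) for s in sources]))
        if not activating and not inhibitors:
            rules[node] = LogicRule(node, Lit(node), is_input=True)
            inputs.add(node)
            continue
        seen: set[str] = set()
        inhib_lits = []
        for i in inhibitors:
            if i not in seen:
                seen.add(i)
                inhib_lits.append(Lit(i))
        if activating and inhib_lits:
            expr: LogicExpr = _flat(
                And, [_flat(Or, activating), Not(_flat(Or, inhib_lits))]
            )
        elif activating:
            expr = _flat(Or, activating)
        else:
            expr = Not(_flat(Or, inhib_lits))
        rules[node] = LogicRule(node, expr)
    return LogicModel(rules=rules, node_order=nodes, inputs=inputs)


# ---------------------------------------------------------------------------
# canonical text form


def _to_text(expr: LogicExpr) -> str:
    if isinstance(expr, Lit):
        return expr.name
    if isinstance(expr, Not):
        return f"(NOT {_to_text(expr.child)})"
    op = " AND " if isinstance(expr, And) else " OR "
    parts = sorted(_to_text(c) for c in expr.children)
    return "(" + op.join(parts) + ")"


def rule_to_text(rule: LogicRule) -> str:
    """Deterministic fully-parenthesised text; commutative operands sorted."""
    return _to_text(rule.expr)


# ---------------------------------------------------------------------------
# SBML-qual I/O


def _math_of(expr: LogicExpr, parent: etree._Element) -> None:
    M = "{%s}" % MATH_NS
    if isinstance(expr, Lit):
        apply = etree.SubElement(parent, M + "apply")
        etree.SubElement(apply, M + "eq")
        ci = etree.SubElement(apply, M + "ci")
        ci.text = f" {expr.name} "
        cn = etree.SubElement(apply, M + "cn")
        cn.set("type", "integer")
        cn.text = " 1 "
        return
    apply = etree.SubElement(parent, M + "apply")
    if isinstance(expr, Not):
        etree.SubElement(apply, M + "not")
        _math_of(expr.child, apply)
    else:
        etree.SubElement(apply, M + ("and" if isinstance(expr, And) else "or"))
        for child in expr.children:
            _math_of(child, apply)


def write_sbml_qual(model: LogicModel, path: str | Path) -> Path:
    """Write the model as SBML-qual L3V1 with binary qualitative species."""
    path = Path(path)
    nsmap = {None: SBML_NS, "qual": QUAL_NS}
    S = "{%s}" % SBML_NS
    Q = "{%s}" % QUAL_NS
    root = etree.Element(S + "sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    root.set(Q + "required", "true")
    sbml_model = etree.SubElement(root, S + "model")
    sbml_model.set("id", "logical_model")
    comps = etree.SubElement(sbml_model, S + "listOfCompartments")
    comp = etree.SubElement(comps, S + "compartment")
    comp.set("id", "default")
    comp.set("constant", "true")
    qs_list = etree.SubElement(sbml_model, Q + "listOfQualitativeSpecies")
    for node in model.node_order:
        qs = etree.SubElement(qs_list, Q + "qualitativeSpecies")
        qs.set(Q + "id", node)
        qs.set(Q + "compartment", "default")
        qs.set(Q + "constant", "false")
        qs.set(Q + "maxLevel", "1")
    tr_list = etree.SubElement(sbml_model, Q + "listOfTransitions")
    for node in model.node_order:
        rule = model.rules[node]
        if rule.is_input:
            continue
        tr = etree.SubElement(tr_list, Q + "transition")
        tr.set(Q + "id", f"tr_{node}")
        in_list = etree.SubElement(tr, Q + "listOfInputs")
        for lit in sorted(expr_literals(rule.expr)):
            inp = etree.SubElement(in_list, Q + "input")
            inp.set(Q + "id", f"tr_{node}_in_{lit}")
            inp.set(Q + "qualitativeSpecies", lit)
            inp.set(Q + "transitionEffect", "none")
        out_list = etree.SubElement(tr, Q + "listOfOutputs")
        out = etree.SubElement(out_list, Q + "output")
        out.set(Q + "id", f"tr_{node}_out")
        out.set(Q + "qualitativeSpecies", node)
        out.set(Q + "transitionEffect", "assignmentLevel")
        ft_list = etree.SubElement(tr, Q + "listOfFunctionTerms")
        ft = etree.SubElement(ft_list, Q + "functionTerm")
        ft.set(Q + "resultLevel", "1")
        math = etree.SubElement(ft, "{%s}math" % MATH_NS)
        _math_of(rule.expr, math)
        dt = etree.SubElement(ft_list, Q + "defaultTerm")
        dt.set(Q + "resultLevel", "0")
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)
    return path


def _parse_math(el: etree._Element) -> LogicExpr:
    ln = etree.QName(el).localname
    if ln == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise MapFormatError("math element must have exactly one child")
        return _parse_math(children[0])
    if ln == "ci":
        return Lit((el.text or "").strip())
    if ln == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        head, args = children[0], children[1:]
        op = etree.QName(head).localname
        if op == "eq":
            ci = [a for a in args if etree.QName(a).localname == "ci"]
            cn = [a for a in args if etree.QName(a).localname == "cn"]
            if len(ci) != 1 or len(cn) != 1:
                raise MapFormatError("eq term must compare one species to one level")
            level = int(float((cn[0].text or "0").strip()))
            if level > 1:
                raise UnsupportedMultilevelError(
                    f"function term compares {ci[0].text.strip()} to level {level}; only binary models supported"
                )
            lit = Lit((ci[0].text or "").strip())
            return lit if level == 1 else Not(lit)
        if op == "geq":
            ci = [a for a in args if etree.QName(a).localname == "ci"]
            return Lit((ci[0].text or "").strip())
        if op == "not":
            return Not(_parse_math(args[0]))
        if op == "and":
            return _flat(And, [_parse_math(a) for a in args])
        if op == "or":
            return _flat(Or, [_parse_math(a) for a in args])
        raise MapFormatError(f"unsupported MathML operator {op!r}")
    raise MapFormatError(f"unsupported MathML element {ln!r}")


def read_sbml_qual(path: str | Path) -> LogicModel:
    """Read a binary SBML-qual file back into a :class:`LogicModel`."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise MapParseError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    Q = "{%s}" % QUAL_NS
    nodes: list[str] = []
    for el in root.iter(Q + "qualitativeSpecies"):
        sid = el.get(Q + "id") or el.get("id")
        if sid is None:
            raise MapFormatError(f"{path}: qualitativeSpecies without id")
        max_level = el.get(Q + "maxLevel") or el.get("maxLevel") or "1"
        if int(max_level) > 1:
            raise UnsupportedMultilevelError(
                f"{path}: species {sid} has maxLevel {max_level}; only binary models supported"
            )
        nodes.append(sid)
    node_set = set(nodes)
    rules: dict[str, LogicRule] = {}
    for tr in root.iter(Q + "transition"):
        outputs = [
            o.get(Q + "qualitativeSpecies") or o.get("qualitativeSpecies")
            for o in tr.iter(Q + "output")
        ]
        if len(outputs) != 1:
            raise MapFormatError(f"{path}: transition must have exactly one output")
        target = outputs[0]
        if target not in node_set:
            raise MapFormatError(f"{path}: transition output references undeclared species {target!r}")
        expr: LogicExpr | None = None
        for ft in tr.iter(Q + "functionTerm"):
            level = int(ft.get(Q + "resultLevel") or ft.get("resultLevel") or "0")
            if level > 1:
                raise UnsupportedMultilevelError(
                    f"{path}: function term with resultLevel {level}; only binary models supported"
                )
            maths = [c for c in ft if etree.QName(c).localname == "math"]
            if level == 1 and maths:
                expr = _parse_math(maths[0])
        if expr is None:
            raise MapFormatError(f"{path}: transition for {target} lacks a resultLevel=1 function term")
        for lit in expr_literals(expr):
            if lit not in node_set:
                raise MapFormatError(f"{path}: transition references undeclared species {lit!r}")
        rules[target] = LogicRule(target, expr)
    inputs = set()
    for node in nodes:
        if node not in rules:
            rules[node] = LogicRule(node, Lit(node), is_input=True)
            inputs.add(node)
    return LogicModel(rules=rules, node_order=nodes, inputs=inputs)


# ---------------------------------------------------------------------------
# equivalence helper (used by round-trip tests and by model comparison)


def rules_equivalent(a: LogicRule, b: LogicRule) -> bool:
    """Truth-table equality of two rules over the union of their literals."""
    lits = sorted(expr_literals(a.expr) | expr_literals(b.expr))
    for values in itertools.product((0, 1), repeat=len(lits)):
        state = dict(zip(lits, values))
        if eval_expr(a.expr, state) != eval_expr(b.expr, state):
            return False
    return True
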