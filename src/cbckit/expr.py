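"""Small arithmetic expression trees over species/parameter symbols.

Imported SBML kinetic laws that do not match a named rate-law family are kept
as expression trees and evaluated by a recursive tree walk.  The grammar is
deliberately tiny: numbers, symbols, + - * / ** (unary minus), and min/max.
That subset is sufficient for every kinetic law in the Calvin-Benson cycle
models this package targets.
"""

from __future__ import annotations

import ast as _pyast
from dataclasses import dataclass
from typing import Mapping, Union

__all__ = [
    "Expr", "Num", "Sym", "BinOp", "Call", "Neg",
    "parse_expression", "evaluate", "symbols", "to_text",
]


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class Sym:
    name: str


@dataclass(frozen=True)
class BinOp:
    op: str  # one of + - * / ^
    left: "Expr"
    right: "Expr"


@dataclass(frozen=True)
class Neg:
    operand: "Expr"


@dataclass(frozen=True)
class Call:
    func: str  # min | max
    args: tuple


Expr = Union[Num, Sym, BinOp, Neg, Call]

_BINOPS = {
    _pyast.Add: "+",
    _pyast.Sub: "-",
    _pyast.Mult: "*",
    _pyast.Div: "/",
    _pyast.Pow: "^",
}

_ALLOWED_CALLS = {"min", "max"}


class ExpressionError(ValueError):
    pass


def _convert(node: _pyast.AST) -> Expr:
    if isinstance(node, _pyast.Expression):
        return _convert(node.body)
    if isinstance(node, _pyast.Constant):
        if isinstance(node.value, (int, float)):
            return Num(float(node.value))
        raise ExpressionError(f"unsupported constant {node.value!r}")
    if isinstance(node, _pyast.Name):
        return Sym(node.id)
    if isinstance(node, _pyast.BinOp):
        op = _BINOPS.get(type(node.op))
        if op is None:
            raise ExpressionError(f"unsupported operator {node.op!r}")
        return BinOp(op, _convert(node.left), _convert(node.right))
    if isinstance(node, _pyast.UnaryOp):
        if isinstance(node.op, _pyast.USub):
            return Neg(_convert(node.operand))
        if isinstance(node.op, _pyast.UAdd):
            return _convert(node.operand)
        raise ExpressionError(f"unsupported unary operator {node.op!r}")
    if isinstance(node, _pyast.Call):
        if not isinstance(node.func, _pyast.Name) or node.func.id not in _ALLOWED_CALLS:
            raise ExpressionError("only min/max calls are allowed")
        if node.keywords:
            raise ExpressionError("keyword arguments are not allowed")
        return Call(node.func.id, tuple(_convert(a) for a in node.args))
    raise ExpressionError(f"unsupported syntax: {_pyast.dump(node)}")


def parse_expression(text: str) -> Expr:
    """Parse an infix expression string (``**`` or ``^`` for powers)."""
    try:
        tree = _pyast.parse(text.replace("^", "**"), mode="eval")
    except SyntaxError as exc:  # pragma: no cover - message detail only
        raise ExpressionError(f"cannot parse {text!r}: {exc}") from exc
    return _convert(tree)


def evaluate(expr: Expr, env: Mapping[str, float]) -> float:
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Sym):
        try:
            return float(env[expr.name])
        except KeyError:
            raise ExpressionError(f"unresolved symbol {expr.name!r}") from None
    if isinstance(expr, Neg):
        return -evaluate(expr.operand, env)
    if isinstance(expr, BinOp):
        a = evaluate(expr.left, env)
        b = evaluate(expr.right, env)
        if expr.op == "+":
            return a + b
        if expr.op == "-":
            return a - b
        if expr.op == "*":
            return a * b
        if expr.op == "/":
            return a / b
        if expr.op == "^":
            return a ** b
        raise ExpressionError(f"unknown operator {expr.op}")
    if isinstance(expr, Call):
        vals = [evaluate(a, env) for a in expr.args]
        return min(vals) if expr.func == "min" else max(vals)
    raise ExpressionError(f"not an expression node: {expr!r}")


def symbols(expr: Expr) -> set:
    if isinstance(expr, Num):
        return set()
    if isinstance(expr, Sym):
        return {expr.name}
    if isinstance(expr, Neg):
        return symbols(expr.operand)
    if isinstance(expr, BinOp):
        return symbols(expr.left) | symbols(expr.right)
    if isinstance(expr, Call):
        out: set = set()
        for a in expr.args:
            out |= symbols(a)
        return out
    raise ExpressionError(f"not an expression node: {expr!r}")


_PREC = {"+": 1, "-": 1, "*": 2, "/": 2, "^": 3}


def to_text(expr: Expr, _parent_prec: int = 0) -> str:
    """Render an expression back to parseable infix text (canonical form)."""
    if isinstance(expr, Num):
        v = expr.value
        return repr(int(v)) if v == int(v) and abs(v) < 1e15 else repr(v)
    if isinstance(expr, Sym):
        return expr.name
    if isinstance(expr, Neg):
        inner = to_text(expr.operand, 4)
        return f"-{inner}"
    if isinstance(expr, Call):
        return f"{expr.func}({', '.join(to_text(a) for a in expr.args)})"
    if isinstance(expr, BinOp):
        prec = _PREC[expr.op]
        # ** is right-associative in the parser: parenthesise a left power chain
        left = to_text(expr.left, prec + (1 if expr.op == "^" else 0))
        # - / ^ are not associative: force parens on same-precedence right child
        right = to_text(expr.right, prec + (0 if expr.op in "+*" else 1))
        text = f"{left} {expr.op} {right}"
        if prec < _parent_prec:
            text = f"({text})"
        return text
    raise ExpressionError(f"not an expression node: {expr!r}")
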