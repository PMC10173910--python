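"""Skip-logic / branching-logic expressions shared by both form dialects.

Two concrete grammars render the same expression tree:

* ``xlsform`` — ``${name}`` field references, operators ``= != < <= > >=``,
  ``and`` / ``or`` / ``not(...)``, membership ``selected(${f}, 'c')`` and a
  bare ``.`` meaning "this field" (constraints only).
* ``redcap`` — ``[name]`` references, operators ``= <> < <= > >=``,
  ``and`` / ``or`` / ``not(...)``, and the checkbox idiom
  ``[f(c)] = '1'`` which parses to the same membership node.

Only this subset is supported; anything else is a :class:`LogicSyntaxError`.

Evaluation semantics: a comparison against a missing (absent or empty)
value is *false*, so a field whose skip logic depends on unanswered
questions stays hidden. Literals that look numeric compare numerically,
ISO dates/datetimes compare chronologically, everything else textually.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, datetime
from typing import Iterator, Union

from .model import FlatRecord

__all__ = [
    "LogicExpr",
    "TrueConst",
    "Comparison",
    "Selected",
    "And",
    "Or",
    "Not",
    "LogicSyntaxError",
    "parse_logic",
    "render_logic",
    "evaluate_logic",
    "field_refs",
]

OPS = ("=", "!=", "<", "<=", ">", ">=")


class LogicSyntaxError(ValueError):
    """Raised on text outside the supported grammar; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class TrueConst:
    """Absent logic: the field is shown unconditionally."""


@dataclass(frozen=True)
class Literal:
    text: str
    quoted: bool = True

    def __post_init__(self) -> None:
        if not self.quoted and not re.match(r"^-?\d+(\.\d+)?$", self.text):
            raise ValueError(f"unquoted literal must be numeric: {self.text!r}")

    def render(self) -> str:
        return f"'{self.text}'" if self.quoted else self.text


@dataclass(frozen=True)
class Comparison:
    field: str
    op: str  # canonical: = != < <= > >=
    literal: Literal

    def __post_init__(self) -> None:
        if self.op not in OPS:
            raise ValueError(f"unknown operator {self.op!r}")


@dataclass(frozen=True)
class Selected:
    """Membership test: option `code` is ticked on multi-select `field`."""

    field: str
    code: str


@dataclass(frozen=True)
class And:
    items: tuple["LogicExpr", ...]


@dataclass(frozen=True)
class Or:
    items: tuple["LogicExpr", ...]


@dataclass(frozen=True)
class Not:
    item: "LogicExpr"


LogicExpr = Union[TrueConst, Comparison, Selected, And, Or, Not]


def field_refs(expr: LogicExpr) -> Iterator[str]:
    """Yield every field name referenced in the tree (with repeats)."""
    if isinstance(expr, Comparison):
        yield expr.field
    elif isinstance(expr, Selected):
        yield expr.field
    elif isinstance(expr, (And, Or)):
        for item in expr.items:
            yield from field_refs(item)
    elif isinstance(expr, Not):
        yield from field_refs(expr.item)


# ---------------------------------------------------------------------------
# tokenizer
# ---------------------------------------------------------------------------

_TOKEN_SPEC = [
    ("WS", r"\s+"),
    ("XREF", r"\$\{[^}]+\}"),
    ("RREF", r"\[[A-Za-z_][\w]*(\([^)\]]+\))?\]"),
    ("STRING", r"'[^']*'|\"[^\"]*\""),
    ("OP", r"<>|!=|<=|>=|=|<|>"),
    ("NUMBER", r"-?\d+(\.\d+)?"),
    ("LPAREN", r"\("),
    ("RPAREN", r"\)"),
    ("COMMA", r","),
    ("DOT", r"\."),
    ("WORD", r"[A-Za-z_][\w]*"),
]
_TOKEN_RE = re.compile("|".join(f"(?P<{n}>{p})" for n, p in _TOKEN_SPEC))


@dataclass
class _Token:
    kind: str
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise LogicSyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "WS":
            tokens.append(_Token(m.lastgroup, m.group(), pos))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token], dialect: str, length: int):
        self.tokens = tokens
        self.dialect = dialect
        self.i = 0
        self.length = length

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise LogicSyntaxError("unexpected end of expression", self.length)
        self.i += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise LogicSyntaxError(f"expected {kind}, found {tok.text!r}", tok.pos)
        return tok

    def _is_word(self, word: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == "WORD" and tok.text.lower() == word

    # grammar: or_expr := and_expr ('or' and_expr)*
    def parse_or(self) -> LogicExpr:
        items = [self.parse_and()]
        while self._is_word("or"):
            self.next()
            items.append(self.parse_and())
        if len(items) == 1:
            return items[0]
        return Or(tuple(_flatten(items, Or)))

    def parse_and(self) -> LogicExpr:
        items = [self.parse_unary()]
        while self._is_word("and"):
            self.next()
            items.append(self.parse_unary())
        if len(items) == 1:
            return items[0]
        return And(tuple(_flatten(items, And)))

    def parse_unary(self) -> LogicExpr:
        tok = self.peek()
        if tok is not None and tok.kind == "WORD" and tok.text.lower() == "not":
            self.next()
            self.expect("LPAREN")
            inner = self.parse_or()
            self.expect("RPAREN")
            return Not(inner)
        return self.parse_primary()

    def parse_primary(self) -> LogicExpr:
        tok = self.peek()
        if tok is None:
            raise LogicSyntaxError("unexpected end of expression", self.length)
        if tok.kind == "LPAREN":
            self.next()
            inner = self.parse_or()
            self.expect("RPAREN")
            return inner
        if tok.kind == "WORD" and tok.text.lower() == "selected":
            if self.dialect != "xlsform":
                raise LogicSyntaxError("selected() is an xlsform construct", tok.pos)
            return self.parse_selected()
        if tok.kind == "WORD":
            raise LogicSyntaxError(f"unknown function or keyword {tok.text!r}", tok.pos)
        return self.parse_comparison()

    def parse_selected(self) -> LogicExpr:
        self.next()  # 'selected'
        self.expect("LPAREN")
        ref = self.expect("XREF")
        field = ref.text[2:-1].strip().lower()
        self.expect("COMMA")
        code_tok = self.next()
        if code_tok.kind == "STRING":
            code = code_tok.text[1:-1]
        elif code_tok.kind in ("NUMBER", "WORD"):
            code = code_tok.text
        else:
            raise LogicSyntaxError("expected option code", code_tok.pos)
        self.expect("RPAREN")
        return Selected(field, code)

    def parse_comparison(self) -> LogicExpr:
        ref = self.next()
        if self.dialect == "xlsform":
            if ref.kind == "XREF":
                field = ref.text[2:-1].strip().lower()
                checkbox_code = None
            elif ref.kind == "DOT":
                field = "."
                checkbox_code = None
            else:
                raise LogicSyntaxError(
                    f"expected ${{field}} reference, found {ref.text!r}", ref.pos
                )
        else:
            if ref.kind != "RREF":
                raise LogicSyntaxError(
                    f"expected [field] reference, found {ref.text!r}", ref.pos
                )
            inner = ref.text[1:-1]
            m = re.match(r"^([\w]+)\(([^)]+)\)$", inner)
            if m:
                field = m.group(1).lower()
                checkbox_code = m.group(2)
            else:
                field = inner.lower()
                checkbox_code = None

        op_tok = self.expect("OP")
        op = {"<>": "!="}.get(op_tok.text, op_tok.text)
        if self.dialect == "xlsform" and op_tok.text == "<>":
            raise LogicSyntaxError("'<>' is redcap syntax; use '!='", op_tok.pos)
        if self.dialect == "redcap" and op_tok.text == "!=":
            raise LogicSyntaxError("'!=' is xlsform syntax; use '<>'", op_tok.pos)

        lit_tok = self.next()
        if lit_tok.kind == "STRING":
            literal = Literal(lit_tok.text[1:-1], quoted=True)
        elif lit_tok.kind == "NUMBER":
            literal = Literal(lit_tok.text, quoted=False)
        else:
            raise LogicSyntaxError(f"expected literal, found {lit_tok.text!r}", lit_tok.pos)

        if checkbox_code is not None:
            # redcap checkbox idiom [f(c)] = '1' / [f(c)] = '0'
            if op == "=" and literal.text == "1":
                return Selected(field, checkbox_code)
            if op == "=" and literal.text == "0":
                return Not(Selected(field, checkbox_code))
            raise LogicSyntaxError(
                "checkbox references support only = '1' or = '0'", op_tok.pos
            )
        return Comparison(field, op, literal)


def _flatten(items: list[LogicExpr], cls) -> list[LogicExpr]:
    out: list[LogicExpr] = []
    for item in items:
        if isinstance(item, cls):
            out.extend(item.items)
        else:
            out.append(item)
    return out


def parse_logic(text: str | None, dialect: str = "xlsform") -> LogicExpr:
    """Parse skip/branching logic text into an expression tree.

    Empty or blank text parses to :class:`TrueConst` (the field is shown
    unconditionally).
    """
    if dialect not in ("xlsform", "redcap"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if text is None or not text.strip():
        return TrueConst()
    parser = _Parser(_tokenize(text), dialect, len(text))
    expr = parser.parse_or()
    trailing = parser.peek()
    if trailing is not None:
        raise LogicSyntaxError(f"trailing input {trailing.text!r}", trailing.pos)
    return expr


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_logic(expr: LogicExpr, dialect: str = "xlsform") -> str:
    """Render a tree back to text; ``parse_logic(render_logic(e)) == e``.

    ``TrueConst`` renders to the empty string in both dialects.
    """
    if dialect not in ("xlsform", "redcap"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(expr, TrueConst):
        return ""
    return _render(expr, dialect)


def _ref(field: str, dialect: str) -> str:
    if dialect == "xlsform":
        return "." if field == "." else "${%s}" % field
    return f"[{field}]"


def _render(expr: LogicExpr, dialect: str) -> str:
    if isinstance(expr, Comparison):
        op = expr.op
        if dialect == "redcap" and op == "!=":
            op = "<>"
        return f"{_ref(expr.field, dialect)} {op} {expr.literal.render()}"
    if isinstance(expr, Selected):
        if dialect == "xlsform":
            return f"selected(${{{expr.field}}}, '{expr.code}')"
        return f"[{expr.field}({expr.code})] = '1'"
    if isinstance(expr, Not):
        return f"not({_render(expr.item, dialect)})"
    if isinstance(expr, And):
        return " and ".join(_child(i, dialect, within="and") for i in expr.items)
    if isinstance(expr, Or):
        return " or ".join(_child(i, dialect, within="or") for i in expr.items)
    raise TypeError(f"not a logic expression: {expr!r}")


def _child(expr: LogicExpr, dialect: str, within: str) -> str:
    # Or inside And needs parentheses; And inside Or kept explicit for clarity.
    needs_parens = isinstance(expr, (And, Or))
    text = _render(expr, dialect)
    return f"({text})" if needs_parens else text


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_DATETIME_RE = re.compile(r"^\d{4}-\d{2}-\d{2}[ T]\d{2}:\d{2}(:\d{2})?$")
_NUM_RE = re.compile(r"^-?\d+(\.\d+)?$")


def _coerce_pair(a: str, b: str):
    if _NUM_RE.match(a) and _NUM_RE.match(b):
        return float(a), float(b)
    if _DATE_RE.match(a) and _DATE_RE.match(b):
        return date.fromisoformat(a), date.fromisoformat(b)
    if _DATETIME_RE.match(a) and _DATETIME_RE.match(b):
        return (
            datetime.fromisoformat(a.replace("T", " ")),
            datetime.fromisoformat(b.replace("T", " ")),
        )
    return a, b


_CMP = {
    "=": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
}


def evaluate_logic(expr: LogicExpr, rec: FlatRecord) -> bool:
    """Evaluate a tree against a record's values.

    Missing or empty values make any comparison false (conservative: a
    dependent field stays hidden until its controlling question is answered).
    """
    if isinstance(expr, TrueConst):
        return True
    if isinstance(expr, Comparison):
        value = rec.values.get(expr.field)
        if value is None or str(value) == "":
            return False
        a, b = _coerce_pair(str(value), expr.literal.text)
        return _CMP[expr.op](a, b)
    if isinstance(expr, Selected):
        expanded = rec.values.get(f"{expr.field}___{expr.code}")
        if expanded is not None:
            return str(expanded) in ("1", "True", "true")
        raw = rec.values.get(expr.field)
        if raw is None:
            return False
        return expr.code in str(raw).split()
    if isinstance(expr, And):
        return all(evaluate_logic(i, rec) for i in expr.items)
    if isinstance(expr, Or):
        return any(evaluate_logic(i, rec) for i in expr.items)
    if isinstance(expr, Not):
        return not evaluate_logic(expr.item, rec)
    raise TypeError(f"not a logic expression: {expr!r}")
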