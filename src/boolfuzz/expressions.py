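"""Logic expression trees shared by the discrete and fuzzy engines.

An expression is an immutable tree over node identifiers with the
connectives AND, OR and NOT plus the constants 0/1.  The same tree is
evaluated in two ways: as a Boolean proposition on {0, 1} assignments
(discrete update rules) and as a fuzzy proposition on [0, 1] levels
(continuous input functions), so it is the single point of truth for
what a regulatory rule *says*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class ExpressionError(ValueError):
    """Malformed rule text or an invalid expression tree."""


@dataclass(frozen=True)
class Expr:
    """Base class for logic expression nodes."""

    def variables(self) -> frozenset[str]:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def variables(self) -> frozenset[str]:
        return frozenset({self.name})

    def __str__(self) -> str:
        return self.name


@dataclass(frozen=True)
class Const(Expr):
    value: int  # 0 or 1

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ExpressionError(f"constant must be 0 or 1, got {self.value!r}")

    def variables(self) -> frozenset[str]:
        return frozenset()

    def __str__(self) -> str:
        return str(self.value)


@dataclass(frozen=True)
class Not(Expr):
    child: Expr

    def variables(self) -> frozenset[str]:
        return self.child.variables()

    def __str__(self) -> str:
        if isinstance(self.child, (Var, Const, Not)):
            return f"!{self.child}"
        return f"!({self.child})"


@dataclass(frozen=True)
class _Nary(Expr):
    children: tuple[Expr, ...]

    _symbol = "?"

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ExpressionError(
                f"{type(self).__name__} needs at least 2 children, "
                f"got {len(self.children)}"
            )

    def variables(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.variables()
        return out

    def __str__(self) -> str:
        parts = []
        for c in self.children:
            if isinstance(c, _Nary) and type(c) is not type(self):
                parts.append(f"({c})")
            elif isinstance(c, _Nary):
                parts.append(f"({c})")
            else:
                parts.append(str(c))
        return f" {self._symbol} ".join(parts)


class And(_Nary):
    _symbol = "&"


class Or(_Nary):
    _symbol = "|"


def evaluate(expr: Expr, assignment: Mapping[str, int]):
    """Evaluate ``expr`` on a binary assignment (0/1 scalars or 0/1 arrays).

    Uses the arithmetic realisation of the connectives (``a·b``,
    ``a+b−a·b``, ``1−a``) which coincides with Boolean evaluation on
    binary inputs and works elementwise on numpy arrays, so a rule can
    be applied to a whole batch of states at once.
    """
    if isinstance(expr, Var):
        try:
            return assignment[expr.name]
        except KeyError:
            raise ExpressionError(f"unassigned variable {expr.name!r}") from None
    if isinstance(expr, Const):
        return expr.value
    if isinstance(expr, Not):
        return 1 - evaluate(expr.child, assignment)
    if isinstance(expr, And):
        out = evaluate(expr.children[0], assignment)
        for c in expr.children[1:]:
            out = out * evaluate(c, assignment)
        return out
    if isinstance(expr, Or):
        out = evaluate(expr.children[0], assignment)
        for c in expr.children[1:]:
            nxt = evaluate(c, assignment)
            out = out + nxt - out * nxt
        return out
    raise ExpressionError(f"unknown expression node {expr!r}")


def eval_binary(expr: Expr, assignment: Mapping[str, int]) -> int:
    """Evaluate on a strict 0/1 assignment, returning 0 or 1."""
    val = evaluate(expr, {k: int(v) for k, v in assignment.items()})
    return int(val)


def iter_subexpressions(expr: Expr) -> Iterator[Expr]:
    yield expr
    if isinstance(expr, Not):
        yield from iter_subexpressions(expr.child)
    elif isinstance(expr, _Nary):
        for c in expr.children:
            yield from iter_subexpressions(c)


def flatten(expr: Expr) -> Expr:
    """Normalize by flattening nested AND/OR of the same kind and
    collapsing double negation.  Keeps child order (deduplicated)."""
    if isinstance(expr, (Var, Const)):
        return expr
    if isinstance(expr, Not):
        child = flatten(expr.child)
        if isinstance(child, Not):
            return child.child
        if isinstance(child, Const):
            return Const(1 - child.value)
        return Not(child)
    assert isinstance(expr, _Nary)
    kind = type(expr)
    out: list[Expr] = []
    for c in expr.children:
        c = flatten(c)
        if isinstance(c, kind):
            out.extend(c.children)
        else:
            out.append(c)
    seen: list[Expr] = []
    for c in out:
        if c not in seen:
            seen.append(c)
    if len(seen) == 1:
        return seen[0]
    return kind(tuple(seen))


# ---------------------------------------------------------------------------
# Parsing of the rule-expression dialect: identifiers, !, &, |, parentheses,
# constants 0/1.  Precedence: ! > & > |.

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])"
    r"|(?P<op>[!&|()])|(?P<bad>\S))"
)

_WORD_OPS = {"not": "!", "and": "&", "or": "|", "NOT": "!", "AND": "&", "OR": "|"}


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        if m.group("bad"):
            raise ExpressionError(f"unexpected character {m.group('bad')!r}")
        tok = m.group("name") or m.group("const") or m.group("op")
        tokens.append(_WORD_OPS.get(tok, tok))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ExpressionError("unexpected end of expression")
        self.pos += 1
        return tok

    def parse(self) -> Expr:
        expr = self.parse_or()
        if self.peek() is not None:
            raise ExpressionError(f"trailing token {self.peek()!r}")
        return expr

    def parse_or(self) -> Expr:
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> Expr:
        factors = [self.parse_unary()]
        while self.peek() == "&":
            self.take()
            factors.append(self.parse_unary())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_unary(self) -> Expr:
        tok = self.take()
        if tok == "!":
            return Not(self.parse_unary())
        if tok == "(":
            inner = self.parse_or()
            if self.take() != ")":
                raise ExpressionError("expected closing parenthesis")
            return inner
        if tok in ("0", "1"):
            return Const(int(tok))
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok):
            return Var(tok)
        raise ExpressionError(f"unexpected token {tok!r}")


def parse_expression(text: str) -> Expr:
    """Parse a single rule expression (``!``, ``&``, ``|``, parentheses;
    ``not/and/or`` keywords also accepted)."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    return _Parser(tokens).parse()
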