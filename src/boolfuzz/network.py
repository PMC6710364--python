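"""Boolean regulatory networks and the plain-text rule-file dialect.

A network is an ordered set of named nodes, one update rule per
non-input node.  Input nodes (microenvironmental signals such as a
cytokine) carry no rule: their value is clamped per scenario, matching
the convention that external cues are "either absent or present".

Rule files have one ``target, expression`` line per node, ``#``
comments, operators ``!``/``&``/``|`` and parentheses (a bnet-style
dialect).  Inputs are declared either through an ``inputs:`` header or
by giving a node the identity rule (``A, A``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .expressions import Expr, Var, ExpressionError, parse_expression


class RuleFileError(ValueError):
    """Rule text that cannot be turned into a valid network."""


@dataclass(frozen=True, eq=True, unsafe_hash=False)
class BooleanNetwork:
    """An ordered node set with one logic rule per non-input node."""

    nodes: tuple[str, ...]
    rules: dict[str, Expr]
    inputs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise RuleFileError("duplicate node names")
        if not self.nodes:
            raise RuleFileError("network has no nodes")
        for inp in self.inputs:
            if inp not in node_set:
                raise RuleFileError(f"input {inp!r} is not a declared node")
            if inp in self.rules:
                raise RuleFileError(f"input {inp!r} must not carry a rule")
        for node in self.free_nodes:
            if node not in self.rules:
                raise RuleFileError(f"missing rule for node {node!r}")
        for target, expr in self.rules.items():
            if target not in node_set:
                raise RuleFileError(f"rule target {target!r} is not a node")
            undeclared = expr.variables() - node_set
            if undeclared:
                raise RuleFileError(
                    f"rule for {target!r} references undeclared "
                    f"node(s) {sorted(undeclared)}"
                )

    @property
    def free_nodes(self) -> tuple[str, ...]:
        """Nodes that are updated by a rule (everything except inputs)."""
        return tuple(n for n in self.nodes if n not in self.inputs)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, name: str) -> int:
        try:
            return self.nodes.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    def regulators(self, node: str) -> frozenset[str]:
        """Names appearing in the rule of ``node`` (empty for inputs)."""
        rule = self.rules.get(node)
        return rule.variables() if rule is not None else frozenset()

    def replace_rules(self, new_rules: dict[str, Expr]) -> "BooleanNetwork":
        merged = dict(self.rules)
        merged.update(new_rules)
        return BooleanNetwork(self.nodes, merged, self.inputs)


def parse_rules(text: str) -> BooleanNetwork:
    """Parse rule-file content into a validated :class:`BooleanNetwork`.

    Node order is file order, with header-declared inputs first.
    Raises :class:`RuleFileError` with the offending line number.
    """
    inputs: list[str] = []
    order: list[str] = []
    rules: dict[str, Expr] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("inputs:"):
            for name in line.split(":", 1)[1].replace(",", " ").split():
                if name in inputs:
                    raise RuleFileError(f"line {lineno}: duplicate input {name!r}")
                inputs.append(name)
            continue
        if "," not in line:
            raise RuleFileError(
                f"line {lineno}: expected 'target, expression', got {line!r}"
            )
        target, expr_text = line.split(",", 1)
        target = target.strip()
        if not target.isidentifier():
            raise RuleFileError(f"line {lineno}: invalid node name {target!r}")
        if target in rules or target in inputs:
            raise RuleFileError(f"line {lineno}: duplicate rule for {target!r}")
        try:
            expr = parse_expression(expr_text)
        except ExpressionError as exc:
            raise RuleFileError(f"line {lineno}: {exc}") from exc
        if expr == Var(target):
            # self-identity rule declares an input node
            inputs.append(target)
        else:
            rules[target] = expr
        order.append(target)

    nodes = [n for n in inputs if n not in order] + order
    try:
        return BooleanNetwork(tuple(nodes), rules, tuple(inputs))
    except RuleFileError:
        raise
    except ExpressionError as exc:  # pragma: no cover - defensive
        raise RuleFileError(str(exc)) from exc


def serialize_rules(net: BooleanNetwork) -> str:
    """Serialize a network so that ``parse_rules`` round-trips it."""
    lines: list[str] = []
    if net.inputs:
        lines.append("inputs: " + ", ".join(net.inputs))
    for node in net.nodes:
        if node in net.inputs:
            continue
        lines.append(f"{node}, {net.rules[node]}")
    return "\n".join(lines) + "\n"
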