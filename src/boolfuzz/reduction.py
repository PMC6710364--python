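"""Logical model reduction: absorption simplification and collapse of
linear downstream chains.

Large rule sets often contain nodes that merely relay the state of a
single upstream regulator (``q3 = q2`` with ``q2 = not q1`` collapses
to ``q3 = q2 = not q1``).  Removing such nodes, substituting their
rules into every rule that references them, and simplifying with the
Boolean absorption law ``a and (a or b) = a`` (and its dual) shrinks
the state space while preserving the fixed-point attractors: at a
fixed point the removed node's value is exactly its rule's value, so
the substitution is an identity there.  Cyclic attractors under
synchronous update are *not* guaranteed to survive (collapsing a relay
node shortens feedback delays), so cycle counts are compared and
reported, never asserted.

Nodes that sit on a feedback circuit (including self-loops) are never
collapsed - removing them would rewire the circuit itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .boolean import StateSpaceError, find_attractors
from .expressions import And, Const, Expr, Not, Or, Var, flatten
from .network import BooleanNetwork


def simplify_absorption(expr: Expr) -> Expr:
    """Apply flattening, identity laws and absorption to a fixed point.

    The result is logically equivalent to the input (an exhaustive
    truth-table check backs this for expressions of up to 16
    variables) and no further absorption applies.
    """
    prev = None
    current = flatten(expr)
    while current != prev:
        prev = current
        current = flatten(_absorb(current))
    return current


def _absorb(expr: Expr) -> Expr:
    if isinstance(expr, (Var, Const)):
        return expr
    if isinstance(expr, Not):
        return Not(_absorb(expr.child))
    assert isinstance(expr, (And, Or))
    kind = type(expr)
    dual = Or if kind is And else And
    children = [_absorb(c) for c in expr.children]

    # identity / annihilator constants
    identity = 1 if kind is And else 0
    annihilator = 1 - identity
    if any(c == Const(annihilator) for c in children):
        return Const(annihilator)
    children = [c for c in children if c != Const(identity)]
    if not children:
        return Const(identity)

    # absorption: inside an AND, drop any OR-child that contains another
    # child as one of its own terms (a & (a | b) = a), and dually.
    kept: list[Expr] = []
    for c in children:
        absorbed = False
        if isinstance(c, dual):
            inner = set(c.children)
            for other in children:
                if other is not c and not isinstance(other, dual) and other in inner:
                    absorbed = True
                    break
            if not absorbed:
                # also absorbed if another dual-child's terms are a subset
                for other in children:
                    if (
                        other is not c
                        and isinstance(other, dual)
                        and set(other.children) < inner
                    ):
                        absorbed = True
                        break
        if not absorbed:
            kept.append(c)
    if len(kept) == 1:
        return kept[0]
    return kind(tuple(kept))


@dataclass(frozen=True)
class ReductionReport:
    """What a reduction removed and whether attractors survived.

    ``removed`` maps each eliminated node, in removal order, to its
    back-substituted expression over retained nodes, so steady values
    of removed nodes are recoverable from a reduced steady state.
    """

    removed: tuple[tuple[str, Expr], ...]
    retained: tuple[str, ...]
    checks: "PreservationResult | None" = None


@dataclass(frozen=True)
class PreservationResult:
    """Fixed-point comparison between an original and a reduced model.

    ``fixed_points_preserved`` asserts set equality after
    back-substitution; cyclic counts are informational only.
    """

    fixed_points_preserved: bool
    original_fixed_points: int
    reduced_fixed_points: int
    original_cyclic: int
    reduced_cyclic: int


def _substitute(expr: Expr, name: str, replacement: Expr) -> Expr:
    if isinstance(expr, Var):
        return replacement if expr.name == name else expr
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Not):
        return Not(_substitute(expr.child, name, replacement))
    assert isinstance(expr, (And, Or))
    return type(expr)(
        tuple(_substitute(c, name, replacement) for c in expr.children)
    )


def _cycle_nodes(net: BooleanNetwork) -> set[str]:
    """Nodes lying on some feedback circuit (incl. self-loops)."""
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for node in net.free_nodes:
        for reg in net.regulators(node):
            g.add_edge(reg, node)
    on_cycle: set[str] = set()
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1:
            on_cycle |= scc
        else:
            (node,) = scc
            if g.has_edge(node, node):
                on_cycle.add(node)
    return on_cycle


def collapse_linear_chains(
    net: BooleanNetwork,
) -> tuple[BooleanNetwork, ReductionReport]:
    """Iteratively remove relay nodes on linear downstream pathways.

    A node is removable when its (absorption-simplified) rule depends
    on exactly one other node and it does not sit on a feedback
    circuit.  Removal substitutes the node's rule into every rule that
    references it, in deterministic file (node) order, until no
    removable node remains.  Irreducible networks come back unchanged.
    """
    rules = {nm: simplify_absorption(e) for nm, e in net.rules.items()}
    nodes = list(net.nodes)
    removed: list[tuple[str, Expr]] = []

    while True:
        g_net = BooleanNetwork(tuple(nodes), dict(rules), net.inputs)
        on_cycle = _cycle_nodes(g_net)
        candidate = None
        for nm in nodes:
            if nm in net.inputs or nm in on_cycle:
                continue
            deps = rules[nm].variables()
            if len(deps) == 1 and nm not in deps:
                candidate = nm
                break
        if candidate is None:
            break
        expr = rules.pop(candidate)
        nodes.remove(candidate)
        rules = {
            nm: simplify_absorption(_substitute(e, candidate, expr))
            for nm, e in rules.items()
        }
        # keep earlier back-substitutions closed over retained nodes
        removed = [
            (nm, simplify_absorption(_substitute(e, candidate, expr)))
            for nm, e in removed
        ]
        removed.append((candidate, expr))

    reduced = BooleanNetwork(tuple(nodes), rules, net.inputs)
    report = ReductionReport(
        removed=tuple(removed), retained=tuple(nodes), checks=None
    )
    return reduced, report


def back_substitute(
    report: ReductionReport, reduced_state: dict[str, int]
) -> dict[str, int]:
    """Extend a reduced-network state to all original nodes."""
    from .expressions import eval_binary

    full = dict(reduced_state)
    for nm, expr in report.removed:
        full[nm] = eval_binary(expr, full)
    return full


def verify_preservation(
    original: BooleanNetwork,
    reduced: BooleanNetwork,
    report: ReductionReport,
) -> PreservationResult:
    """Compare fixed-point attractors before and after reduction.

    The reduced network's fixed points, extended by back-substitution,
    must equal the original's fixed points exactly; cyclic attractor
    counts are recorded for information (synchronous reduction may
    legitimately change them).
    """
    orig_atts = find_attractors(original, "all")
    red_atts = find_attractors(reduced, "all")

    orig_fps = {
        a.states[0] for a in orig_atts if a.kind == "fixed_point"
    }
    red_fps_extended = set()
    for a in red_atts:
        if a.kind != "fixed_point":
            continue
        state = dict(zip(reduced.nodes, a.states[0]))
        full = back_substitute(report, state)
        red_fps_extended.add(tuple(full[nm] for nm in original.nodes))

    return PreservationResult(
        fixed_points_preserved=orig_fps == red_fps_extended,
        original_fixed_points=len(orig_fps),
        reduced_fixed_points=sum(
            a.kind == "fixed_point" for a in red_atts
        ),
        original_cyclic=sum(a.kind == "cyclic" for a in orig_atts),
        reduced_cyclic=sum(a.kind == "cyclic" for a in red_atts),
    )


def reduce_network(
    net: BooleanNetwork, verify: bool = True
) -> tuple[BooleanNetwork, ReductionReport]:
    """Collapse linear chains and (optionally) verify fixed-point
    preservation by exhaustive enumeration of both models."""
    reduced, report = collapse_linear_chains(net)
    if verify:
        try:
            checks = verify_preservation(net, reduced, report)
        except StateSpaceError:
            checks = None
        report = ReductionReport(
            removed=report.removed, retained=report.retained, checks=checks
        )
    return reduced, report
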