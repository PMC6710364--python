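"""Bundled fixture networks and a scale-free random-network generator.

The fixtures are small regulatory circuits used throughout the test
suite and documentation:

``bpc``
    The transcriptional core driving naive B cell to plasma-cell
    differentiation (Pax-5 / Bcl-6 / Blimp-1 / AP-1, LPS as input).
``nfkb``
    The NF-kB negative-feedback signaling core (TNFa as input).
``toggle``
    Two mutual repressors - the canonical bistable switch.
``negring3``
    A three-node ring with one inhibition - the minimal negative
    circuit, which oscillates and has no fixed point.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import numpy as np

from .expressions import And, Expr, Not, Or, Var
from .network import BooleanNetwork, parse_rules, serialize_rules  # noqa: F401

FIXTURE_NAMES = ("bpc", "nfkb", "toggle", "negring3")


def fixture_text(name: str) -> str:
    """Raw rule-file content of a bundled fixture."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return (
        resources.files("boolfuzz") / "fixtures" / f"{name}.txt"
    ).read_text(encoding="utf-8")


def load_fixture(name: str) -> BooleanNetwork:
    """Load one of the bundled fixture networks by name."""
    return parse_rules(fixture_text(name))


def random_network(n: int, seed: int, wiring: int = 2) -> BooleanNetwork:
    """Generate a random Boolean network with scale-free topology.

    The undirected skeleton comes from preferential attachment
    (Barabasi-Albert with attachment parameter ``wiring``), so a few
    hubs accumulate many links while most nodes keep few - the
    heavy-tailed degree structure typical of biological networks.
    Each edge is then oriented at random, every node is guaranteed at
    least one regulator, and each rule is a random AND/OR composition
    of its (possibly negated) regulators.  Self-loops are not
    generated.  Deterministic for a fixed ``(n, seed, wiring)``.
    """
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")
    rng = np.random.default_rng(seed)
    m = max(1, min(wiring, n - 1))
    skeleton = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    names = [f"G{i}" for i in range(n)]

    regulators: dict[str, list[str]] = {name: [] for name in names}
    for u, v in sorted(skeleton.edges()):
        if rng.random() < 0.5:
            u, v = v, u
        regulators[names[v]].append(names[u])
    for name, idx in zip(names, range(n)):
        if not regulators[name]:
            others = [nm for nm in names if nm != name]
            regulators[name].append(others[int(rng.integers(len(others)))])

    rules = {
        name: _random_rule(regulators[name], rng) for name in names
    }
    return BooleanNetwork(tuple(names), rules, inputs=())


def _random_rule(regulators: list[str], rng: np.random.Generator) -> Expr:
    """Random AND/OR tree over the given regulators, each possibly negated."""
    literals: list[Expr] = [
        Not(Var(r)) if rng.random() < 0.5 else Var(r) for r in regulators
    ]
    rng.shuffle(literals)  # type: ignore[arg-type]
    expr = literals[0]
    for lit in literals[1:]:
        op = And if rng.random() < 0.5 else Or
        if isinstance(expr, op):
            expr = op(expr.children + (lit,))
        else:
            expr = op((expr, lit))
    return expr
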