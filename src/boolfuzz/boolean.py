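"""Synchronous discrete dynamics of Boolean regulatory networks.

All nodes update simultaneously: ``q_k(t+1) = F_k(q_1(t), ..., q_n(t))``.
Because the map is deterministic on a finite state space, every
trajectory ends in a fixed point (``q(t+1) = q(t)``) or a cycle of
period N (``q(t+N) = q(t)``).  Exhaustive enumeration over all initial
states per input configuration yields, for each attractor, the basin
size ``omega`` and the expression probability ``p = omega / Omega``
with ``Omega = 2^(number of free nodes)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .expressions import Const, evaluate
from .network import BooleanNetwork

#: refuse exhaustive enumeration beyond this many states per configuration
STATE_SPACE_GUARD = 2**22


class StateSpaceError(ValueError):
    """State space too large for exhaustive enumeration."""


State = tuple[int, ...]


@dataclass(frozen=True)
class Attractor:
    """A fixed point (period 1) or cycle of the synchronous dynamics.

    ``states`` holds full network states (inputs included) in cycle
    order, rotated so the lexicographically smallest state comes first.
    ``basin_size`` counts initial free-node states, within the input
    configuration recorded in ``inputs``, whose trajectories end here;
    ``probability`` is basin_size / state-space size.
    """

    states: tuple[State, ...]
    basin_size: int
    probability: float
    inputs: dict[str, int] = field(default_factory=dict)

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def kind(self) -> str:
        return "fixed_point" if self.period == 1 else "cyclic"

    def free_profile(self, net: BooleanNetwork) -> tuple[State, ...]:
        """Cycle states restricted to the free (non-input) nodes."""
        idx = [net.index(n) for n in net.free_nodes]
        return tuple(tuple(s[i] for i in idx) for s in self.states)


@dataclass(frozen=True)
class Perturbation:
    """A genetic or signaling perturbation of one node.

    ``knockout`` clamps the node to 0 and ``overexpression`` to 1,
    permanently (the rule is replaced by a constant).  ``pulse`` forces
    the node to ``value`` for ``duration`` update steps and is honored
    by :func:`trajectory`.
    """

    node: str
    mode: str  # knockout | overexpression | pulse
    duration: int | None = None  # steps, pulses only
    value: int = 1  # pulse level

    def __post_init__(self) -> None:
        if self.mode not in ("knockout", "overexpression", "pulse"):
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        if self.mode == "pulse" and (self.duration is None or self.duration < 1):
            raise ValueError("pulse perturbations need duration >= 1")


def _check_state(net: BooleanNetwork, s) -> State:
    s = tuple(int(v) for v in s)
    if len(s) != net.n:
        raise ValueError(
            f"state has {len(s)} entries but network has {net.n} nodes"
        )
    if any(v not in (0, 1) for v in s):
        raise ValueError("state entries must be 0 or 1")
    return s


def synchronous_step(net: BooleanNetwork, s) -> State:
    """One synchronous update; clamped inputs keep their value."""
    s = _check_state(net, s)
    env = dict(zip(net.nodes, s))
    return tuple(
        s[i] if name in net.inputs else evaluate(net.rules[name], env)
        for i, name in enumerate(net.nodes)
    )


def trajectory(
    net: BooleanNetwork,
    s0,
    max_steps: int = 10_000,
    pulse: Perturbation | None = None,
) -> tuple[list[State], Attractor]:
    """Iterate the synchronous map from ``s0`` until a state repeats.

    Returns the visited states (including ``s0`` and the first repeat
    of the attractor entry state) and the attractor reached.  A pulse
    perturbation, if given, clamps its node for the first
    ``pulse.duration`` steps.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if pulse is not None and pulse.mode != "pulse":
        raise ValueError("only pulse perturbations are applied to trajectories")

    s = _check_state(net, s0)
    states: list[State] = []

    if pulse is not None:
        i = net.index(pulse.node)
        for _ in range(pulse.duration):
            s = s[:i] + (pulse.value,) + s[i + 1:]
            states.append(s)
            s = synchronous_step(net, s)

    seen: dict[State, int] = {}
    offset = len(states)
    for t in itertools.count():
        if s in seen:
            cycle = states[offset + seen[s]:]
            states.append(s)
            break
        seen[s] = t
        states.append(s)
        if t >= max_steps:
            raise RuntimeError("max_steps exceeded without revisit")
        s = synchronous_step(net, s)

    inputs = {n: states[-1][net.index(n)] for n in net.inputs}
    attractor = Attractor(
        states=_canonical_cycle(tuple(cycle)),
        basin_size=0,
        probability=0.0,
        inputs=inputs,
    )
    return states, attractor


def _canonical_cycle(cycle: tuple[State, ...]) -> tuple[State, ...]:
    """Rotate a cycle so the lexicographically smallest state is first."""
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return cycle[k:] + cycle[:k]


def apply_perturbation(net: BooleanNetwork, pert: Perturbation) -> BooleanNetwork:
    """Return the network with a permanent knockout/overexpression applied.

    The perturbed node's rule is replaced by the corresponding constant
    (and the node is no longer treated as an input, since its value is
    now fixed by the mutation).  Pulses are transient and must be passed
    to :func:`trajectory` instead.
    """
    net.index(pert.node)
    if pert.mode == "pulse":
        raise ValueError("pulse perturbations are applied by trajectory()")
    value = 0 if pert.mode == "knockout" else 1
    rules = dict(net.rules)
    rules[pert.node] = Const(value)
    inputs = tuple(n for n in net.inputs if n != pert.node)
    return BooleanNetwork(net.nodes, rules, inputs)


# ---------------------------------------------------------------------------
# Exhaustive attractor search


def _input_configs(net: BooleanNetwork, input_config) -> list[dict[str, int]]:
    if input_config == "all" or input_config is None and net.inputs:
        return [
            dict(zip(net.inputs, combo))
            for combo in itertools.product((0, 1), repeat=len(net.inputs))
        ]
    if input_config is None:
        return [{}]
    cfg = {str(k): int(v) for k, v in dict(input_config).items()}
    unknown = set(cfg) - set(net.inputs)
    if unknown:
        raise KeyError(f"not input nodes: {sorted(unknown)}")
    missing = set(net.inputs) - set(cfg)
    if missing:
        raise KeyError(f"missing input values for {sorted(missing)}")
    return [cfg]


def _successor_table(net: BooleanNetwork, cfg: dict[str, int]) -> np.ndarray:
    """Vectorized successor function over all free-node states.

    State ``i`` encodes free-node values as bits (free node j ->
    bit j); returns ``succ`` with ``succ[i]`` the successor index.
    """
    free = net.free_nodes
    n_free = len(free)
    omega = 1 << n_free
    if omega > STATE_SPACE_GUARD:
        raise StateSpaceError(
            f"state space 2^{n_free} exceeds the enumeration guard "
            f"(2^22); reduce the model first"
        )
    idx = np.arange(omega, dtype=np.int64)
    env: dict[str, np.ndarray | int] = {name: val for name, val in cfg.items()}
    for j, name in enumerate(free):
        env[name] = (idx >> j) & 1
    succ = np.zeros(omega, dtype=np.int64)
    for j, name in enumerate(free):
        col = np.asarray(evaluate(net.rules[name], env))
        succ |= (col.astype(np.int64) & 1) << j
    return succ


def _decode(net: BooleanNetwork, code: int, cfg: dict[str, int]) -> State:
    free = net.free_nodes
    bits = {name: (code >> j) & 1 for j, name in enumerate(free)}
    return tuple(
        cfg[name] if name in cfg else bits[name] for name in net.nodes
    )


def find_attractors(net: BooleanNetwork, input_config="all") -> list[Attractor]:
    """Exhaustive synchronous attractor search with basin sizes.

    ``input_config`` is a mapping input-name -> 0/1, or ``"all"`` to
    enumerate every input combination.  Within each configuration all
    ``Omega = 2^(free nodes)`` initial states are tracked to their
    attractor (memoized, O(Omega) total), so basins partition the state
    space and probabilities sum to 1 per configuration.
    """
    out: list[Attractor] = []
    for cfg in _input_configs(net, input_config):
        succ = _successor_table(net, cfg)
        omega_total = len(succ)
        # label[i]: -1 unvisited, -2 on current path, else attractor id
        label = np.full(omega_total, -1, dtype=np.int64)
        cycles: list[list[int]] = []
        basins: list[int] = []
        for start in range(omega_total):
            if label[start] != -1:
                continue
            path: list[int] = []
            s = start
            while label[s] == -1:
                label[s] = -2
                path.append(s)
                s = int(succ[s])
            if label[s] == -2:
                # new cycle discovered along this path
                cyc_start = path.index(s)
                cycle = path[cyc_start:]
                aid = len(cycles)
                cycles.append(cycle)
                basins.append(0)
            else:
                aid = int(label[s])
            for v in path:
                label[v] = aid
            basins[aid] += len(path)
        for cycle, omega in zip(cycles, basins):
            states = tuple(_decode(net, code, cfg) for code in cycle)
            out.append(
                Attractor(
                    states=_canonical_cycle(states),
                    basin_size=omega,
                    probability=omega / omega_total,
                    inputs=dict(cfg),
                )
            )
    return sorted(out, key=lambda a: (tuple(sorted(a.inputs.items())), a.states))


def attractor_census(
    net: BooleanNetwork, input_config="all"
) -> list[Attractor]:
    """Attractors with duplicates across input configurations merged.

    Two attractors are the same census entry when their free-node state
    profiles coincide (an attractor indifferent to an input shows up
    once per input value in :func:`find_attractors`).  Basin sizes are
    summed over the merged configurations; the probability becomes the
    summed basin over the total number of enumerated initial states.
    """
    per_cfg = find_attractors(net, input_config)
    n_cfg = len({tuple(sorted(a.inputs.items())) for a in per_cfg}) or 1
    merged: dict[tuple, Attractor] = {}
    for att in per_cfg:
        key = att.free_profile(net)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                basin_size=prev.basin_size + att.basin_size,
                probability=prev.probability + att.probability / n_cfg,
            )
        else:
            merged[key] = replace(att, probability=att.probability / n_cfg)
    return list(merged.values())
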