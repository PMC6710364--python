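"""Deterministic continuous dynamics of fuzzified regulatory networks.

Each free node follows

    dq_k/dt = mu[w_k(q_1, ..., q_n)] - alpha_k * q_k

where ``w_k`` is the fuzzy translation of the node's Boolean rule,
``mu`` the membership function, and ``alpha_k`` a first-order decay
rate with characteristic time ``tau_k = 1/alpha_k`` (a faster decay
means a shorter timescale; the ordering of the alphas induces the
reverse ordering of the taus).  Clamped inputs have zero derivative.

Steady states satisfy ``q_k^s = mu[w_k(q^s)] / alpha_k``: a node with
``alpha_k > 1`` equilibrates below its input function value and is
completely inhibited as ``alpha_k >> 1``, while ``alpha_k < 1``
over-expresses it (levels above 1 are allowed by the formalism).

In the limit ``beta >> 1`` with all ``alpha_k = 1`` the fixed-point
attractors of the continuous system coincide with the Boolean ones by
construction; cyclic attractors generally differ, typically appearing
as damped or sustained oscillations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .boolean import find_attractors
from .fuzzy import FuzzyScheme, MembershipSpec, fuzzify, membership
from .network import BooleanNetwork


@dataclass(frozen=True)
class FuzzyConfig:
    """Run configuration for the continuous (and stochastic) dynamics.

    ``alpha`` is either one global decay rate or a per-node map
    (nodes not listed fall back to ``alpha_default``); all rates must
    be positive.  ``clamp_inputs`` fixes the level of each input node.
    ``w_thr_overrides`` optionally overrides the membership threshold
    per node (a transcriptional event may switch at a different
    proposition value than a fast biochemical one).
    """

    alpha: Mapping[str, float] = field(default_factory=dict)
    alpha_default: float = 1.0
    membership: MembershipSpec = MembershipSpec()
    scheme: str = "probabilistic"
    clamp_inputs: Mapping[str, float] = field(default_factory=dict)
    w_thr_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.alpha_default > 0:
            raise ValueError("alpha_default must be positive")
        for node, a in self.alpha.items():
            if not a > 0:
                raise ValueError(f"alpha[{node!r}] must be positive, got {a}")

    def alpha_for(self, node: str) -> float:
        return float(self.alpha.get(node, self.alpha_default))

    def tau_for(self, node: str) -> float:
        """Characteristic expression time tau = 1/alpha."""
        return 1.0 / self.alpha_for(node)

    def spec_for(self, node: str) -> MembershipSpec:
        if node in self.w_thr_overrides:
            return replace(self.membership, w_thr=self.w_thr_overrides[node])
        return self.membership


@dataclass(frozen=True)
class Trajectory:
    """Time grid plus the level of every node along it."""

    times: np.ndarray  # (T,)
    levels: np.ndarray  # (T, n)
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.levels)):
            raise ValueError("trajectory levels must be finite")

    def node_series(self, name: str) -> np.ndarray:
        return self.levels[:, self.nodes.index(name)]

    @property
    def final(self) -> np.ndarray:
        return self.levels[-1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.levels, columns=list(self.nodes))
        frame.insert(0, "time", self.times)
        return frame


@dataclass(frozen=True)
class SteadyState:
    """Outcome of a steady-state search.

    ``converged`` means the max-norm residual ``|dq/dt|`` stayed below
    the tolerance for a full hold window; then the self-consistency
    ``q_k^s = mu[w_k(q^s)] / alpha_k`` holds to within a small multiple
    of that tolerance.  ``oscillatory`` is set when the residual's
    window maxima stop decreasing - a sustained oscillation.
    """

    levels: np.ndarray
    residual: float
    converged: bool
    hold_time: float
    oscillatory: bool = False
    window_residuals: tuple[float, ...] = ()
    nodes: tuple[str, ...] = ()


class _System:
    """Network + config compiled to a vectorized ODE right-hand side."""

    def __init__(self, net: BooleanNetwork, cfg: FuzzyConfig):
        missing = set(net.inputs) - set(cfg.clamp_inputs)
        if missing:
            raise ValueError(f"inputs need clamp levels: {sorted(missing)}")
        unknown = set(cfg.clamp_inputs) - set(net.inputs)
        if unknown:
            raise ValueError(f"clamped names are not inputs: {sorted(unknown)}")
        self.net = net
        self.cfg = cfg
        scheme = FuzzyScheme.from_name(cfg.scheme)
        self.alpha = np.array([cfg.alpha_for(nm) for nm in net.nodes])
        self.free_idx = np.array(
            [i for i, nm in enumerate(net.nodes) if nm not in net.inputs],
            dtype=int,
        )
        self._funcs: list[tuple[int, Callable, MembershipSpec]] = [
            (net.index(nm), fuzzify(net.rules[nm], scheme), cfg.spec_for(nm))
            for nm in net.free_nodes
        ]
        self.clamp = np.zeros(net.n)
        self.clamp_mask = np.zeros(net.n, dtype=bool)
        for nm, level in cfg.clamp_inputs.items():
            self.clamp[net.index(nm)] = float(level)
            self.clamp_mask[net.index(nm)] = True

    def propositions(self, q: np.ndarray) -> np.ndarray:
        """Fuzzy proposition value w_k for every free node (batch-aware)."""
        values = {nm: q[..., i] for i, nm in enumerate(self.net.nodes)}
        out = np.zeros(q.shape[:-1] + (len(self._funcs),))
        for j, (_, func, _) in enumerate(self._funcs):
            out[..., j] = func(values)
        return out

    def rhs(self, q: np.ndarray) -> np.ndarray:
        values = {nm: q[..., i] for i, nm in enumerate(self.net.nodes)}
        dq = np.zeros_like(q, dtype=float)
        for i, func, spec in self._funcs:
            mu = membership(func(values), spec)
            dq[..., i] = mu - self.alpha[i] * q[..., i]
        return dq

    def apply_clamp(self, q: np.ndarray) -> np.ndarray:
        q = np.array(q, dtype=float)
        q[..., self.clamp_mask] = self.clamp[self.clamp_mask]
        return q

    def step_rk4(self, q: np.ndarray, dt: float) -> np.ndarray:
        k1 = self.rhs(q)
        k2 = self.rhs(q + 0.5 * dt * k1)
        k3 = self.rhs(q + 0.5 * dt * k2)
        k4 = self.rhs(q + dt * k3)
        return q + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    def step_euler(self, q: np.ndarray, dt: float) -> np.ndarray:
        return q + dt * self.rhs(q)


def ode_rhs(net: BooleanNetwork, cfg: FuzzyConfig, q) -> np.ndarray:
    """Derivative vector ``mu[w_k(q)] - alpha_k q_k`` (0 for inputs)."""
    system = _System(net, cfg)
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != net.n:
        raise ValueError(f"state has {q.shape[-1]} entries, expected {net.n}")
    return system.rhs(q)


def integrate(
    net: BooleanNetwork,
    cfg: FuzzyConfig,
    q0,
    t_max: float,
    dt: float = 0.01,
    method: str = "rk4",
) -> Trajectory:
    """Integrate the fuzzy ODE on a fixed grid (classical RK4 by default).

    ``q0`` gives initial levels in node order; entries for clamped
    inputs are overridden by their clamp level.  ``method`` is ``rk4``
    or ``euler``.  Deterministic for fixed arguments.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    system = _System(net, cfg)
    stepper = {"rk4": system.step_rk4, "euler": system.step_euler}[method]
    q = system.apply_clamp(np.asarray(q0, dtype=float))
    if q.shape != (net.n,):
        raise ValueError(f"q0 must have shape ({net.n},)")
    n_steps = int(round(t_max / dt))
    levels = np.empty((n_steps + 1, net.n))
    levels[0] = q
    for t in range(1, n_steps + 1):
        q = stepper(q, dt)
        if not np.all(np.isfinite(q)):
            raise FloatingPointError(
                f"non-finite state at t = {t * dt:.6g}"
            )
        levels[t] = q
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times=times, levels=levels, nodes=net.nodes)


def find_steady_state(
    net: BooleanNetwork,
    cfg: FuzzyConfig,
    q0,
    tolerance: float = 1e-6,
    hold_time: float = 10.0,
    t_max: float = 400.0,
    dt: float = 0.01,
) -> SteadyState:
    """Integrate until ``max|dq/dt| < tolerance`` holds for ``hold_time``.

    The run is cut into consecutive hold windows; the state converges
    when every residual inside a window is below tolerance, and is
    flagged oscillatory when the per-window residual maxima fail to
    decrease over two consecutive windows (a sustained, not damped,
    oscillation).  Neither outcome is an error: undecided runs return
    with both flags off and the residual history attached.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    system = _System(net, cfg)
    q = system.apply_clamp(np.asarray(q0, dtype=float))
    steps_per_window = max(1, int(round(hold_time / dt)))
    n_windows = max(1, int(np.ceil(t_max / hold_time)))
    window_maxima: list[float] = []
    converged = False
    oscillatory = False
    residual = float(np.max(np.abs(system.rhs(q))))
    for _ in range(n_windows):
        window_max = 0.0
        all_below = True
        for _ in range(steps_per_window):
            q = system.step_rk4(q, dt)
            residual = float(np.max(np.abs(system.rhs(q))))
            window_max = max(window_max, residual)
            if residual >= tolerance:
                all_below = False
        window_maxima.append(window_max)
        if all_below:
            converged = True
            break
        if (
            len(window_maxima) >= 3
            and window_maxima[-1] >= window_maxima[-2]
            and window_maxima[-2] >= window_maxima[-3]
        ):
            oscillatory = True
            break
    return SteadyState(
        levels=q,
        residual=residual,
        converged=converged,
        hold_time=hold_time,
        oscillatory=oscillatory,
        window_residuals=tuple(window_maxima),
        nodes=net.nodes,
    )


def steady_state_defect(
    net: BooleanNetwork, cfg: FuzzyConfig, levels
) -> float:
    """Max deviation from the self-consistency ``q_k = mu[w_k(q)]/alpha_k``."""
    system = _System(net, cfg)
    q = np.asarray(levels, dtype=float)
    defects = []
    for i, func, spec in system._funcs:
        values = {nm: q[..., j] for j, nm in enumerate(net.nodes)}
        mu = membership(func(values), spec)
        defects.append(abs(mu / system.alpha[i] - q[..., i]))
    return float(np.max(defects))


# ---------------------------------------------------------------------------
# Oscillation helpers


def local_maxima(series: np.ndarray) -> np.ndarray:
    """Values of the strict interior local maxima of a 1-D series."""
    series = np.asarray(series, dtype=float)
    if series.size < 3:
        return np.empty(0)
    interior = (series[1:-1] > series[:-2]) & (series[1:-1] > series[2:])
    return series[1:-1][interior]


def is_damped_oscillation(series: np.ndarray, min_peaks: int = 2) -> bool:
    """True when successive local maxima strictly decrease.

    The signature of a damped oscillator relaxing to its steady level:
    at least ``min_peaks`` interior peaks, each lower than the one
    before it.
    """
    peaks = local_maxima(series)
    if len(peaks) < min_peaks:
        return False
    return bool(np.all(np.diff(peaks) < 0))


# ---------------------------------------------------------------------------
# Boolean-fuzzy correspondence


@dataclass(frozen=True)
class CorrespondenceReport:
    """Findings of the discrete/continuous fixed-point comparison.

    ``confirmed`` lists Boolean fixed points that are continuous steady
    states (integration from the vertex stays within tolerance);
    ``missing`` any that are not.  ``rounding_mismatches`` are converged
    continuous steady states, reached from some binary vertex, whose
    thresholded profile is *not* a Boolean fixed point.  States with a
    component at the no-contradiction threshold 1/2 (where rounding is
    undefined) are listed under ``threshold_states``; vertices whose
    runs neither converge nor settle are counted in ``non_converged``.
    """

    confirmed: tuple[tuple[int, ...], ...]
    missing: tuple[tuple[int, ...], ...]
    rounding_mismatches: tuple[tuple[float, ...], ...]
    threshold_states: tuple[tuple[float, ...], ...]
    non_converged: int

    @property
    def ok(self) -> bool:
        return not self.missing and not self.rounding_mismatches


def binary_vertices(net: BooleanNetwork, cfg: dict[str, int]) -> np.ndarray:
    """All binary states with the inputs fixed at ``cfg`` (rows x nodes)."""
    free = net.free_nodes
    combos = np.array(
        list(itertools.product((0.0, 1.0), repeat=len(free)))
    ).reshape(-1, len(free))
    out = np.zeros((combos.shape[0], net.n))
    for j, nm in enumerate(free):
        out[:, net.index(nm)] = combos[:, j]
    for nm, v in cfg.items():
        out[:, net.index(nm)] = v
    return out


def _batch_settle(
    system: _System,
    q0: np.ndarray,
    tolerance: float,
    hold_time: float,
    t_max: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a batch of initial states; return final levels and a
    boolean converged flag per row (residual below tolerance for a full
    hold window)."""
    q = system.apply_clamp(q0)
    hold_steps = max(1, int(round(hold_time / dt)))
    below = np.zeros(q.shape[0], dtype=int)
    converged = np.zeros(q.shape[0], dtype=bool)
    n_steps = int(round(t_max / dt))
    for _ in range(n_steps):
        q = system.step_rk4(q, dt)
        residual = np.max(np.abs(system.rhs(q)), axis=-1)
        below = np.where(residual < tolerance, below + 1, 0)
        converged |= below >= hold_steps
        if np.all(converged):
            break
    return q, converged


def boolean_correspondence(
    net: BooleanNetwork,
    beta_large: float = 200.0,
    tol: float = 1e-3,
    t_max: float = 100.0,
    dt: float = 0.01,
) -> CorrespondenceReport:
    """Check the large-beta coincidence of discrete and continuous fixed
    points (all decay rates 1, probabilistic scheme).

    Every Boolean fixed point, started from its own vertex, must stay a
    continuous steady state within ``tol``; every converged continuous
    steady state reached from any binary vertex must round (threshold
    1/2) to a Boolean fixed point.  Mismatches are reported as findings.
    """
    cfg_template = FuzzyConfig(
        membership=MembershipSpec(form="logistic", beta=beta_large),
        scheme="probabilistic",
    )
    free_idx = [net.index(nm) for nm in net.free_nodes]
    confirmed: list[tuple[int, ...]] = []
    missing: list[tuple[int, ...]] = []
    mismatches: list[tuple[float, ...]] = []
    threshold_states: list[tuple[float, ...]] = []
    non_converged = 0

    attractors = find_attractors(net, "all")
    by_cfg: dict[tuple, list] = {}
    for att in attractors:
        by_cfg.setdefault(tuple(sorted(att.inputs.items())), []).append(att)

    for cfg_key, atts in by_cfg.items():
        input_cfg = dict(cfg_key)
        fixed_points = {
            att.states[0] for att in atts if att.kind == "fixed_point"
        }
        cfg = replace(
            cfg_template,
            clamp_inputs={k: float(v) for k, v in input_cfg.items()},
        )
        system = _System(net, cfg)
        vertices = binary_vertices(net, input_cfg)
        finals, conv = _batch_settle(
            system, vertices, tolerance=1e-8, hold_time=5.0,
            t_max=t_max, dt=dt,
        )
        # (a) each Boolean fixed point stays put
        for fp in sorted(fixed_points):
            row = np.argmin(np.abs(vertices - np.array(fp)).sum(axis=1))
            stayed = conv[row] and np.max(np.abs(finals[row] - np.array(fp))) <= tol
            (confirmed if stayed else missing).append(fp)
        # (b) every converged steady state rounds to a fixed point
        for row in range(vertices.shape[0]):
            if not conv[row]:
                non_converged += 1
                continue
            level = finals[row]
            if np.any(np.abs(level[free_idx] - 0.5) <= tol):
                threshold_states.append(tuple(level))
                continue
            rounded = tuple(
                int(input_cfg[nm]) if nm in input_cfg else int(level[i] > 0.5)
                for i, nm in enumerate(net.nodes)
            )
            if rounded not in fixed_points:
                mismatches.append(tuple(level))
    return CorrespondenceReport(
        confirmed=tuple(confirmed),
        missing=tuple(missing),
        rounding_mismatches=tuple(mismatches),
        threshold_states=tuple(threshold_states),
        non_converged=non_converged,
    )


# ---------------------------------------------------------------------------
# Parameter sweeps


def parameter_sweep(
    net: BooleanNetwork,
    cfg: FuzzyConfig,
    vary: str,
    values: Sequence[float],
    q0,
    tolerance: float = 1e-6,
    hold_time: float = 10.0,
    t_max: float = 400.0,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Explore the landscape by varying one control parameter.

    ``vary`` is ``"beta"``, ``"w_thr"`` or ``"alpha:<node>"``.  Each
    value yields one labeled outcome row: the converged steady levels
    (one column per node) plus ``converged`` / ``oscillatory`` flags.
    """
    if len(values) == 0:
        raise ValueError("values list must not be empty")
    rows = []
    for value in values:
        if vary == "beta":
            run_cfg = replace(
                cfg, membership=replace(cfg.membership, beta=float(value))
            )
        elif vary == "w_thr":
            run_cfg = replace(
                cfg, membership=replace(cfg.membership, w_thr=float(value))
            )
        elif vary.startswith("alpha:"):
            node = vary.split(":", 1)[1]
            net.index(node)
            alpha = dict(cfg.alpha)
            alpha[node] = float(value)
            run_cfg = replace(cfg, alpha=alpha)
        else:
            raise ValueError(
                f"unknown sweep parameter {vary!r}; "
                "use 'beta', 'w_thr' or 'alpha:<node>'"
            )
        state = find_steady_state(
            net, run_cfg, q0,
            tolerance=tolerance, hold_time=hold_time, t_max=t_max, dt=dt,
        )
        row: dict[str, float | bool] = {
            vary: value,
            "converged": state.converged,
            "oscillatory": state.oscillatory,
            "residual": state.residual,
        }
        for i, nm in enumerate(net.nodes):
            row[nm] = state.levels[i]
        rows.append(row)
    return pd.DataFrame(rows)
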