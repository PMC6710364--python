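"""Langevin extension of the fuzzy dynamics: white-noise fluctuations.

Each free node follows

    dq_k/dt = mu[w_k(q)] - alpha_k q_k + xi_k(t)

with independent Gaussian white noise of zero mean and autocorrelation
``<xi(t) xi(t')> = D delta(t - t')``.  Paths are generated with the
Euler-Maruyama scheme (the noise is additive, so there is no
Ito/Stratonovich ambiguity): per step the state gains the deterministic
Euler increment plus ``sqrt(D dt) N(0, 1)`` per node.  With D = 0 the
scheme reproduces the deterministic Euler trajectory bit-for-bit.

Noise drives the free nodes only - clamped inputs are boundary
conditions.  Levels are floored at 0 after every step (expression
cannot go negative); the upper side is left unclipped, consistent with
the convention that decay rates below 1 may push levels above 1.

In the small-noise regime (D << 1) the ensemble mean tracks the
deterministic path, and at late times the mean steady state satisfies
``<q_k^s> = <mu[w_k^s]> / alpha_k`` up to sampling error.  Larger D
allows noise-induced switching between neighbouring basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .continuous import FuzzyConfig, Trajectory, _System
from .network import BooleanNetwork


@dataclass(frozen=True)
class NoiseSpec:
    """White-noise settings: intensity ``D`` and the root seed.

    One root seed deterministically spawns independent streams per
    path, so ensembles are reproducible and paths are uncorrelated.
    """

    D: float = 0.0
    seed: int = 0
    correlation: str = "white"

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("noise intensity D must be >= 0")
        if self.correlation != "white":
            raise ValueError("only white (delta-correlated) noise is supported")


def langevin_integrate(
    net: BooleanNetwork,
    cfg: FuzzyConfig,
    noise: NoiseSpec,
    q0,
    t_max: float,
    dt: float = 0.01,
    path_index: int = 0,
) -> Trajectory:
    """One Euler-Maruyama sample path of the Langevin dynamics.

    ``path_index`` selects an independent stream from the root seed, so
    an ensemble is ``[langevin_integrate(..., path_index=i) for i in
    range(n_paths)]`` (or use :func:`ensemble`).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    system = _System(net, cfg)
    q = system.apply_clamp(np.asarray(q0, dtype=float))
    if q.shape != (net.n,):
        raise ValueError(f"q0 must have shape ({net.n},)")
    rng = np.random.default_rng([int(noise.seed), int(path_index)])
    n_steps = int(round(t_max / dt))
    free = system.free_idx
    sigma = float(np.sqrt(noise.D * dt))
    levels = np.empty((n_steps + 1, net.n))
    levels[0] = q
    for t in range(1, n_steps + 1):
        q = q + dt * system.rhs(q)
        if noise.D > 0:
            q[free] += sigma * rng.standard_normal(len(free))
            np.maximum(q, 0.0, out=q)
        if not np.all(np.isfinite(q)):
            raise FloatingPointError(f"non-finite excursion at t = {t * dt:.6g}")
        levels[t] = q
    times = np.arange(n_steps + 1) * dt
    return Trajectory(times=times, levels=levels, nodes=net.nodes)


def ensemble(
    net: BooleanNetwork,
    cfg: FuzzyConfig,
    noise: NoiseSpec,
    q0,
    t_max: float,
    dt: float = 0.01,
    n_paths: int = 100,
) -> list[Trajectory]:
    """Generate ``n_paths`` independent Langevin paths on a common grid."""
    return [
        langevin_integrate(net, cfg, noise, q0, t_max, dt, path_index=i)
        for i in range(n_paths)
    ]


@dataclass(frozen=True)
class EnsembleStats:
    """Pointwise mean and standard deviation over an ensemble of paths."""

    times: np.ndarray
    mean: np.ndarray  # (T, n)
    std: np.ndarray  # (T, n)
    nodes: tuple[str, ...]
    n_paths: int

    @property
    def mean_trajectory(self) -> Trajectory:
        return Trajectory(times=self.times, levels=self.mean, nodes=self.nodes)

    def node_mean(self, name: str) -> np.ndarray:
        return self.mean[:, self.nodes.index(name)]

    def node_std(self, name: str) -> np.ndarray:
        return self.std[:, self.nodes.index(name)]


def ensemble_stats(paths: list[Trajectory]) -> EnsembleStats:
    """Pointwise ensemble mean and dispersion per node.

    All paths must share the same time grid and node order.
    """
    if len(paths) < 2:
        raise ValueError("need at least 2 paths")
    first = paths[0]
    for p in paths[1:]:
        if p.nodes != first.nodes or not np.array_equal(p.times, first.times):
            raise ValueError("paths are not on a common grid")
    stack = np.stack([p.levels for p in paths])  # (paths, T, n)
    return EnsembleStats(
        times=first.times,
        mean=stack.mean(axis=0),
        std=stack.std(axis=0, ddof=0),
        nodes=first.nodes,
        n_paths=len(paths),
    )


def basin_switch_count(
    paths: list[Trajectory],
    node: str,
    start_side: int,
    threshold: float = 0.5,
) -> int:
    """How many paths end on the other side of ``threshold`` for ``node``.

    A crude but robust detector of noise-induced basin switching on
    bistable circuits: a path counts as switched when the node's final
    level falls on the opposite side of the threshold from
    ``start_side`` (0 or 1).
    """
    if start_side not in (0, 1):
        raise ValueError("start_side must be 0 or 1")
    count = 0
    for p in paths:
        final = p.node_series(node)[-1]
        side = int(final > threshold)
        count += side != start_side
    return count
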