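"""Fuzzy-logic translation of Boolean rules and membership functions.

A Boolean rule becomes a continuous proposition ``w_k(q_1, ..., q_n)``
by swapping each connective for a fuzzy counterpart, under one of two
schemes:

============  ==============  ===================
connective    Zadeh           probabilistic
============  ==============  ===================
q AND p       min(q, p)       q * p
q OR p        max(q, p)       q + p - q * p
NOT p         1 - p           1 - p
============  ==============  ===================

Both reduce to the Boolean truth tables on {0, 1} arguments; the
probabilistic scheme additionally yields continuously differentiable
expressions (the default, since the propositions feed an ODE).

The proposition value is mapped to an activation through a membership
function mu: the logistic sigmoid

    mu[w] = 1 / (1 + exp(-beta * (w - w_thr)))

with saturation rate ``beta`` and threshold ``w_thr`` (default 1/2, the
fixed point of w = 1 - w, i.e. the boundary between falsity and truth),
or equivalently a Hill function of ``x = exp(w)`` after the change of
variable ``w = ln x``:

    mu~[x] = x^beta / (x_thr^beta + x^beta).

For ``beta >> 1`` the logistic tends to the step function
``theta(w - w_thr)`` and the discrete dynamics is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.special import expit

from .expressions import And, Const, Expr, Not, Or, Var, flatten


@dataclass(frozen=True)
class FuzzyScheme:
    """A choice of fuzzy realisations for AND / OR / NOT."""

    name: str
    and_op: Callable
    or_op: Callable
    not_op: Callable

    @staticmethod
    def zadeh() -> "FuzzyScheme":
        return FuzzyScheme(
            "zadeh",
            and_op=np.minimum,
            or_op=np.maximum,
            not_op=lambda p: 1.0 - p,
        )

    @staticmethod
    def probabilistic() -> "FuzzyScheme":
        return FuzzyScheme(
            "probabilistic",
            and_op=lambda q, p: q * p,
            or_op=lambda q, p: q + p - q * p,
            not_op=lambda p: 1.0 - p,
        )

    @staticmethod
    def from_name(name: str) -> "FuzzyScheme":
        try:
            return {"zadeh": FuzzyScheme.zadeh,
                    "probabilistic": FuzzyScheme.probabilistic}[name]()
        except KeyError:
            raise ValueError(
                f"unknown scheme {name!r}; use 'zadeh' or 'probabilistic'"
            ) from None


@dataclass(frozen=True)
class MembershipSpec:
    """Shape of the activation function mu.

    ``form`` is ``logistic`` (default), ``hill`` (the same sigmoid in
    the variable ``x = exp(w)``) or ``step`` (the discrete beta -> inf
    limit).  ``beta`` sets how steeply mu switches around the threshold
    ``w_thr`` (``x_thr`` for the Hill form).
    """

    form: str = "logistic"
    beta: float = 60.0
    w_thr: float = 0.5
    x_thr: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("logistic", "hill", "step"):
            raise ValueError(f"unknown membership form {self.form!r}")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if self.form in ("logistic", "step") and not 0 < self.w_thr < 1:
            raise ValueError("w_thr must lie strictly between 0 and 1")
        if self.form == "hill" and not self.x_thr > 0:
            raise ValueError("x_thr must be positive")


def membership(w, spec: MembershipSpec):
    """Activation mu for proposition value ``w`` (elementwise on arrays).

    Logistic: ``1 / (1 + exp(-beta (w - w_thr)))`` - strictly increasing,
    with ``mu(w_thr) = 1/2``.  Hill: ``w`` is interpreted as a positive
    level ``x``; ``mu(x_thr) = 1/2``.  Step: the indicator of
    ``w > w_thr`` (1/2 exactly at threshold).
    """
    w = np.asarray(w, dtype=float)
    if spec.form == "logistic":
        out = expit(spec.beta * (w - spec.w_thr))
    elif spec.form == "hill":
        if np.any(w < 0):
            raise ValueError("hill membership requires non-negative levels")
        # computed in log space so it is the logistic under w = ln x
        with np.errstate(divide="ignore"):
            out = expit(spec.beta * (np.log(w) - np.log(spec.x_thr)))
    else:  # step
        out = np.where(w > spec.w_thr, 1.0, np.where(w < spec.w_thr, 0.0, 0.5))
    return out if out.ndim else float(out)


def fuzzify(
    expr: Expr, scheme: FuzzyScheme | str = "probabilistic"
) -> Callable[[Mapping[str, float]], float]:
    """Compile a logic expression into its continuous fuzzy proposition.

    The returned callable maps ``{node: level}`` (scalars or numpy
    arrays in [0, 1]) to the proposition value ``w``; it agrees with the
    Boolean evaluation at every binary vertex.  The expression is
    flattened first so the translation is deterministic.
    """
    if isinstance(scheme, str):
        scheme = FuzzyScheme.from_name(scheme)
    expr = flatten(expr)

    def compiled(values: Mapping[str, float]):
        return _eval_fuzzy(expr, scheme, values)

    compiled.expression = expr  # type: ignore[attr-defined]
    compiled.scheme = scheme  # type: ignore[attr-defined]
    return compiled


def _eval_fuzzy(expr: Expr, scheme: FuzzyScheme, values: Mapping[str, float]):
    if isinstance(expr, Var):
        return values[expr.name]
    if isinstance(expr, Const):
        return float(expr.value)
    if isinstance(expr, Not):
        return scheme.not_op(_eval_fuzzy(expr.child, scheme, values))
    if isinstance(expr, And):
        out = _eval_fuzzy(expr.children[0], scheme, values)
        for c in expr.children[1:]:
            out = scheme.and_op(out, _eval_fuzzy(c, scheme, values))
        return out
    if isinstance(expr, Or):
        out = _eval_fuzzy(expr.children[0], scheme, values)
        for c in expr.children[1:]:
            out = scheme.or_op(out, _eval_fuzzy(c, scheme, values))
        return out
    raise TypeError(f"unknown expression node {expr!r}")


def hill_logistic_equivalence(x: float, spec: MembershipSpec) -> float:
    """Residual between the Hill form and the logistic form at ``x``.

    Under the change of variable ``w = ln x`` (with ``w_thr = ln
    x_thr``) the logistic sigmoid *is* the Hill function
    ``x^beta / (x_thr^beta + x^beta)``; the returned absolute
    difference should vanish to numerical precision.
    """
    x = float(x)
    if x <= 0:
        raise ValueError("x must be positive")
    logistic = expit(spec.beta * (np.log(x) - np.log(spec.x_thr)))
    with np.errstate(over="ignore"):
        hill = 1.0 / (1.0 + (spec.x_thr / x) ** spec.beta)
    return float(abs(logistic - hill))
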