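"""Heuristic and closed-form variance-stabilizing transforms for comparison.

These are the fixed-form maps practitioners apply to count data when no
replicate information is available: the shifted logarithm, the inverse
hyperbolic sine, and the delta-method closed form for a negative-binomial
mean–variance law. All are strictly increasing and map 0 to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "NamedTransform",
    "shifted_log",
    "asinh_transform",
    "nb_closed_form",
    "identity_transform",
    "transform_registry",
]


@dataclass(frozen=True)
class NamedTransform:
    """An evaluable monotone map on x >= 0 with a display name."""

    name: str
    map: Callable[[np.ndarray], np.ndarray]

    def __call__(self, x) -> np.ndarray:
        return self.map(np.asarray(x, dtype=float))


def identity_transform() -> NamedTransform:
    """x -> x; scores the raw signal in benchmarks."""
    return NamedTransform("identity", lambda x: x)


def shifted_log(x0: float = 1.0) -> NamedTransform:
    """x -> ln(x + x0), the shifted logarithm (default log1p).

    Exactly stabilizes a variance proportional to the square of the mean;
    approximately stabilizes an NB law in the large-mean limit.
    """
    if x0 <= 0:
        raise ValueError("shift x0 must be positive")
    shift = np.log(x0)
    return NamedTransform(f"log(x+{x0:g})", lambda x: np.log(x + x0) - shift)


def asinh_transform() -> NamedTransform:
    """x -> ln(x + sqrt(x^2 + 1)), the inverse hyperbolic sine.

    Behaves like x near 0 and like ln(2x) for large x.
    """
    return NamedTransform("asinh", np.arcsinh)


def nb_closed_form(alpha: float) -> NamedTransform:
    """Delta-method transform for the NB variance law Var = mu + alpha*mu^2.

    ``h(mu) = sqrt(mu + alpha mu^2)`` integrates in closed form to
    ``t(x) = (2 / sqrt(alpha)) * ln(sqrt(alpha x) + sqrt(1 + alpha x))``,
    approaching the square-root map ``2 sqrt(x)`` (the Poisson limit) as
    ``alpha -> 0``.
    """
    if alpha <= 0:
        raise ValueError("overdispersion alpha must be positive")
    sa = np.sqrt(alpha)

    def f(x: np.ndarray) -> np.ndarray:
        ax = alpha * x
        return (2.0 / sa) * np.log(np.sqrt(ax) + np.sqrt(1.0 + ax))

    return NamedTransform(f"nb(alpha={alpha:g})", f)


def transform_registry(nb_alpha: float = 0.2) -> dict[str, Callable]:
    """Named constructors for the CLI: maps a registry key to a transform.

    ``vss`` and ``vss_log_converge`` are placeholders resolved by the caller
    once a transform has been learned from replicates; the rest are
    parameter-free closed forms.
    """
    return {
        "identity": identity_transform(),
        "log1p": shifted_log(1.0),
        "asinh": asinh_transform(),
        "nb_alpha": nb_closed_form(nb_alpha),
    }
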