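"""Density-dependent mortality multipliers.

The mortality term entering every model is ``d * D(n)`` where ``D`` is a
multiplier in [0, 1] that (for the density-dependent kinds) declines with
conspecific density ``n``.  The canonical form is the hyperbolic

    D(n) = 1 / (1 + s * n)

whose decline rate at zero density is ``-s``; ``s = 0`` switches density
dependence off for every kind.  Alternative kinds are kept behind a small
registry so new functional forms are one entry away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "MortalityKind",
    "MortalitySpec",
    "evaluate_mortality",
    "mortality_density_slope",
    "mortality_factor_sensitivity",
]


class MortalityKind(str, Enum):
    """Functional family of the mortality multiplier D(n)."""

    HYPERBOLIC = "hyperbolic"
    EXPONENTIAL = "exponential"
    LINEAR = "linear"
    #: density-independent control: D is constant in n, equal to the
    #: hyperbolic multiplier evaluated at a fixed reference density, so
    #: increasing s still lowers mortality but without density dependence.
    CONTROL = "control"


@dataclass(frozen=True)
class MortalitySpec:
    """A mortality multiplier family together with its decline factor.

    Parameters
    ----------
    kind:
        Member of :class:`MortalityKind` (or its string value).
    s:
        Nonnegative decline factor.  For the hyperbolic and exponential
        kinds this is the decline rate of ``D`` at ``n = 0``; ``s = 0``
        means constant mortality (``D ≡ 1``) for every kind.
    control_density:
        Reference density used only by the ``control`` kind.
    """

    kind: MortalityKind = MortalityKind.HYPERBOLIC
    s: float = 0.0
    control_density: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", MortalityKind(self.kind))
        if not np.isfinite(self.s) or self.s < 0:
            raise ValueError(f"density-dependence factor s must be >= 0, got {self.s}")
        if self.control_density < 0:
            raise ValueError("control_density must be >= 0")


def _check_density(n):
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("density must be nonnegative")
    return n


def evaluate_mortality(spec: MortalitySpec, n):
    """Multiplier ``D(n)`` in [0, 1]; vectorized over ``n``."""
    n = _check_density(n)
    s = spec.s
    if spec.kind is MortalityKind.HYPERBOLIC:
        out = 1.0 / (1.0 + s * n)
    elif spec.kind is MortalityKind.EXPONENTIAL:
        out = np.exp(-s * n)
    elif spec.kind is MortalityKind.LINEAR:
        out = np.maximum(0.0, 1.0 - s * n)
    elif spec.kind is MortalityKind.CONTROL:
        out = np.full_like(n, 1.0 / (1.0 + s * spec.control_density))
    else:  # pragma: no cover
        raise ValueError(f"unknown mortality kind {spec.kind!r}")
    return out if out.ndim else float(out)


def mortality_density_slope(spec: MortalitySpec, n):
    """Partial derivative ``dD/dn``; equals ``-s`` at ``n = 0`` for the
    hyperbolic and exponential kinds."""
    n = _check_density(n)
    s = spec.s
    if spec.kind is MortalityKind.HYPERBOLIC:
        out = -s / (1.0 + s * n) ** 2
    elif spec.kind is MortalityKind.EXPONENTIAL:
        out = -s * np.exp(-s * n)
    elif spec.kind is MortalityKind.LINEAR:
        out = np.where(1.0 - s * n > 0, -s, 0.0)
    elif spec.kind is MortalityKind.CONTROL:
        out = np.zeros_like(n)
    else:  # pragma: no cover
        raise ValueError(f"unknown mortality kind {spec.kind!r}")
    return out if out.ndim else float(out)


def mortality_factor_sensitivity(spec: MortalitySpec, n):
    """Partial derivative ``dD/ds``.

    Nonpositive everywhere and vanishing as ``n`` grows for the hyperbolic
    kind (``-n / (1 + s n)^2``, maximal in magnitude at ``n = 1/s``): species
    at very high density barely gain from a larger decline factor.
    """
    n = _check_density(n)
    s = spec.s
    if spec.kind is MortalityKind.HYPERBOLIC:
        out = -n / (1.0 + s * n) ** 2
    elif spec.kind is MortalityKind.EXPONENTIAL:
        out = -n * np.exp(-s * n)
    elif spec.kind is MortalityKind.LINEAR:
        out = np.where(1.0 - s * n > 0, -n, 0.0)
    elif spec.kind is MortalityKind.CONTROL:
        c = spec.control_density
        out = np.full_like(n, -c / (1.0 + s * c) ** 2)
    else:  # pragma: no cover
        raise ValueError(f"unknown mortality kind {spec.kind!r}")
    return out if out.ndim else float(out)
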