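"""Right-hand sides of the competition models.

All models are written in rescaled, dimensionless variables: time is scaled
to the growth rate and densities to the carrying capacity.  Every species
has logistic self-limitation, an interspecific competition load, and a
mortality term ``m * D(n_i)`` with a density-dependent multiplier ``D``
(:mod:`coexdd.mortality`).  Reproductive interference enters as a
frequency-dependent growth factor, evaluated in the singularity-free form
``n_i / sum_j(a'_{j,i} n_j)`` (0 at ``n_i = 0``).

Two-species variants
--------------------
``asym_competition``   species 1 depresses species 2 (coefficient ``alpha1``)
                       but is itself unaffected.
``basal_mortality``    symmetric competition ``alpha``; species 2 carries the
                       extra mortality ``delta * (1 - d)``.
``repro_interference`` symmetric competition ``alpha``; species 2 suffers
                       frequency-dependent interference ``alpha1p``.

The N-species model generalizes all three through interaction matrices; see
:func:`embed_two_species` for the exact 2x2 embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence, Union

import numpy as np

from .mortality import MortalityKind, MortalitySpec, evaluate_mortality

__all__ = [
    "ModelKind",
    "TwoSpeciesParams",
    "CommunityParams",
    "evaluate_rhs",
    "make_rhs",
    "embed_two_species",
]


class ModelKind(str, Enum):
    ASYM_COMPETITION = "asym_competition"
    BASAL_MORTALITY = "basal_mortality"
    REPRO_INTERFERENCE = "repro_interference"


def _check_unit(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class TwoSpeciesParams:
    """Parameters of one of the three two-species models.

    Fields irrelevant to ``model_kind`` must stay at 0 (enforced).
    """

    model_kind: ModelKind
    d: float = 0.0
    alpha1: float = 0.0
    alpha: float = 0.0
    delta: float = 0.0
    alpha1p: float = 0.0
    mortality: MortalitySpec = field(default_factory=MortalitySpec)

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind(self.model_kind))
        for name in ("d", "alpha1", "alpha", "delta", "alpha1p"):
            object.__setattr__(self, name, _check_unit(getattr(self, name), name))
        irrelevant = {
            ModelKind.ASYM_COMPETITION: ("alpha", "delta", "alpha1p"),
            ModelKind.BASAL_MORTALITY: ("alpha1", "alpha1p"),
            ModelKind.REPRO_INTERFERENCE: ("alpha1", "delta"),
        }[self.model_kind]
        for name in irrelevant:
            if getattr(self, name) != 0.0:
                raise ValueError(
                    f"{name} is not a parameter of model {self.model_kind.value} "
                    "and must be 0"
                )

    def with_s(self, s: float) -> "TwoSpeciesParams":
        return replace(self, mortality=replace(self.mortality, s=float(s)))


MortalityLike = Union[MortalitySpec, Sequence[MortalitySpec]]


@dataclass(frozen=True)
class CommunityParams:
    """Parameters of the N-species model.

    ``comp`` and ``ri`` are indexed ``[i, j]`` = effect of acting species j
    on affected species i; diagonals are exactly 1.  ``mortality`` is one
    spec shared by all species, or a per-species sequence of length N.
    """

    comp: np.ndarray
    ri: np.ndarray
    delta: np.ndarray
    d: float = 0.0
    mortality: MortalityLike = field(default_factory=MortalitySpec)

    def __post_init__(self) -> None:
        comp = np.array(self.comp, dtype=float)
        ri = np.array(self.ri, dtype=float)
        delta = np.array(self.delta, dtype=float)
        n = comp.shape[0]
        if comp.shape != (n, n) or ri.shape != (n, n) or delta.shape != (n,):
            raise ValueError("comp/ri must be NxN and delta length N")
        for name, mat in (("comp", comp), ("ri", ri)):
            if not np.allclose(np.diag(mat), 1.0, rtol=0, atol=0):
                raise ValueError(f"{name} diagonal must be exactly 1")
            if np.any(mat < 0) or np.any(mat > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if np.any(delta < 0) or np.any(delta > 1):
            raise ValueError("delta entries must lie in [0, 1]")
        _check_unit(self.d, "d")
        comp.setflags(write=False)
        ri.setflags(write=False)
        delta.setflags(write=False)
        object.__setattr__(self, "comp", comp)
        object.__setattr__(self, "ri", ri)
        object.__setattr__(self, "delta", delta)
        if not isinstance(self.mortality, MortalitySpec):
            specs = tuple(self.mortality)
            if len(specs) != n:
                raise ValueError("per-species mortality must have length N")
            object.__setattr__(self, "mortality", specs)

    @property
    def n_species(self) -> int:
        return self.comp.shape[0]

    def effective_mortality(self) -> np.ndarray:
        """Per-species basal mortality ``d + delta_i * (1 - d)``."""
        return self.d + self.delta * (1.0 - self.d)

    def with_s(self, s: float) -> "CommunityParams":
        if isinstance(self.mortality, MortalitySpec):
            mort: MortalityLike = replace(self.mortality, s=float(s))
        else:
            mort = tuple(replace(m, s=float(s)) for m in self.mortality)
        return replace(self, mortality=mort)

    def subcommunity(self, idx: np.ndarray) -> "CommunityParams":
        """Restriction to the species in ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        mort = self.mortality
        if not isinstance(mort, MortalitySpec):
            mort = tuple(mort[i] for i in idx)
        return CommunityParams(
            comp=self.comp[np.ix_(idx, idx)],
            ri=self.ri[np.ix_(idx, idx)],
            delta=self.delta[idx],
            d=self.d,
            mortality=mort,
        )


def _community_multiplier(mortality: MortalityLike, n: np.ndarray) -> np.ndarray:
    if isinstance(mortality, MortalitySpec):
        return np.asarray(evaluate_mortality(mortality, n))
    return np.array([evaluate_mortality(m, ni) for m, ni in zip(mortality, n)])


def _check_state(n, size: int | None = None) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if n.ndim != 1:
        raise ValueError("state must be a 1-D density vector")
    if size is not None and n.size != size:
        raise ValueError(f"state has {n.size} entries, expected {size}")
    if np.any(n < 0) or not np.all(np.isfinite(n)):
        raise ValueError("densities must be finite and nonnegative")
    return n


def _two_species_rhs(p: TwoSpeciesParams, n: np.ndarray) -> np.ndarray:
    n1, n2 = n
    D1 = evaluate_mortality(p.mortality, n1)
    D2 = evaluate_mortality(p.mortality, n2)
    if p.model_kind is ModelKind.ASYM_COMPETITION:
        b1 = 1.0 - n1 - p.d * D1
        b2 = 1.0 - (p.alpha1 * n1 + n2) - p.d * D2
        return np.array([n1 * b1, n2 * b2])
    if p.model_kind is ModelKind.BASAL_MORTALITY:
        m2 = p.d + p.delta * (1.0 - p.d)
        b1 = 1.0 - (n1 + p.alpha * n2) - p.d * D1
        b2 = 1.0 - (p.alpha * n1 + n2) - m2 * D2
        return np.array([n1 * b1, n2 * b2])
    # reproductive interference: growth factor n2/(n2 + a1p*n1), 0 at n2=0
    growth2 = n2 / (p.alpha1p * n1 + n2) if n2 > 0 else 0.0
    b1 = 1.0 - (n1 + p.alpha * n2) - p.d * D1
    b2 = growth2 - (p.alpha * n1 + n2) - p.d * D2
    return np.array([n1 * b1, n2 * b2])


def _community_rhs(p: CommunityParams, n: np.ndarray) -> np.ndarray:
    load = p.comp @ n
    ri_load = p.ri @ n
    D = _community_multiplier(p.mortality, n)
    m = p.effective_mortality()
    # frequency-dependent growth term: n_i / sum_j a'_{j,i} n_j, with the
    # 0/0 at n_i = 0 resolved to 0 (extinction is absorbing).
    growth = np.where(n > 0, n / np.where(ri_load > 0, ri_load, 1.0), 0.0)
    return n * (growth - load - m * D)


def evaluate_rhs(params: TwoSpeciesParams | CommunityParams, n) -> np.ndarray:
    """Per-unit-time density changes ``dn/dt`` at state ``n``.

    Every coordinate with ``n_i = 0`` has derivative exactly 0, and the
    result is finite for every nonnegative state.
    """
    if isinstance(params, TwoSpeciesParams):
        n = _check_state(n, 2)
        return _two_species_rhs(params, n)
    if isinstance(params, CommunityParams):
        n = _check_state(n, params.n_species)
        return _community_rhs(params, n)
    raise TypeError(f"unsupported params type {type(params)!r}")


def make_rhs(params: TwoSpeciesParams | CommunityParams, validate: bool = False):
    """``f(t, n)`` closure for ODE integrators.

    With ``validate=False`` (default for hot loops) tiny negative densities
    produced by the integrator are clipped to 0 instead of raising.
    """
    if isinstance(params, TwoSpeciesParams):
        def f(t, n):
            n = np.asarray(n, dtype=float)
            if validate:
                n = _check_state(n, 2)
            else:
                n = np.maximum(n, 0.0)
            return _two_species_rhs(params, n)
        return f
    def f(t, n):
        n = np.asarray(n, dtype=float)
        if validate:
            n = _check_state(n, params.n_species)
        else:
            n = np.maximum(n, 0.0)
        return _community_rhs(params, n)
    return f


def embed_two_species(params: TwoSpeciesParams) -> CommunityParams:
    """The N = 2 community whose dynamics coincide with ``params``."""
    comp = np.eye(2)
    ri = np.eye(2)
    delta = np.zeros(2)
    if params.model_kind is ModelKind.ASYM_COMPETITION:
        comp[1, 0] = params.alpha1  # species 1 acts on species 2 only
    elif params.model_kind is ModelKind.BASAL_MORTALITY:
        comp[0, 1] = comp[1, 0] = params.alpha
        delta[1] = params.delta
    else:
        comp[0, 1] = comp[1, 0] = params.alpha
        ri[1, 0] = params.alpha1p  # interference of species 1 on species 2
    return CommunityParams(comp=comp, ri=ri, delta=delta, d=params.d,
                           mortality=params.mortality)
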