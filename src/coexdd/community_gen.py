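"""Seeded generation of random species pools.

Four scenarios of species asymmetry are supported; each draws the relevant
parameters of an N-species community independently and uniformly from
configurable ranges, leaving the others at scenario-specific constants:

1. ``asym_competition_only``    off-diagonal competition drawn, no
                                interference, equal basal mortality.
2. ``repro_interference_only``  off-diagonal interference drawn, symmetric
                                competition at a fixed level.
3. ``basal_mortality_only``     per-species extra mortality drawn, symmetric
                                competition at a fixed level.
4. ``all_asymmetries``          competition, interference and mortality all
                                drawn.

Pool ``k`` under master seed ``S`` uses the child seed sequence ``(S, k)``,
so individual pools are reproducible without generating their predecessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Tuple

import numpy as np

from .models import CommunityParams
from .mortality import MortalityKind, MortalitySpec

__all__ = ["Scenario", "PoolDistributionConfig", "generate_pool"]


class Scenario(str, Enum):
    ASYM_COMPETITION_ONLY = "asym_competition_only"
    REPRO_INTERFERENCE_ONLY = "repro_interference_only"
    BASAL_MORTALITY_ONLY = "basal_mortality_only"
    ALL_ASYMMETRIES = "all_asymmetries"

    @classmethod
    def from_index(cls, idx: int) -> "Scenario":
        return list(cls)[idx - 1]


def _default_alpha(scenario: Scenario) -> float:
    # fixed symmetric competition used when competition is not drawn
    if scenario is Scenario.BASAL_MORTALITY_ONLY:
        return 0.05
    return 0.0


@dataclass(frozen=True)
class PoolDistributionConfig:
    """Distributions from which one species pool is drawn.

    ``comp_range`` / ``ri_range`` default to ``U(0, 2/N)`` so the expected
    interspecific load on a species is of the same order as its
    self-limitation; ``delta_range`` defaults to ``U(0, 1)``.
    """

    scenario: Scenario = Scenario.ALL_ASYMMETRIES
    N: int = 100
    comp_range: Optional[Tuple[float, float]] = None
    ri_range: Optional[Tuple[float, float]] = None
    delta_range: Tuple[float, float] = (0.0, 1.0)
    symmetric_alpha: Optional[float] = None
    d: float = 0.5
    mortality: MortalitySpec = field(default_factory=MortalitySpec)
    #: fraction of species whose mortality is density-*independent* (the
    #: control kind); the rest keep ``mortality``
    control_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenario", Scenario(self.scenario))
        if self.N < 1:
            raise ValueError("N must be >= 1")
        default_range = (0.0, min(1.0, 2.0 / self.N))
        for name, rng in (("comp_range", self.comp_range),
                          ("ri_range", self.ri_range)):
            if rng is None:
                object.__setattr__(self, name, default_range)
                rng = default_range
            lo, hi = rng
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 <= low <= high <= 1")
        lo, hi = self.delta_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("delta_range must satisfy 0 <= low <= high <= 1")
        if self.symmetric_alpha is None:
            object.__setattr__(self, "symmetric_alpha", _default_alpha(self.scenario))
        if not 0.0 <= self.symmetric_alpha <= 1.0:
            raise ValueError("symmetric_alpha must lie in [0, 1]")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("d must lie in [0, 1]")
        if not 0.0 <= self.control_fraction <= 1.0:
            raise ValueError("control_fraction must lie in [0, 1]")

    def with_s(self, s: float) -> "PoolDistributionConfig":
        return replace(self, mortality=replace(self.mortality, s=float(s)))


def _rng_for_pool(config: PoolDistributionConfig, pool_index: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), int(pool_index)])


def generate_pool(config: PoolDistributionConfig, pool_index: int = 0) -> CommunityParams:
    """Draw one :class:`~coexdd.models.CommunityParams` pool.

    Identical ``(config, pool_index)`` gives a bitwise-identical pool.
    """
    rng = _rng_for_pool(config, pool_index)
    N = config.N
    off = ~np.eye(N, dtype=bool)
    scen = config.scenario

    draws_comp = scen in (Scenario.ASYM_COMPETITION_ONLY, Scenario.ALL_ASYMMETRIES)
    draws_ri = scen in (Scenario.REPRO_INTERFERENCE_ONLY, Scenario.ALL_ASYMMETRIES)
    draws_delta = scen in (Scenario.BASAL_MORTALITY_ONLY, Scenario.ALL_ASYMMETRIES)

    comp = np.eye(N)
    if draws_comp:
        comp[off] = rng.uniform(*config.comp_range, size=N * (N - 1))
    else:
        comp[off] = config.symmetric_alpha

    ri = np.eye(N)
    if draws_ri:
        ri[off] = rng.uniform(*config.ri_range, size=N * (N - 1))

    delta = np.zeros(N)
    if draws_delta:
        delta = rng.uniform(*config.delta_range, size=N)

    mortality = config.mortality
    if config.control_fraction > 0.0:
        n_ctrl = int(round(config.control_fraction * N))
        ctrl_idx = rng.choice(N, size=n_ctrl, replace=False)
        specs = [config.mortality] * N
        for i in ctrl_idx:
            specs[i] = MortalitySpec(MortalityKind.CONTROL, config.mortality.s)
        mortality = tuple(specs)

    return CommunityParams(comp=comp, ri=ri, delta=delta, d=config.d,
                           mortality=mortality)
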