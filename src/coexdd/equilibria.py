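"""Equilibrium location, stability, invasion analysis and coexistence class.

The central object is the tristate classification of a two-species model:

``none``              no feasible, locally stable interior equilibrium.
``global_attractor``  the interior equilibrium is reached from every positive
                      initial condition (checked through invasion growth
                      rates at locally stable boundary attractors *and* a
                      probe grid of trajectories).
``local_attractor``   the interior equilibrium exists and is locally stable
                      but some positive initial conditions escape it
                      (typically: the weaker species starts too rare).

Borderline cases (marginal eigenvalues, probe trajectories that fail to
settle within the time budget) raise :class:`InconclusiveClassification`
instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .models import (
    CommunityParams,
    ModelKind,
    TwoSpeciesParams,
    embed_two_species,
    evaluate_rhs,
)
from .mortality import MortalityKind, MortalitySpec, evaluate_mortality, mortality_density_slope

__all__ = [
    "FEASIBILITY_TOL",
    "STABILITY_MARGIN",
    "ROOT_RESIDUAL_TOL",
    "InconclusiveClassification",
    "EquilibriumRecord",
    "CoexistenceClass",
    "ClassifyControls",
    "single_species_equilibria",
    "find_equilibria",
    "jacobian",
    "invasion_growth_rate",
    "classify_coexistence",
]

#: a density counts as strictly positive above this
FEASIBILITY_TOL = 1e-6
#: an equilibrium is locally stable if max Re(eig) < -STABILITY_MARGIN;
#: eigenvalues within +/- the margin are flagged as marginal
STABILITY_MARGIN = 1e-8
#: max |dn/dt| allowed at a reported equilibrium
ROOT_RESIDUAL_TOL = 1e-10

_DEDUP_TOL = 1e-6


class InconclusiveClassification(RuntimeError):
    """Raised when the basin classification cannot be settled honestly."""


@dataclass(frozen=True)
class EquilibriumRecord:
    location: np.ndarray
    residual: float
    feasible: bool
    eig_real_parts: np.ndarray
    locally_stable: bool
    marginal: bool = False

    def to_dict(self) -> dict:
        return {
            "location": [float(x) for x in self.location],
            "residual": float(self.residual),
            "feasible": bool(self.feasible),
            "eig_real_parts": [float(x) for x in self.eig_real_parts],
            "locally_stable": bool(self.locally_stable),
            "marginal": bool(self.marginal),
        }


@dataclass(frozen=True)
class CoexistenceClass:
    label: str  # "none" | "local_attractor" | "global_attractor"
    coexistence_eq: Optional[EquilibriumRecord]
    boundary_eqs: List[EquilibriumRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "coexistence_eq": None
            if self.coexistence_eq is None
            else self.coexistence_eq.to_dict(),
            "boundary_eqs": [e.to_dict() for e in self.boundary_eqs],
        }


@dataclass(frozen=True)
class ClassifyControls:
    """Numerical knobs of the probe-grid basin check."""

    probe_densities: tuple = (1e-4, 1e-2, 1e-1, 0.5, 1.0)
    probe_tol: float = 1e-4
    window: float = 400.0
    max_time: float = 4e4
    rtol: float = 1e-8
    atol: float = 1e-11
    settled_rhs_tol: float = 1e-9


# ---------------------------------------------------------------------------
# single-species equilibria


def single_species_equilibria(effective_mortality: float, mortality: MortalitySpec):
    """All nonnegative equilibria of ``dn/dt = n (1 - n - m D(n))``.

    Returns ``[(density, locally_stable), ...]`` sorted by density and
    always including the trivial root ``n = 0``.  For the hyperbolic kind
    the nonzero roots come from the closed-form quadratic
    ``s n^2 + (1 - s) n + (m - 1) = 0``.
    """
    m = float(effective_mortality)
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"effective mortality must lie in [0, 1], got {m}")
    s = mortality.s

    def percap(n):
        return 1.0 - n - m * evaluate_mortality(mortality, n)

    roots: list[float] = []
    if mortality.kind is MortalityKind.HYPERBOLIC and s > 0:
        disc = (1.0 - s) ** 2 - 4.0 * s * (m - 1.0)
        if disc >= 0:
            sq = np.sqrt(disc)
            for r in ((s - 1.0) + sq, (s - 1.0) - sq):
                r /= 2.0 * s
                if r > 0:
                    roots.append(float(r))
    elif s == 0 or mortality.kind is MortalityKind.CONTROL:
        Dc = evaluate_mortality(mortality, 0.0)
        r = 1.0 - m * Dc
        if r > 0:
            roots.append(float(r))
    else:
        # generic kinds: bracket sign changes of the per-capita rate on (0, 1]
        grid = np.linspace(1e-9, 1.0, 513)
        vals = percap(grid)
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if fa == 0.0:
                roots.append(float(a))
            elif fa * fb < 0:
                roots.append(float(brentq(percap, a, b, xtol=1e-14)))
        if vals[-1] == 0.0:
            roots.append(float(grid[-1]))

    out = [(0.0, percap(0.0) < 0.0)]
    for r in sorted(set(np.round(roots, 12))):
        # stability of n* > 0: sign of d/dn [n g(n)] = n* g'(n*)
        gprime = -1.0 - m * mortality_density_slope(mortality, r)
        out.append((float(r), bool(r * gprime < 0.0)))
    return out


# ---------------------------------------------------------------------------
# Jacobian


def jacobian(params, location) -> np.ndarray:
    """Finite-difference Jacobian of the RHS at ``location``.

    Central differences with step ``1e-7 * max(1, |n_i|)``; one-sided at
    coordinates sitting on the extinction boundary ``n_i = 0``.
    """
    x = np.asarray(location, dtype=float)
    if np.any(x < 0):
        raise ValueError("location must be nonnegative")
    k = x.size
    jac = np.empty((k, k))
    for j in range(k):
        h = 1e-7 * max(1.0, abs(x[j]))
        if x[j] - h < 0:
            f0 = evaluate_rhs(params, x)
            xp = x.copy()
            xp[j] += h
            jac[:, j] = (evaluate_rhs(params, xp) - f0) / h
        else:
            xp = x.copy()
            xm = x.copy()
            xp[j] += h
            xm[j] -= h
            jac[:, j] = (evaluate_rhs(params, xp) - evaluate_rhs(params, xm)) / (2.0 * h)
    return jac


def _record_at(params, x: np.ndarray) -> EquilibriumRecord:
    resid = float(np.max(np.abs(evaluate_rhs(params, x))))
    eigs = np.linalg.eigvals(jacobian(params, x))
    re = np.sort(eigs.real)[::-1]
    marginal = bool(np.any(np.abs(re) < STABILITY_MARGIN))
    return EquilibriumRecord(
        location=x.copy(),
        residual=resid,
        feasible=bool(np.all(x > FEASIBILITY_TOL)),
        eig_real_parts=re,
        locally_stable=bool(re[0] < -STABILITY_MARGIN),
        marginal=marginal,
    )


# ---------------------------------------------------------------------------
# equilibrium enumeration for the two-species models


def _percapita(params: TwoSpeciesParams, n: np.ndarray) -> np.ndarray:
    """Per-capita growth brackets, valid for strictly positive densities."""
    n1, n2 = n
    D1 = evaluate_mortality(params.mortality, n1)
    D2 = evaluate_mortality(params.mortality, n2)
    if params.model_kind is ModelKind.ASYM_COMPETITION:
        return np.array([
            1.0 - n1 - params.d * D1,
            1.0 - params.alpha1 * n1 - n2 - params.d * D2,
        ])
    if params.model_kind is ModelKind.BASAL_MORTALITY:
        m2 = params.d + params.delta * (1.0 - params.d)
        return np.array([
            1.0 - n1 - params.alpha * n2 - params.d * D1,
            1.0 - params.alpha * n1 - n2 - m2 * D2,
        ])
    return np.array([
        1.0 - n1 - params.alpha * n2 - params.d * D1,
        n2 / (n2 + params.alpha1p * n1) - params.alpha * n1 - n2 - params.d * D2,
    ])


def _single_mortality_2(params: TwoSpeciesParams, species: int) -> float:
    """Effective basal mortality of one species alone."""
    if params.model_kind is ModelKind.BASAL_MORTALITY and species == 1:
        return params.d + params.delta * (1.0 - params.d)
    return params.d


def find_equilibria(params: TwoSpeciesParams) -> List[EquilibriumRecord]:
    """Origin, boundary and interior equilibria, each with residual
    < :data:`ROOT_RESIDUAL_TOL` and a local-stability verdict."""
    records: list[EquilibriumRecord] = [_record_at(params, np.zeros(2))]

    for sp in (0, 1):
        m = _single_mortality_2(params, sp)
        for dens, _ in single_species_equilibria(m, params.mortality):
            if dens <= 0:
                continue
            x = np.zeros(2)
            x[sp] = dens
            records.append(_record_at(params, x))

    # interior roots: multi-start quasi-Newton on the per-capita system in
    # log coordinates (enforces positivity)
    seeds = np.geomspace(1e-3, 1.5, 12)

    def g_log(u):
        # clip keeps hybr trial points finite; real roots lie well inside
        return _percapita(params, np.exp(np.clip(u, -745.0, 4.0)))

    found: list[np.ndarray] = []
    for a in seeds:
        for b in seeds:
            sol = root(g_log, np.log([a, b]), method="hybr",
                       options={"xtol": 1e-13})
            if not sol.success:
                continue
            x = np.exp(sol.x)
            if np.any(x <= 1e-8) or np.any(x > 10.0):
                continue
            if float(np.max(np.abs(evaluate_rhs(params, x)))) > ROOT_RESIDUAL_TOL:
                continue
            if any(np.max(np.abs(x - y)) < _DEDUP_TOL for y in found):
                continue
            found.append(x)
    for x in sorted(found, key=lambda v: (v[0], v[1])):
        records.append(_record_at(params, x))
    return records


# ---------------------------------------------------------------------------
# invasion analysis


def invasion_growth_rate(params, invader: int, resident_equilibrium) -> float:
    """Per-capita growth rate of ``invader`` at vanishing density, with the
    remaining species resting at ``resident_equilibrium``.

    The frequency-dependent interference term contributes 0 to the limit
    whenever an interfering resident has positive density (a rare invader
    is swamped), and 1 otherwise.
    """
    comm = embed_two_species(params) if isinstance(params, TwoSpeciesParams) else params
    x = np.asarray(resident_equilibrium, dtype=float)
    if x.size != comm.n_species:
        raise ValueError("resident state has wrong dimension")
    if x[invader] != 0.0:
        raise ValueError("invader density must be exactly 0 in the resident state")
    # the resident subcommunity must actually be at rest
    if float(np.max(np.abs(evaluate_rhs(comm, x)))) > 1e-8:
        raise ValueError("resident state is not an equilibrium")
    ri_load = float(comm.ri[invader] @ x)  # invader itself contributes 0
    growth = 0.0 if ri_load > 0 else 1.0
    m = comm.effective_mortality()[invader]
    mort = comm.mortality
    spec = mort if isinstance(mort, MortalitySpec) else mort[invader]
    D0 = evaluate_mortality(spec, 0.0)
    return float(growth - comm.comp[invader] @ x - m * D0)


# ---------------------------------------------------------------------------
# probe-grid basin check


def _probe_batch_rhs(params: TwoSpeciesParams):
    """Vectorized RHS over a batch of independent 2-D states."""
    kind = params.model_kind

    def f(t, y):
        z = np.maximum(y.reshape(-1, 2), 0.0)
        n1, n2 = z[:, 0], z[:, 1]
        D1 = evaluate_mortality(params.mortality, n1)
        D2 = evaluate_mortality(params.mortality, n2)
        if kind is ModelKind.ASYM_COMPETITION:
            b1 = 1.0 - n1 - params.d * D1
            b2 = 1.0 - params.alpha1 * n1 - n2 - params.d * D2
        elif kind is ModelKind.BASAL_MORTALITY:
            m2 = params.d + params.delta * (1.0 - params.d)
            b1 = 1.0 - n1 - params.alpha * n2 - params.d * D1
            b2 = 1.0 - params.alpha * n1 - n2 - m2 * D2
        else:
            denom = n2 + params.alpha1p * n1
            growth = np.where(n2 > 0, n2 / np.where(denom > 0, denom, 1.0), 0.0)
            b1 = 1.0 - n1 - params.alpha * n2 - params.d * D1
            b2 = growth - params.alpha * n1 - n2 - params.d * D2
        out = np.empty_like(z)
        out[:, 0] = n1 * b1
        out[:, 1] = n2 * b2
        return out.ravel()

    return f


def _probes_converge(params: TwoSpeciesParams, target: np.ndarray,
                     controls: ClassifyControls) -> bool:
    """Integrate the probe grid; True iff every trajectory reaches
    ``target``.  Raises InconclusiveClassification on timeout."""
    pts = np.array([(a, b) for a in controls.probe_densities
                    for b in controls.probe_densities])
    f = _probe_batch_rhs(params)
    y = pts.ravel().copy()
    t = 0.0
    while t < controls.max_time:
        sol = solve_ivp(f, (t, t + controls.window), y, method="LSODA",
                        rtol=controls.rtol, atol=controls.atol)
        if not sol.success:
            raise InconclusiveClassification(f"probe integration failed: {sol.message}")
        t = sol.t[-1]
        y = sol.y[:, -1]
        z = np.maximum(y.reshape(-1, 2), 0.0)
        dist = np.max(np.abs(z - target), axis=1)
        if np.all(dist < controls.probe_tol):
            return True
        # any probe settled at a different attractor -> not global
        rhs = np.abs(f(t, y).reshape(-1, 2)).max(axis=1)
        if np.any((rhs < controls.settled_rhs_tol) & (dist > 10 * controls.probe_tol)):
            return False
    raise InconclusiveClassification(
        f"probe trajectories not settled after t={controls.max_time:g}")


def classify_coexistence(params: TwoSpeciesParams,
                         controls: ClassifyControls | None = None) -> CoexistenceClass:
    """Tristate basin classification of the coexistence equilibrium."""
    controls = controls or ClassifyControls()
    records = find_equilibria(params)
    interior = [r for r in records if bool(np.all(r.location > FEASIBILITY_TOL))]
    boundary = [r for r in records if not np.all(r.location > FEASIBILITY_TOL)]

    candidates = [r for r in interior if r.locally_stable and r.feasible]
    if any(r.marginal for r in interior):
        raise InconclusiveClassification("marginal interior eigenvalue")
    if not candidates:
        return CoexistenceClass("none", None, boundary)
    if len(candidates) > 1:
        raise InconclusiveClassification("multiple stable interior equilibria")
    coex = candidates[0]

    # (a) rare-invader growth at every locally stable boundary attractor
    invadable = True
    for rec in boundary:
        if rec.marginal:
            raise InconclusiveClassification("marginal boundary eigenvalue")
        if not rec.locally_stable:
            continue
        for sp in np.flatnonzero(rec.location == 0.0):
            if invasion_growth_rate(params, int(sp), rec.location) <= 0.0:
                invadable = False
    if not invadable:
        return CoexistenceClass("local_attractor", coex, boundary)

    # (b) probe-grid trajectories must all reach the interior equilibrium
    if _probes_converge(params, coex.location, controls):
        return CoexistenceClass("global_attractor", coex, boundary)
    return CoexistenceClass("local_attractor", coex, boundary)
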