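"""Parameter-plane sweeps of the coexistence classification.

A scan fixes one two-species model, varies its asymmetry parameter along x
and the density-dependence factor ``s`` along y (log-spaced, with ``s = 0``
prepended), and classifies every cell.  Class-change points along ``s`` can
then be sharpened by bisection (:func:`find_s_threshold`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import pandas as pd

from .equilibria import (
    ClassifyControls,
    CoexistenceClass,
    InconclusiveClassification,
    classify_coexistence,
)
from .models import ModelKind, TwoSpeciesParams

__all__ = [
    "X_PARAM",
    "ScanResult",
    "Transition",
    "default_s_grid",
    "scan_plane",
    "find_s_threshold",
]

#: asymmetry parameter swept along x, per model
X_PARAM = {
    ModelKind.ASYM_COMPETITION: "alpha1",
    ModelKind.BASAL_MORTALITY: "delta",
    ModelKind.REPRO_INTERFERENCE: "alpha1p",
}

#: interpretive split of the s axis: below this, mortality declines
#: appreciably with density over the whole density range
S_SPLIT = 1e2


def default_s_grid(n_log: int = 60, lo: float = 1e-2, hi: float = 1e4) -> np.ndarray:
    """``{0} U n_log log-spaced points in [lo, hi]`` (canonical y axis)."""
    return np.concatenate([[0.0], np.geomspace(lo, hi, n_log)])


def _cell_params(model_kind: ModelKind, fixed: TwoSpeciesParams,
                 x: float, s: float) -> TwoSpeciesParams:
    return replace(fixed, **{X_PARAM[model_kind]: float(x)}).with_s(s)


@dataclass
class ScanResult:
    model_kind: ModelKind
    x_name: str
    x_grid: np.ndarray
    s_grid: np.ndarray
    classes: np.ndarray        # (|x|, |s|) array of label strings
    n1_star: np.ndarray        # NaN where no coexistence equilibrium
    n2_star: np.ndarray
    inconclusive: np.ndarray   # boolean mask
    fixed: TwoSpeciesParams

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, x in enumerate(self.x_grid):
            for j, s in enumerate(self.s_grid):
                rows.append({
                    "x_name": self.x_name,
                    "x_value": x,
                    "s": s,
                    "class": self.classes[i, j],
                    "n1_star": self.n1_star[i, j],
                    "n2_star": self.n2_star[i, j],
                    "inconclusive_flag": bool(self.inconclusive[i, j]),
                })
        return pd.DataFrame(rows)


def scan_plane(model_kind, x_grid, s_grid, fixed_params: TwoSpeciesParams,
               controls: ClassifyControls | None = None) -> ScanResult:
    """Classify every (x, s) cell; inconclusive cells are flagged, never
    interpolated."""
    model_kind = ModelKind(model_kind)
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    s_grid = np.atleast_1d(np.asarray(s_grid, dtype=float))
    if x_grid.size == 0 or s_grid.size == 0:
        raise ValueError("grids must be nonempty")
    shape = (x_grid.size, s_grid.size)
    classes = np.full(shape, "none", dtype=object)
    n1 = np.full(shape, np.nan)
    n2 = np.full(shape, np.nan)
    inconclusive = np.zeros(shape, dtype=bool)
    for i, x in enumerate(x_grid):
        for j, s in enumerate(s_grid):
            params = _cell_params(model_kind, fixed_params, x, s)
            try:
                cls = classify_coexistence(params, controls)
            except InconclusiveClassification:
                inconclusive[i, j] = True
                continue
            classes[i, j] = cls.label
            if cls.coexistence_eq is not None:
                n1[i, j], n2[i, j] = cls.coexistence_eq.location
    return ScanResult(model_kind, X_PARAM[model_kind], x_grid, s_grid,
                      classes, n1, n2, inconclusive, fixed_params)


@dataclass(frozen=True)
class Transition:
    """A class change along s: ``class_below`` holds for s < s_star,
    ``class_above`` for s > s_star (up to the bisection tolerance)."""

    s_star: float
    class_below: str
    class_above: str


def _classify_label(model_kind, fixed, x, s, controls) -> str:
    return classify_coexistence(_cell_params(model_kind, fixed, x, s), controls).label


def find_s_threshold(model_kind, fixed_params: TwoSpeciesParams, x_value: float,
                     s_grid=None, controls: ClassifyControls | None = None,
                     log_rel_tol: float = 1e-3) -> List[Transition]:
    """Bisect each class-change boundary along s at fixed ``x_value``.

    Bisection runs in log s between positive grid neighbours (and linearly
    between ``s = 0`` and the first positive point), to a relative tolerance
    of ``log_rel_tol`` in log10 s.
    """
    model_kind = ModelKind(model_kind)
    s_grid = default_s_grid() if s_grid is None else np.asarray(s_grid, dtype=float)
    labels = [_classify_label(model_kind, fixed_params, x_value, s, controls)
              for s in s_grid]
    out: list[Transition] = []
    for k in range(len(s_grid) - 1):
        lo, hi = s_grid[k], s_grid[k + 1]
        la, lb = labels[k], labels[k + 1]
        if la == lb:
            continue
        if lo > 0:
            ulo, uhi = np.log10(lo), np.log10(hi)
            while uhi - ulo > log_rel_tol:
                mid = 0.5 * (ulo + uhi)
                lm = _classify_label(model_kind, fixed_params, x_value, 10 ** mid, controls)
                if lm == la:
                    ulo = mid
                else:
                    uhi = mid
                    lb = lm
            s_star = 10 ** (0.5 * (ulo + uhi))
        else:
            while hi - lo > log_rel_tol * max(hi, 1e-12):
                mid = 0.5 * (lo + hi)
                lm = _classify_label(model_kind, fixed_params, x_value, mid, controls)
                if lm == la:
                    lo = mid
                else:
                    hi = mid
                    lb = lm
            s_star = 0.5 * (lo + hi)
        out.append(Transition(float(s_star), la, lb))
    return out
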