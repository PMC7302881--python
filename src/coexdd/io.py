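"""CSV/JSON writers and readers for scan and simulation outputs.

CSV conventions: '.' decimal, no thousands separators, 12 significant
digits for densities, literal class labels.  Every CSV gets a JSON sidecar
(``<stem>.meta.json``) echoing the fully resolved configuration, so a run
is reproducible from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from enum import Enum
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

from .scan import ScanResult
from .simulate import RichnessRecord

__all__ = [
    "write_scan_csv",
    "read_scan_csv",
    "write_richness_csv",
    "read_richness_csv",
    "write_sidecar",
]

_FLOAT_FMT = "%.12g"


def _jsonable(obj):
    if isinstance(obj, Enum):
        return obj.value
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sidecar(csv_path, metadata: dict) -> Path:
    path = Path(csv_path).with_suffix(".meta.json")
    path.write_text(json.dumps(_jsonable(metadata), indent=2, sort_keys=True))
    return path


def write_scan_csv(result: ScanResult, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    result.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = {"kind": "scan", "model_kind": result.model_kind,
            "x_name": result.x_name, "fixed": result.fixed,
            "x_grid": result.x_grid, "s_grid": result.s_grid}
    meta.update(metadata or {})
    write_sidecar(path, meta)
    return path


def read_scan_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"x_name": str, "class": str,
                                    "inconclusive_flag": bool})


def write_richness_csv(records: Iterable[RichnessRecord], path,
                       metadata: dict | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame([r.to_dict() for r in records])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    write_sidecar(path, {"kind": "richness", **(metadata or {})})
    return path


def read_richness_csv(path) -> List[RichnessRecord]:
    df = pd.read_csv(path)
    return [
        RichnessRecord(
            pool_id=int(row.pool_id), seed=int(row.seed),
            scenario=str(row.scenario), s=float(row.s),
            final_richness=int(row.final_richness),
            converged=bool(row.converged), stable=bool(row.stable),
        )
        for row in df.itertuples()
    ]
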