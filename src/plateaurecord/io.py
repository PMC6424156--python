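"""Readers, writers, and run manifests.

Formats are deliberately plain:

* records CSV — header ``id,birth_date,death_date,group`` with optional
  ``entry_age``; dates strictly ISO-8601 (locale date parsing is exactly the
  ambiguity that corrupts historical age records, so it is refused).
* life-table CSV — header ``age,qx``.
* survival-curve TSV — ``time<TAB>survival<TAB>at_risk``.
* result JSON — stable field order, full precision, with a schema_version.

Malformed rows are reported with their 1-based data row numbers.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from . import __version__
from .cohorts import CohortTable, LifeTable, SurvivalCurve, ValidationError
from .plateau import PlateauExperiment
from .plausibility import PlausibilityResult

__all__ = [
    "SCHEMA_VERSION",
    "RunManifest",
    "read_records_csv",
    "write_records_csv",
    "read_life_table_csv",
    "write_life_table_csv",
    "write_curve_tsv",
    "write_result_json",
    "read_result_json",
]

SCHEMA_VERSION = 1


def read_records_csv(path) -> CohortTable:
    """Load and validate a lifespan records CSV (see module docs for format)."""
    frame = pd.read_csv(path, dtype=str)
    required = list(CohortTable.REQUIRED)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    problems = []
    for col in ("birth_date", "death_date"):
        for i, raw in enumerate(frame[col]):
            try:
                dt.date.fromisoformat(str(raw))
            except ValueError:
                # 1-based data line numbers, counting the header as line 1
                problems.append(f"line {i + 2}: {col} {raw!r} is not ISO-8601")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))
    try:
        return CohortTable(frame)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_records_csv(table: CohortTable, path) -> None:
    frame = table.frame
    frame["birth_date"] = [d.isoformat() for d in frame["birth_date"]]
    frame["death_date"] = [d.isoformat() for d in frame["death_date"]]
    frame.to_csv(path, index=False)


def read_life_table_csv(path) -> LifeTable:
    """Load and validate a period life table CSV with header ``age,qx``."""
    frame = pd.read_csv(path)
    for col in ("age", "qx"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    ages = frame["age"].to_numpy()
    qx = frame["qx"].to_numpy(dtype=float)
    bad = np.nonzero((qx < 0) | (qx > 1))[0]
    if bad.size:
        raise ValidationError(
            f"{path}: qx outside [0, 1] at line(s) {[int(b) + 2 for b in bad]}"
        )
    if np.any(np.diff(ages) != 1):
        raise ValidationError(f"{path}: ages must be consecutive integers")
    try:
        return LifeTable(ages=ages, qx=qx, label=str(Path(path).stem))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_life_table_csv(table: LifeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def write_curve_tsv(curve: SurvivalCurve, path_or_buf) -> None:
    curve.to_frame().to_csv(path_or_buf, sep="\t", index=False)


def _result_payload(result) -> dict:
    if isinstance(result, PlausibilityResult):
        kind = "plausibility"
    elif isinstance(result, PlateauExperiment):
        kind = "plateau_experiment"
    else:
        raise TypeError(f"cannot serialise result of type {type(result).__name__}")
    return {"schema_version": SCHEMA_VERSION, "kind": kind, **result.to_dict()}


def write_result_json(result: Union[PlausibilityResult, PlateauExperiment], path_or_buf) -> None:
    """Serialise a result with a schema version and stable field order."""
    payload = _result_payload(result)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(type(o).__name__)

    text = json.dumps(payload, indent=2, default=_default)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text + "\n")
    else:
        Path(path_or_buf).write_text(text + "\n")


def read_result_json(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    parameters: dict
    seed: object = None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: dt.datetime.now(dt.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")
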