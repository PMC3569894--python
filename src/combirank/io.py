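"""Tab-separated table readers/writers and YAML configuration.

Table layouts (one header row, UTF-8, tab-separated; multi-valued cells are
pipe-separated):

* ``compounds.tsv``   — compound_id, name, functional_groups
* ``targets.tsv``     — protein_id, name, is_cancer, is_aml, is_hub, pathways
* ``predictions.tsv`` — compound_id, protein_id, source, confidence
* ``docking.tsv``     — compound_id, protein_id, docking_score, ki_um

Unknown columns are preserved and returned as per-table metadata frames.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Dict, Iterable, List, Sequence, Tuple

import pandas as pd
import yaml

from .datamodel import (
    CompoundRecord,
    DockingRecord,
    TargetPrediction,
    TargetProtein,
)
from .errors import SchemaError, ValidationError

COMPOUND_COLUMNS = ("compound_id", "name", "functional_groups")
TARGET_COLUMNS = ("protein_id", "name", "is_cancer", "is_aml", "is_hub", "pathways")
PREDICTION_COLUMNS = ("compound_id", "protein_id", "source", "confidence")
DOCKING_COLUMNS = ("compound_id", "protein_id", "docking_score", "ki_um")

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _read_frame(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {missing}; "
            f"found {list(frame.columns)}"
        )
    return frame


def _check_unique(values: Iterable[Any], what: str, where: str) -> None:
    seen: set = set()
    dups: List[Any] = []
    for v in values:
        if v in seen:
            dups.append(v)
        seen.add(v)
    if dups:
        raise ValidationError(f"{where}: duplicate {what}: {sorted(set(dups))}")


def _split_multi(cell: str) -> frozenset[str]:
    return frozenset(x.strip() for x in cell.split("|") if x.strip())


def _parse_bool(cell: str, column: str, row: int) -> bool:
    token = cell.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValidationError(f"row {row}: cannot parse boolean {column}={cell!r}")


def _parse_float(cell: str, column: str, row: int) -> float:
    try:
        value = float(cell)
    except ValueError as exc:
        raise ValidationError(f"row {row}: bad {column}={cell!r}") from exc
    if math.isnan(value):
        raise ValidationError(f"row {row}: {column} is NaN")
    return value


def read_compounds(path: str | Path) -> List[CompoundRecord]:
    frame = _read_frame(path, COMPOUND_COLUMNS)
    _check_unique(frame["compound_id"], "compound_id", Path(path).name)
    return [
        CompoundRecord(
            compound_id=row.compound_id,
            name=row.name_,
            functional_groups=_split_multi(row.functional_groups),
        )
        for row in frame.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def read_targets(path: str | Path) -> List[TargetProtein]:
    frame = _read_frame(path, TARGET_COLUMNS)
    _check_unique(frame["protein_id"], "protein_id", Path(path).name)
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=2):
        out.append(
            TargetProtein(
                protein_id=row["protein_id"],
                name=row["name"],
                is_cancer=_parse_bool(row["is_cancer"], "is_cancer", i),
                is_aml=_parse_bool(row["is_aml"], "is_aml", i),
                is_hub=_parse_bool(row["is_hub"], "is_hub", i),
                pathways=_split_multi(row["pathways"]),
            )
        )
    return out


def read_predictions(path: str | Path) -> List[TargetPrediction]:
    frame = _read_frame(path, PREDICTION_COLUMNS)
    _check_unique(
        zip(frame["compound_id"], frame["protein_id"], frame["source"]),
        "(compound_id, protein_id, source)",
        Path(path).name,
    )
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=2):
        ki = None
        if "ki_um" in row and str(row["ki_um"]).strip():
            ki = _parse_float(str(row["ki_um"]), "ki_um", i)
        try:
            out.append(
                TargetPrediction(
                    compound_id=row["compound_id"],
                    protein_id=row["protein_id"],
                    source=row["source"],
                    confidence=row["confidence"],
                    ki_um=ki,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{Path(path).name} row {i}: {exc}") from exc
    return out


def read_docking(path: str | Path) -> List[DockingRecord]:
    frame = _read_frame(path, DOCKING_COLUMNS)
    out = []
    for i, row in enumerate(frame.to_dict("records"), start=2):
        try:
            out.append(
                DockingRecord(
                    compound_id=row["compound_id"],
                    protein_id=row["protein_id"],
                    docking_score=_parse_float(
                        str(row["docking_score"]), "docking_score", i
                    ),
                    ki_um=_parse_float(str(row["ki_um"]), "ki_um", i),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{Path(path).name} row {i}: {exc}") from exc
    return out


def read_tables(
    compounds_path: str | Path,
    targets_path: str | Path,
    predictions_path: str | Path,
    docking_path: str | Path,
) -> Tuple[
    List[CompoundRecord],
    List[TargetProtein],
    List[TargetPrediction],
    List[DockingRecord],
]:
    """Read and validate the four pipeline input tables."""
    return (
        read_compounds(compounds_path),
        read_targets(targets_path),
        read_predictions(predictions_path),
        read_docking(docking_path),
    )


def _join_multi(values: Iterable[str]) -> str:
    return "|".join(sorted(values))


def write_compounds(records: Sequence[CompoundRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "name": [r.name for r in records],
            "functional_groups": [_join_multi(r.functional_groups) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_targets(records: Sequence[TargetProtein], path: str | Path) -> None:
    pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "name": [r.name for r in records],
            "is_cancer": [int(r.is_cancer) for r in records],
            "is_aml": [int(r.is_aml) for r in records],
            "is_hub": [int(r.is_hub) for r in records],
            "pathways": [_join_multi(r.pathways) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_predictions(records: Sequence[TargetPrediction], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "protein_id": [r.protein_id for r in records],
            "source": [r.source for r in records],
            "confidence": [r.confidence for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_docking(records: Sequence[DockingRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "protein_id": [r.protein_id for r in records],
            "docking_score": [repr(r.docking_score) for r in records],
            "ki_um": [repr(r.ki_um) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_tables(
    compounds: Sequence[CompoundRecord],
    targets: Sequence[TargetProtein],
    predictions: Sequence[TargetPrediction],
    docking: Sequence[DockingRecord],
    out_dir: str | Path,
) -> Dict[str, Path]:
    """Write the four tables under ``out_dir``; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compounds.tsv",
        "targets": out / "targets.tsv",
        "predictions": out / "predictions.tsv",
        "docking": out / "docking.tsv",
    }
    write_compounds(compounds, paths["compounds"])
    write_targets(targets, paths["targets"])
    write_predictions(predictions, paths["predictions"])
    write_docking(docking, paths["docking"])
    return paths


def load_config(path: str | Path) -> Dict[str, Any]:
    """Load a nested key-value configuration file (YAML)."""
    with open(path, "r", encoding="utf-8") as handle:
        cfg = yaml.safe_load(handle)
    return cfg or {}


def _round_floats(obj: Any, ndigits: int = 9) -> Any:
    if isinstance(obj, float):
        return round(obj, ndigits)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _round_floats(dataclasses.asdict(obj), ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


def dump_json(obj: Any, path: str | Path) -> None:
    """Serialize a pipeline output as JSON, floats at 9 decimal places."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(_round_floats(obj), handle, indent=2, sort_keys=True)
        handle.write("\n")
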