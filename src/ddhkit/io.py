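"""File formats: annotation JSON, criteria TSV/JSON, images, reports.

All structured records are JSON; the criteria table is clinician-editable
TSV (header: nationality sex side age_min age_max mean_deg sd_deg) or an
equivalent JSON list.  Images are 8-bit grayscale PNG/JPEG; color inputs
are converted by the ITU-R 601 luma transform.  Writers and readers
round-trip bit-exactly, and reports echo tool version, configuration, and
input checksums so every result is reproducible from the file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .core import AnnotationSet, Landmark, Side, ValidationError
from .diagnose import (
    CriteriaEntry,
    CriteriaSide,
    CriteriaTable,
    Nationality,
    PatientInfo,
    Sex,
    StudyReport,
)
from .refine import RefinementConfig

__all__ = [
    "AnnotationFile",
    "SCHEMA_VERSION",
    "load_image",
    "save_image",
    "read_annotations",
    "write_annotations",
    "read_criteria",
    "write_criteria",
    "read_config",
    "write_report",
    "file_sha256",
]

SCHEMA_VERSION = "1.0"

_CRITERIA_COLUMNS = [
    "nationality",
    "sex",
    "side",
    "age_min",
    "age_max",
    "mean_deg",
    "sd_deg",
]


def load_image(path: Union[str, Path]) -> np.ndarray:
    """Read a PNG/JPEG as an 8-bit grayscale array (luma for color input)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def save_image(path: Union[str, Path], image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def file_sha256(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass(frozen=True)
class AnnotationFile:
    """On-disk annotation record: key points plus optional patient/image."""

    annotations: AnnotationSet
    patient: Optional[PatientInfo] = None
    image_path: Optional[str] = None
    schema_version: str = SCHEMA_VERSION


def _parse_patient(obj: dict) -> PatientInfo:
    try:
        return PatientInfo(
            nationality=Nationality(obj["nationality"]),
            sex=Sex(obj["sex"]),
            age_years=float(obj["age_years"]),
        )
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"invalid patient record: {exc}") from exc


def read_annotations(path: Union[str, Path]) -> AnnotationFile:
    """Parse and validate an annotation JSON file.

    Rejects unknown labels/sides, duplicate (label, side) pairs, missing
    ``landmarks``, and unrecognized schema versions.
    """
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise ValidationError(f"{path}: top level must be a JSON object")
    version = obj.get("schema_version", SCHEMA_VERSION)
    if str(version).split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise ValidationError(f"{path}: unrecognized schema_version {version!r}")
    if "landmarks" not in obj:
        raise ValidationError(f"{path}: missing required field 'landmarks'")
    points: Dict[Tuple[Landmark, Side], Tuple[float, float]] = {}
    for i, rec in enumerate(obj["landmarks"]):
        try:
            key = (Landmark(rec["label"]), Side(rec["side"]))
            xy = (float(rec["x"]), float(rec["y"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: landmarks[{i}] invalid: {exc}"
            ) from exc
        if key in points:
            raise ValidationError(
                f"{path}: duplicate landmark {key[0].value} ({key[1].value})"
            )
        points[key] = xy
    patient = _parse_patient(obj["patient"]) if obj.get("patient") else None
    return AnnotationFile(
        annotations=AnnotationSet(points),
        patient=patient,
        image_path=obj.get("image_path"),
        schema_version=str(version),
    )


def write_annotations(path: Union[str, Path], record: AnnotationFile) -> None:
    obj: dict = {"schema_version": record.schema_version}
    if record.patient is not None:
        obj["patient"] = {
            "nationality": record.patient.nationality.value,
            "sex": record.patient.sex.value,
            "age_years": record.patient.age_years,
        }
    if record.image_path is not None:
        obj["image_path"] = record.image_path
    obj["landmarks"] = [
        {"label": lm.value, "side": side.value, "x": xy[0], "y": xy[1]}
        for (lm, side), xy in sorted(
            record.annotations.points.items(),
            key=lambda kv: (kv[0][1].value, kv[0][0].value),
        )
    ]
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def _entry_from_row(row: dict, where: str) -> CriteriaEntry:
    try:
        return CriteriaEntry(
            nationality=Nationality(str(row["nationality"]).lower()),
            sex=Sex(str(row["sex"]).lower()),
            side=CriteriaSide(str(row["side"]).lower()),
            age_min_years=float(row["age_min"]),
            age_max_years=float(row["age_max"]),
            mean_deg=float(row["mean_deg"]),
            sd_deg=float(row["sd_deg"]),
        )
    except (KeyError, ValueError, ValidationError) as exc:
        raise ValidationError(f"{where}: {exc}") from exc


def read_criteria(path: Union[str, Path]) -> CriteriaTable:
    """Load a criteria table (TSV or JSON by extension), validating every
    invariant; the first violation is reported with its line/entry."""
    path = Path(path)
    entries: List[CriteriaEntry] = []
    source = path.stem
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        rows = obj["entries"] if isinstance(obj, dict) else obj
        if isinstance(obj, dict):
            source = obj.get("source_label", source)
        for i, row in enumerate(rows):
            entries.append(_entry_from_row(row, f"{path}: entries[{i}]"))
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = [c for c in _CRITERIA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"{path}: missing column(s) {missing}")
        for i, row in df.iterrows():
            # +2: header line plus 1-based numbering
            entries.append(_entry_from_row(dict(row), f"{path}: line {i + 2}"))
    return CriteriaTable(entries=tuple(entries), source_label=source)


def write_criteria(path: Union[str, Path], table: CriteriaTable) -> None:
    df = pd.DataFrame(
        [
            {
                "nationality": e.nationality.value,
                "sex": e.sex.value,
                "side": e.side.value,
                "age_min": e.age_min_years,
                "age_max": e.age_max_years,
                "mean_deg": e.mean_deg,
                "sd_deg": e.sd_deg,
            }
            for e in table.entries
        ],
        columns=_CRITERIA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def default_criteria_table() -> CriteriaTable:
    """The shipped synthetic criteria template (placeholder normative values)."""
    from importlib.resources import files

    return read_criteria(Path(str(files("ddhkit") / "data" / "criteria_synthetic.tsv")))


def read_config(path: Union[str, Path]) -> RefinementConfig:
    """Load a refinement config from a flat JSON key-value file."""
    obj = json.loads(Path(path).read_text())
    if not isinstance(obj, dict):
        raise ValidationError(f"{path}: config must be a JSON object")
    known = {f.name for f in dataclasses.fields(RefinementConfig)}
    unknown = set(obj) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    if "enabled_labels" in obj and obj["enabled_labels"] is not None:
        obj["enabled_labels"] = frozenset(
            (Landmark(rec["label"]), Side(rec["side"]))
            for rec in obj["enabled_labels"]
        )
    try:
        return RefinementConfig(**obj)
    except (TypeError, ValidationError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_report(
    path: Union[str, Path],
    report: StudyReport,
    *,
    config: Optional[RefinementConfig] = None,
    input_paths: Optional[Dict[str, Union[str, Path]]] = None,
) -> dict:
    """Serialize a study report with version, config echo, and checksums."""
    obj = {
        "tool": {"name": "ddhkit", "version": __version__},
        "schema_version": SCHEMA_VERSION,
        "config": _config_to_jsonable(config) if config is not None else None,
        "inputs": {
            name: {"path": str(p), "sha256": file_sha256(p)}
            for name, p in (input_paths or {}).items()
        },
        "report": report.to_dict(),
    }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return obj


def _config_to_jsonable(config: RefinementConfig) -> dict:
    d = dataclasses.asdict(config)
    if d["enabled_labels"] is not None:
        d["enabled_labels"] = [
            {"label": lm, "side": side}
            for lm, side in sorted(
                (lm.value, side.value) for lm, side in config.enabled_labels
            )
        ]
    return d
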