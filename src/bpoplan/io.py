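"""File formats: landmark JSON, attachment JSON, criteria YAML, CSV tables.

All lengths are millimetres; the landmark frame is the package's sagittal
convention (x anterior-positive, y cranial-positive), and both are stated
explicitly in the files so a mismatched export fails loudly rather than
silently rescaling.  CSV numeric output is fixed at six significant digits
to keep results diff-stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .closed_form import LinearModel
from .geometry import LANDMARK_NAMES, PREDICTION_COLUMNS, LandmarkSet, Point2
from .muscles import MuscleAttachment, MuscleResult, muscle_results_table
from .planner import Criteria

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_attachments",
    "write_attachments",
    "read_criteria",
    "write_prediction_table",
    "read_prediction_table",
    "write_linear_models",
    "write_muscle_results",
]

LANDMARK_FRAME = "x_anterior_y_cranial"
_CSV_FLOAT_FORMAT = "%.6g"


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a landmark JSON file into a validated :class:`LandmarkSet`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON landmark file: {exc}") from exc
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: landmark file must be a JSON object")
    units = payload.get("units")
    if units != "mm":
        raise ValueError(f"{path}: units must be 'mm' (millimetres), got {units!r}")
    frame = payload.get("frame")
    if frame != LANDMARK_FRAME:
        raise ValueError(f"{path}: frame must be {LANDMARK_FRAME!r}, got {frame!r}")
    unknown = set(payload) - set(LANDMARK_NAMES) - {"units", "frame"}
    if unknown:
        raise ValueError(f"{path}: unknown keys in landmark file: {sorted(unknown)}")
    points = {}
    for name in LANDMARK_NAMES:
        if name not in payload:
            raise ValueError(f"{path}: missing landmark {name!r}")
        xy = payload[name]
        if not (isinstance(xy, (list, tuple)) and len(xy) == 2):
            raise ValueError(f"{path}: landmark {name!r} must be an [x, y] pair")
        points[name] = Point2(float(xy[0]), float(xy[1]))
    return LandmarkSet(**points)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    payload: dict = {"units": "mm", "frame": LANDMARK_FRAME}
    for name in LANDMARK_NAMES:
        p = landmarks.point(name)
        payload[name] = [p.x, p.y]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_attachments(path: str | Path) -> list[MuscleAttachment]:
    """Read a muscle attachment JSON file (list of 3-D segments)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON attachment file: {exc}") from exc
    if not isinstance(payload, dict) or "segments" not in payload:
        raise ValueError(f"{path}: attachment file must be an object with 'segments'")
    if payload.get("units") != "mm":
        raise ValueError(f"{path}: units must be 'mm', got {payload.get('units')!r}")
    segments = payload["segments"]
    if not segments:
        raise ValueError(f"{path}: attachment file has no segments")
    out = []
    seen = set()
    for seg in segments:
        extra = set(seg) - {"name", "group", "section", "cranial", "caudal"}
        if extra:
            raise ValueError(f"{path}: unknown segment keys {sorted(extra)}")
        name = seg["name"]
        if name in seen:
            raise ValueError(f"{path}: duplicated segment name {name!r}")
        seen.add(name)
        out.append(
            MuscleAttachment(
                name=name,
                group=seg["group"],
                section=seg["section"],
                cranial_point=tuple(float(c) for c in seg["cranial"]),
                caudal_point=tuple(float(c) for c in seg["caudal"]),
            )
        )
    return out


def write_attachments(attachments: Sequence[MuscleAttachment], path: str | Path) -> None:
    payload = {
        "units": "mm",
        "segments": [
            {
                "name": a.name,
                "group": a.group,
                "section": a.section,
                "cranial": list(a.cranial_point),
                "caudal": list(a.caudal_point),
            }
            for a in attachments
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


_CRITERIA_KEYS = (
    "sva_min_mm",
    "sva_max_mm",
    "tpa_max_deg",
    "pt_max_deg",
    "pi_minus_ll_max_deg",
    "oa_cap_deg",
)


def read_criteria(path: str | Path) -> Criteria:
    """Read a criteria YAML file; missing keys take the standard defaults.

    A key set to ``null`` disables that constraint; unknown keys are rejected.
    """
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: criteria file must be a YAML mapping")
    unknown = set(payload) - set(_CRITERIA_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown criteria keys: {sorted(unknown)}")
    kwargs = {k: payload[k] for k in _CRITERIA_KEYS if k in payload}
    return Criteria(**kwargs)


def write_prediction_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table CSV with the fixed column order."""
    missing = [c for c in PREDICTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"prediction table missing columns: {missing}")
    table[PREDICTION_COLUMNS].to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def read_prediction_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in PREDICTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: prediction CSV missing columns: {missing}")
    return table[PREDICTION_COLUMNS]


def write_linear_models(models: Mapping[str, LinearModel], path: str | Path) -> None:
    rows = [
        {
            "parameter": m.parameter_name,
            "slope": m.slope,
            "intercept": m.intercept,
            "r_squared": m.r_squared,
            "oa_min_deg": m.oa_range_deg[0],
            "oa_max_deg": m.oa_range_deg[1],
        }
        for _, m in sorted(models.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)


def write_muscle_results(results: Sequence[MuscleResult], path: str | Path) -> None:
    muscle_results_table(results).to_csv(path, index=False, float_format=_CSV_FLOAT_FORMAT)
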