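"""Reading and writing the package's plain-text formats.

* tumour time series — 2-column CSV with header ``day,volume_cm3``
* treatment protocol — YAML/JSON mapping ``{dose_gy, times_days, tw_days}``
* fit results — JSON with a full config echo
* comparison tables — CSV

All round-trips are stable to float formatting (repr-level precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import ValidationError
from .fitting import FitResult
from .models import TreatmentProtocol, TumourTimeSeries

__all__ = [
    "read_series",
    "write_series",
    "read_protocol",
    "write_protocol",
    "read_fit_result",
    "write_fit_result",
]

_SERIES_COLUMNS = ("day", "volume_cm3")


def write_series(series: TumourTimeSeries, path: str | Path) -> None:
    pd.DataFrame({"day": series.times, "volume_cm3": series.volumes}).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_series(path: str | Path, patient_id: str | None = None) -> TumourTimeSeries:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"could not parse CSV {path}: {exc}") from exc
    if tuple(frame.columns[:2]) != _SERIES_COLUMNS:
        raise ValidationError(
            f"{path}: expected header 'day,volume_cm3', got {','.join(frame.columns[:2])}"
        )
    pid = patient_id if patient_id is not None else Path(path).stem
    return TumourTimeSeries(
        times=frame["day"].to_numpy(dtype=float),
        volumes=frame["volume_cm3"].to_numpy(dtype=float),
        patient_id=pid,
    )


def write_protocol(proto: TreatmentProtocol, path: str | Path) -> None:
    payload = {
        "dose_gy": float(proto.dose_per_fraction),
        "times_days": [float(t) for t in proto.treatment_times],
        "tw_days": float(proto.tw),
    }
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def read_protocol(path: str | Path) -> TreatmentProtocol:
    path = Path(path)
    text = path.read_text()
    try:
        payload = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except Exception as exc:
        raise ValidationError(f"could not parse protocol {path}: {exc}") from exc
    try:
        return TreatmentProtocol(
            dose_per_fraction=float(payload["dose_gy"]),
            treatment_times=tuple(float(t) for t in payload["times_days"]),
            tw=float(payload.get("tw_days", 1.0 / 96.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"{path}: malformed protocol mapping: {exc}") from exc


def write_fit_result(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, default=float) + "\n")


def read_fit_result(path: str | Path) -> FitResult:
    payload = json.loads(Path(path).read_text())
    try:
        return FitResult(**payload)
    except TypeError as exc:
        raise ValidationError(f"{path}: malformed fit result: {exc}") from exc
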