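"""Readers and writers for vibration records and cohort tables.

Records travel as WAV (float32, sampling rate in the header) or two-column
CSV (``time_s, velocity``), always with a JSON sidecar carrying the trigger
times and units. Cohorts travel as comma-separated CSV with a mandatory
header of unit-bearing column names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .pipeline import VibrationRecord
from .validation import SpecimenMeasurements, cohort_to_frame, frame_to_cohort

__all__ = [
    "write_record",
    "read_record",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

#: Mandatory cohort CSV schema (order fixed, units in the names).
COHORT_COLUMNS = ["specimen_id", "group", "peak_torque_Nm", "pullout_N", "isq", "rf_hz"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".triggers.json")


def write_record(
    record: VibrationRecord, path: str | Path, triggers_path: str | Path | None = None
) -> Path:
    """Write a record as WAV (.wav, float32) or CSV (.csv, float64 text).

    A JSON sidecar (default ``<path>.triggers.json``) stores the trigger
    times, units and sampling rate. Returns the sidecar path.
    """
    path = Path(path)
    if path.suffix.lower() == ".wav":
        wavfile.write(
            path, int(record.sampling_rate), record.samples.astype(np.float32)
        )
    elif path.suffix.lower() == ".csv":
        t = np.arange(record.samples.size) / record.sampling_rate
        df = pd.DataFrame({"time_s": t, "velocity": record.samples})
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unsupported record format {path.suffix!r} (wav/csv)")
    sidecar = Path(triggers_path) if triggers_path else _sidecar_path(path)
    sidecar.write_text(
        json.dumps(
            {
                "trigger_times_s": record.trigger_times.tolist(),
                "units": record.units,
                "sampling_rate_hz": record.sampling_rate,
            },
            indent=1,
        )
    )
    return sidecar


def read_record(
    path: str | Path, triggers_path: str | Path | None = None
) -> VibrationRecord:
    """Read a WAV or CSV record plus its trigger sidecar.

    WAV float32 samples are widened to float64 (the writer's float32
    rounding is the only loss in a WAV round trip); CSV records round-trip
    exactly at float64.
    """
    path = Path(path)
    sidecar = Path(triggers_path) if triggers_path else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"trigger sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("trigger_times_s", "units"):
        if key not in meta:
            raise ValueError(f"trigger sidecar {sidecar} missing key {key!r}")
    triggers = np.asarray(meta["trigger_times_s"], dtype=float)
    if triggers.ndim != 1 or (triggers.size > 1 and np.any(np.diff(triggers) <= 0)):
        raise ValueError(
            f"trigger sidecar {sidecar}: trigger_times_s must be strictly increasing"
        )

    if path.suffix.lower() == ".wav":
        rate, samples = wavfile.read(path)
        samples = np.asarray(samples, dtype=float)
    elif path.suffix.lower() == ".csv":
        df = _read_comma_csv(path, required=["time_s", "velocity"])
        samples = df["velocity"].to_numpy(dtype=float)
        dt = np.diff(df["time_s"].to_numpy(dtype=float))
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > 1e-9 * dt[0]):
            raise ValueError(f"{path}: time_s column is not uniformly sampled")
        rate = 1.0 / dt[0] if dt.size else float(meta.get("sampling_rate_hz", 1.0))
    else:
        raise ValueError(f"unsupported record format {path.suffix!r} (wav/csv)")

    return VibrationRecord(
        samples=samples,
        sampling_rate=float(rate),
        trigger_times=triggers,
        units=str(meta["units"]),
    )


def _read_comma_csv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    """Comma-dialect CSV reader with line-numbered schema diagnostics."""
    with open(path) as fh:
        header = fh.readline()
    if ";" in header and "," not in header:
        raise ValueError(
            f"{path}:1: semicolon-delimited file detected; "
            "this reader expects the comma dialect (hint: s/;/,/)"
        )
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}:1: missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    return df


def write_cohort(
    cohort: Sequence[SpecimenMeasurements] | pd.DataFrame, path: str | Path
) -> Path:
    """Write a cohort measurement table as comma-separated CSV with header."""
    path = Path(path)
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s) {missing}")
    df[COHORT_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    return path


def read_cohort(path: str | Path) -> list[SpecimenMeasurements]:
    """Read a cohort CSV, validating the schema (missing columns are named)."""
    df = _read_comma_csv(Path(path), required=COHORT_COLUMNS)
    return frame_to_cohort(df)
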