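"""File I/O: cohort tables, waveform files, results.

Dialect: comma-separated UTF-8 text with a header row and units encoded
in column names (``mpap_mmHg``, ``co_ml_min``, ...), eliminating unit
ambiguity at the file boundary.  Writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .waveforms import PressureTrace

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort_table",
    "write_cohort_table",
    "read_waveform_file",
    "write_waveform_file",
    "write_results",
]

#: required cohort-table columns (mvo2 optional on read)
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "hr_bpm",
    "mpap_mmHg",
    "pp_mmHg",
    "sv_ml",
    "co_ml_min",
    "mrv_ep_mmHg",
    "rv_edp_mmHg",
    "rv_edv_ml",
    "rv_esv_ml",
    "ef_frac",
    "sa_frac",
    "oef_frac",
    "q_rca_ml_min",
    "chb_g_ml",
]

_WAVE_COLUMNS = ["time_s", "rv_pressure_mmHg", "pa_pressure_mmHg"]
_REL_TOL = 1e-4  # tolerance for derived-field row validation


def _atomic_write(path: str | Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            writer(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Checks required columns, positivity, and the derived-field
    identities CO = HR·SV, EF = SV/RV_EDV, RV_ESV = RV_EDV − SV; errors
    name the offending row and column.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"cohort table {path}: missing columns {missing}")
    numeric = [c for c in COHORT_COLUMNS if c not in ("subject_id", "group")]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            raise InvalidInputError(
                f"cohort table {path}: non-numeric value in column {col!r}, "
                f"row {int(bad.idxmax())}"
            )
        df[col] = vals

    def check(lhs, rhs, what):
        err = np.abs(lhs - rhs) > _REL_TOL * np.maximum(np.abs(lhs), np.abs(rhs))
        if err.any():
            raise InvalidInputError(
                f"cohort table {path}: row {int(np.argmax(err.to_numpy()))} "
                f"violates {what}"
            )

    check(df["co_ml_min"], df["hr_bpm"] * df["sv_ml"], "CO = HR × SV")
    check(df["ef_frac"], df["sv_ml"] / df["rv_edv_ml"], "EF = SV / RV_EDV")
    check(df["rv_esv_ml"], df["rv_edv_ml"] - df["sv_ml"], "RV_ESV = RV_EDV − SV")
    return df


def write_cohort_table(path: str | Path, df: pd.DataFrame) -> None:
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False))


def read_waveform_file(path: str | Path) -> dict[str, PressureTrace]:
    """Read a waveform file (time_s, rv_pressure_mmHg, pa_pressure_mmHg
    and optionally pa_flow_ml_min) into PressureTraces.

    The time grid must be uniform; a skipped or irregular timestamp is a
    hard error.
    """
    df = pd.read_csv(path)
    missing = [c for c in _WAVE_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"waveform file {path}: missing columns {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise InvalidInputError(f"waveform file {path}: needs >= 2 samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6 * max(dt[0], 1e-12)) or dt[0] <= 0:
        raise InvalidInputError(
            f"waveform file {path}: non-uniform time grid (step varies)"
        )
    rate = 1.0 / dt[0]
    out = {
        "rv": PressureTrace(
            df["rv_pressure_mmHg"].to_numpy(float), rate, "RV_pressure", t0=t[0]
        ),
        "pa": PressureTrace(
            df["pa_pressure_mmHg"].to_numpy(float), rate, "PA_pressure", t0=t[0]
        ),
    }
    if "pa_flow_ml_min" in df.columns:
        out["flow"] = PressureTrace(
            df["pa_flow_ml_min"].to_numpy(float), rate, "PA_flow", t0=t[0]
        )
    return out


def write_waveform_file(
    path: str | Path,
    rv: PressureTrace,
    pa: PressureTrace,
    flow: PressureTrace | None = None,
) -> None:
    if rv.samples.size != pa.samples.size or abs(rv.rate - pa.rate) > 1e-9:
        raise InvalidInputError("RV and PA traces must share a time base")
    data = {
        "time_s": rv.times,
        "rv_pressure_mmHg": rv.samples,
        "pa_pressure_mmHg": pa.samples,
    }
    if flow is not None:
        if flow.samples.size != rv.samples.size:
            raise InvalidInputError("flow trace must share the time base")
        data["pa_flow_ml_min"] = flow.samples
    df = pd.DataFrame(data)
    _atomic_write(path, lambda fh: df.to_csv(fh, index=False))


def write_results(path: str | Path, results: dict) -> None:
    """Atomically write a JSON results document."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    _atomic_write(
        path, lambda fh: json.dump(results, fh, indent=2, default=default)
    )
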