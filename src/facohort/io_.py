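"""CSV schemas, readers/writers and table validation.

Three tables travel through the pipeline:

* ``dwellings.csv`` — dwelling_id + the ten predictor columns,
* ``measurements.csv`` — dwelling_id, season, fa_level (µg/m³), below_loq,
* ``subjects.csv`` — subject_id, outcome, the covariate columns,
  residence_history encoded ``dwelling:fraction;dwelling:fraction``, measured.

All files carry a header row, UTF-8, "." decimal separator; missing values are
empty fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DWELLING_LEVELS, OUTCOME_LEVELS, SEASONS, SUBJECT_LEVELS
from .errors import SchemaError

DWELLING_COLUMNS = ["dwelling_id"] + list(DWELLING_LEVELS) + ["window_open_hours"]
MEASUREMENT_COLUMNS = ["dwelling_id", "season", "fa_level", "below_loq"]
SUBJECT_COLUMNS = (
    ["subject_id", "outcome"] + list(SUBJECT_LEVELS) + ["residence_history", "measured"]
)


def format_history(history) -> str:
    return ";".join(f"{d}:{frac:g}" for d, frac in history)


def parse_history(text: str):
    out = []
    for part in str(text).split(";"):
        if not part:
            continue
        d, _, frac = part.partition(":")
        out.append((d, float(frac)))
    return out


def write_tables(outdir, dwellings, measurements, subjects) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwellings": outdir / "dwellings.csv",
        "measurements": outdir / "measurements.csv",
        "subjects": outdir / "subjects.csv",
    }
    dwellings[DWELLING_COLUMNS].to_csv(paths["dwellings"], index=False)
    measurements[MEASUREMENT_COLUMNS].to_csv(paths["measurements"], index=False)
    subj = subjects.copy()
    subj["residence_history"] = [
        h if isinstance(h, str) else format_history(h) for h in subj["residence_history"]
    ]
    subj[SUBJECT_COLUMNS].to_csv(paths["subjects"], index=False)
    return {k: str(v) for k, v in paths.items()}


def _require_columns(df, cols, name):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing column(s) {missing}")


def read_dwellings(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"dwelling_id": str})
    _require_columns(df, DWELLING_COLUMNS, "dwellings")
    for col in DWELLING_LEVELS:
        df[col] = df[col].astype(str)
    return df


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"dwelling_id": str})
    _require_columns(df, MEASUREMENT_COLUMNS, "measurements")
    return df


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "residence_history": str})
    _require_columns(df, SUBJECT_COLUMNS, "subjects")
    for col in SUBJECT_LEVELS:
        df[col] = df[col].astype(str)
    df["residence_history"] = df["residence_history"].map(parse_history)
    return df


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {"ok": self.ok, "errors": self.errors, "warnings": self.warnings}


def validate_tables(dwellings, measurements, subjects) -> ValidationReport:
    """Check levels, referential integrity, residence fractions and positivity."""
    rep = ValidationReport()

    def err(msg):
        rep.errors.append(msg)

    for col, levels in DWELLING_LEVELS.items():
        bad = set(dwellings[col].astype(str)) - set(levels)
        if bad:
            err(f"dwellings.{col}: unknown level(s) {sorted(bad)}")
    if (pd.to_numeric(dwellings["window_open_hours"], errors="coerce") < 0).any():
        err("dwellings.window_open_hours: negative values")
    if dwellings["dwelling_id"].duplicated().any():
        err("dwellings.dwelling_id: duplicated ids")

    known = set(dwellings["dwelling_id"])
    bad_season = set(measurements["season"]) - set(SEASONS)
    if bad_season:
        err(f"measurements.season: unknown level(s) {sorted(bad_season)}")
    orphan = set(measurements["dwelling_id"]) - known
    if orphan:
        err(f"measurements reference unknown dwelling(s) {sorted(orphan)[:5]}")
    levels_num = pd.to_numeric(measurements["fa_level"], errors="coerce")
    if (levels_num <= 0).any() or levels_num.isna().any():
        err("measurements.fa_level: non-positive or non-numeric values")
    dup = measurements.duplicated(["dwelling_id", "season"])
    if dup.any():
        err(f"measurements: duplicated dwelling/season pairs "
            f"({measurements[dup]['dwelling_id'].iloc[0]})")

    for col, levels in SUBJECT_LEVELS.items():
        bad = set(subjects[col].astype(str)) - set(levels)
        if bad:
            err(f"subjects.{col}: unknown level(s) {sorted(bad)}")
    if "outcome" in subjects.columns:
        bad = set(subjects["outcome"].dropna()) - set(OUTCOME_LEVELS)
        if bad:
            err(f"subjects.outcome: unknown level(s) {sorted(bad)}")
    for sid, entry in zip(subjects["subject_id"], subjects["residence_history"]):
        hist = parse_history(entry) if isinstance(entry, str) else list(entry)
        fracs = [f for _, f in hist]
        if any(f <= 0 for f in fracs):
            err(f"subjects.residence_history[{sid}]: non-positive fraction")
        if abs(sum(fracs) - 1.0) > 1e-6:
            err(f"subjects.residence_history[{sid}]: fractions sum to {sum(fracs):.4f}")
        unknown = [d for d, _ in hist if d not in known]
        if unknown:
            err(f"subject {sid} references unknown dwelling(s) {unknown}")

    n_measured = int(pd.to_numeric(subjects["measured"]).sum())
    if n_measured == 0:
        rep.warnings.append("no measured subjects flagged (R=1 group empty)")
    measured_d = set(measurements["dwelling_id"])
    if measured_d:
        flagged = {
            d
            for entry, flag in zip(subjects["residence_history"], subjects["measured"])
            if int(flag)
            for d, _ in (parse_history(entry) if isinstance(entry, str) else list(entry))
        }
        loose = measured_d - flagged
        if loose:
            rep.warnings.append(
                f"measurements exist for dwellings of unflagged subjects: {sorted(loose)[:5]}"
            )
    return rep
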