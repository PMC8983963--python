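"""File input/output: chamber-trial CSVs, fit records, profiles, configs.

The chamber-trial CSV is long format, one row per timed sample, with
columns ``trial_id, analyte, chamber_volume_ml, flow_ml_min, mass_g,
midpoint_hr, duration_min, conc_mg_m3`` (optional ``roast_level`` and
``physical_form``).  Rows within a trial may arrive in any order; they are
sorted by midpoint time, and duplicate times are rejected.  Schema errors
report the offending column or CSV row number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chamber import ChamberTrial, EmissionFit
from .errors import ParseError
from .scenario import ExposureProfile

__all__ = [
    "read_chamber_trials",
    "write_fits",
    "read_particles_csv",
    "write_profile_csv",
    "load_config",
]

REQUIRED_TRIAL_COLUMNS = [
    "trial_id", "analyte", "chamber_volume_ml", "flow_ml_min", "mass_g",
    "midpoint_hr", "duration_min", "conc_mg_m3",
]
_NUMERIC_TRIAL_COLUMNS = REQUIRED_TRIAL_COLUMNS[2:]


def read_chamber_trials(path) -> list[ChamberTrial]:
    """Parse and validate a chamber-trial CSV into ChamberTrial objects."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in _NUMERIC_TRIAL_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] if df[col].notna().any() else []
        bad = df.index[coerced.isna()]
        if len(bad) > 0:
            # +2: one for the header line, one for 0-based indexing.
            raise ParseError(f"{path}: non-numeric value in column {col!r}, row {bad[0] + 2}")
        df[col] = coerced
    trials: list[ChamberTrial] = []
    for trial_id, grp in df.groupby("trial_id", sort=False):
        grp = grp.sort_values("midpoint_hr")
        times = grp["midpoint_hr"].to_numpy()
        if np.any(np.diff(times) <= 0):
            row = int(grp.index[np.argmin(np.diff(times) > 0) + 1]) + 2
            raise ParseError(
                f"{path}: trial {trial_id!r} has duplicate/non-increasing midpoint times (row {row})"
            )
        meta = grp.iloc[0]
        samples = tuple(
            (float(t), float(c), float(d))
            for t, c, d in zip(times, grp["conc_mg_m3"], grp["duration_min"])
        )
        def _opt(col: str):
            v = meta.get(col)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else str(v)
        trials.append(ChamberTrial(
            trial_id=str(trial_id),
            analyte=str(meta["analyte"]),
            chamber_volume_ml=float(meta["chamber_volume_ml"]),
            flow_ml_min=float(meta["flow_ml_min"]),
            sample_mass_g=float(meta["mass_g"]),
            samples=samples,
            roast_level=_opt("roast_level"),
            physical_form=_opt("physical_form"),
        ))
    return trials


def write_fits(fits: list[EmissionFit], path) -> None:
    """Write fit records as JSON (``.json``) or CSV (anything else)."""
    path = Path(path)
    records = [f.as_dict() for f in fits]
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=2, default=_json_default))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def read_particles_csv(path) -> pd.DataFrame:
    """Particle-diameter list: columns ``physical_form, diameter_cm``."""
    df = pd.read_csv(path)
    for col in ("physical_form", "diameter_cm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    df["diameter_cm"] = pd.to_numeric(df["diameter_cm"], errors="raise")
    return df


def write_profile_csv(profile: ExposureProfile, path) -> None:
    pd.DataFrame({
        "time_min": profile.times_min,
        "conc_ppb": profile.worker_ppb,
        "c_ff_ppb": profile.far_field_ppb,
        "running_twa_ppb": profile.running_twa_ppb,
    }).to_csv(path, index=False)


def load_config(path) -> dict:
    """Load a YAML or JSON configuration document."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such config file: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
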