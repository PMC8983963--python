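"""Seeded generators for every input the pipeline consumes.

Three generators with known ground truth make the whole chain testable
without laboratory data:

* chamber concentration series following the decaying-source curve at the
  standard eight sample midpoints, with multiplicative lognormal noise;
* lognormal Feret-diameter samples with a specified GM/GSD;
* storage-age SER series with a linear trend and Gaussian noise.

All randomness flows through :func:`numpy.random.default_rng` with an
explicit integer seed, so identical seeds reproduce identical output
bit-for-bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chamber import ChamberTrial, model_concentration
from .errors import InvalidParameterError

__all__ = [
    "ChamberDesign",
    "TrueEmissionParams",
    "reference_design",
    "gen_chamber_series",
    "gen_particle_sample",
    "gen_storage_series",
    "write_trials_csv",
    "write_truth_sidecar",
]


@dataclass(frozen=True)
class ChamberDesign:
    """Chamber geometry and sampling plan for a synthetic emission test."""

    chamber_volume_ml: float
    flow_ml_min: float
    sample_mass_g: float
    midpoint_times_hr: tuple[float, ...]
    sample_durations_min: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.chamber_volume_ml <= 0 or self.flow_ml_min <= 0 or self.sample_mass_g <= 0:
            raise InvalidParameterError("volume, flow and mass must be > 0")
        t = np.asarray(self.midpoint_times_hr, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise InvalidParameterError("midpoint times must be positive and strictly increasing")
        if len(self.sample_durations_min) != t.size:
            raise InvalidParameterError("one duration per midpoint time required")


@dataclass(frozen=True)
class TrueEmissionParams:
    """Ground-truth source parameters (and noise level) for a synthetic trial."""

    ef0: float
    ef_ss: float
    k: float
    seed: int
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.ef0 < 0 or self.ef_ss < 0:
            raise InvalidParameterError("emission factors must be >= 0")
        if self.k <= 0:
            raise InvalidParameterError("decay rate k must be > 0")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise CV must be >= 0")


def reference_design() -> ChamberDesign:
    """The standard micro-chamber protocol: 114 mL chamber swept at
    39.4 mL/min holding 5.2 g of coffee, sampled at midpoints
    2, 4, 6, 8, 10, 15, 35 and 60 min (first five for 30 s, last three
    for 1 min)."""
    minutes = (2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 35.0, 60.0)
    durations = (0.5,) * 5 + (1.0,) * 3
    return ChamberDesign(
        chamber_volume_ml=114.0,
        flow_ml_min=39.4,
        sample_mass_g=5.2,
        midpoint_times_hr=tuple(m / 60.0 for m in minutes),
        sample_durations_min=durations,
    )


def gen_chamber_series(
    design: ChamberDesign,
    truth: TrueEmissionParams,
    trial_id: str = "synthetic",
    analyte: str = "diacetyl",
    roast_level: str | None = None,
    physical_form: str | None = None,
) -> ChamberTrial:
    """Synthetic chamber trial: model curve at the design midpoints times
    independent unit-median lognormal noise with coefficient of variation
    ``truth.noise_cv``.

    Concentrations are generated at the midpoint instant; sample durations
    are carried as metadata only.  The ground truth is not stored on the
    trial (the trial mimics a measured dataset); keep ``truth`` alongside
    for recovery tests or persist it with :func:`write_truth_sidecar`.
    """
    n_air = 60.0 * design.flow_ml_min / design.chamber_volume_ml
    loading = design.sample_mass_g / design.chamber_volume_ml * 1000.0
    t = np.asarray(design.midpoint_times_hr, dtype=float)
    if truth.ef0 == 0.0 and truth.ef_ss == 0.0:
        clean = np.zeros_like(t)
    else:
        clean = model_concentration(truth.ef0, truth.ef_ss, truth.k, n_air, loading, t)
    if truth.noise_cv > 0:
        rng = np.random.default_rng(truth.seed)
        # Unit-median multiplicative noise: exp(sigma * Z) with
        # sigma^2 = ln(1 + cv^2).
        sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2))
        noise = np.exp(sigma * rng.standard_normal(t.size))
        conc = clean * noise
    else:
        conc = clean
    samples = tuple(
        (float(ti), float(ci), float(di))
        for ti, ci, di in zip(t, conc, design.sample_durations_min)
    )
    return ChamberTrial(
        trial_id=trial_id,
        analyte=analyte,
        chamber_volume_ml=design.chamber_volume_ml,
        flow_ml_min=design.flow_ml_min,
        sample_mass_g=design.sample_mass_g,
        samples=samples,
        roast_level=roast_level,
        physical_form=physical_form,
    )


def gen_particle_sample(gm: float, gsd: float, n: int, seed: int) -> np.ndarray:
    """``n`` lognormal Feret-diameter draws (cm) with geometric mean ``gm``
    and geometric standard deviation ``gsd`` (log-mean ln gm, log-SD ln gsd)."""
    if gm <= 0:
        raise InvalidParameterError("geometric mean must be > 0")
    if gsd < 1.0:
        raise InvalidParameterError("geometric standard deviation must be >= 1")
    if n < 1:
        raise InvalidParameterError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=math.log(gm), sigma=math.log(gsd), size=n)


def gen_storage_series(
    intercept: float,
    slope: float,
    days,
    noise_sd: float,
    seed: int,
) -> pd.DataFrame:
    """Storage-age SER series: SER(day) = intercept + slope*day + N(0, sd).

    Returns a DataFrame with columns ``day`` and ``ser``.
    """
    days = np.asarray(list(days), dtype=float)
    if days.size == 0:
        raise InvalidParameterError("days must be nonempty")
    if noise_sd < 0:
        raise InvalidParameterError("noise SD must be >= 0")
    ser = intercept + slope * days
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ser = ser + noise_sd * rng.standard_normal(days.size)
    return pd.DataFrame({"day": days, "ser": ser})


TRIAL_CSV_COLUMNS = [
    "trial_id", "analyte", "chamber_volume_ml", "flow_ml_min", "mass_g",
    "midpoint_hr", "duration_min", "conc_mg_m3", "roast_level", "physical_form",
]


def write_trials_csv(trials, path) -> None:
    """Serialize trials to the long-format CSV schema (one row per sample)."""
    rows = []
    for tr in trials:
        for t_hr, c, dur in tr.samples:
            rows.append({
                "trial_id": tr.trial_id,
                "analyte": tr.analyte,
                "chamber_volume_ml": tr.chamber_volume_ml,
                "flow_ml_min": tr.flow_ml_min,
                "mass_g": tr.sample_mass_g,
                "midpoint_hr": t_hr,
                "duration_min": dur,
                "conc_mg_m3": c,
                "roast_level": tr.roast_level or "",
                "physical_form": tr.physical_form or "",
            })
    pd.DataFrame(rows, columns=TRIAL_CSV_COLUMNS).to_csv(path, index=False)


def write_truth_sidecar(truths: dict[str, TrueEmissionParams], path) -> None:
    """Persist ground-truth parameters keyed by trial id next to a fixture CSV."""
    payload = {
        tid: {"ef0": tp.ef0, "ef_ss": tp.ef_ss, "k": tp.k,
              "seed": tp.seed, "noise_cv": tp.noise_cv}
        for tid, tp in truths.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))
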