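"""Probabilistic exposure assessment: input sampling, MC propagation, and
the inter-zone-flow sensitivity sweep.

Input uncertainty follows the published convention for this kind of model:
measured flows get a uniform distribution over their stated range,
generation rates get a normal distribution whose stated ``+/-`` half-width
is a 95% confidence interval (sd = half-width / 1.96), and anything known
exactly is fixed.  Physically positive parameters are truncated at zero by
rejection (redrawn), with the number of rejected draws reported.

Each Monte Carlo draw re-runs the full scenario simulation; outputs are
reduced to medians and 95th percentiles (linear-interpolation percentile
method) per task label and for the full shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import DIACETYL_REL_PPB, DIACETYL_STEL_PPB
from .errors import ConfigError, InvalidParameterError, MonteCarloError
from .scenario import (
    NEAR_FIELD,
    ExposureProfile,
    Schedule,
    full_shift_twa,
    simulate_schedule,
)
from .twozone import NearFieldGeometry, TwoZoneSystem, mass_to_ppb, steady_state

__all__ = [
    "Uniform",
    "Normal",
    "Fixed",
    "MCSpec",
    "DrawSet",
    "ExposureSummary",
    "SensitivityResult",
    "parse_distribution",
    "sample_inputs",
    "run_mc",
    "mc_steady_state",
    "sensitivity_beta",
]


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError("uniform distribution needs lo < hi")

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, int]:
        return rng.uniform(self.lo, self.hi, size=n), 0


@dataclass(frozen=True)
class Normal:
    mean: float
    sd: float
    truncate_positive: bool = True

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigError("normal distribution needs sd >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, int]:
        x = self.mean + self.sd * rng.standard_normal(n)
        rejected = 0
        if self.truncate_positive and self.sd > 0:
            bad = x <= 0
            while bad.any():
                rejected += int(bad.sum())
                x[bad] = self.mean + self.sd * rng.standard_normal(int(bad.sum()))
                bad = x <= 0
        return x, rejected


@dataclass(frozen=True)
class Fixed:
    value: float

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, int]:
        return np.full(n, self.value, dtype=float), 0


def parse_distribution(spec) -> Uniform | Normal | Fixed:
    """Accept Uniform/Normal/Fixed instances, dicts, scalars or tuples.

    Dict forms: ``{"kind": "uniform", "lo": ..., "hi": ...}``,
    ``{"kind": "normal", "mean": ..., "sd": ..., "truncate_positive": ...}``,
    ``{"kind": "fixed", "value": ...}``.  A bare number means fixed.
    """
    if isinstance(spec, (Uniform, Normal, Fixed)):
        return spec
    if isinstance(spec, (int, float)):
        return Fixed(float(spec))
    if isinstance(spec, dict):
        kind = spec.get("kind")
        if kind == "uniform":
            return Uniform(float(spec["lo"]), float(spec["hi"]))
        if kind == "normal":
            return Normal(float(spec["mean"]), float(spec["sd"]),
                          bool(spec.get("truncate_positive", True)))
        if kind == "fixed":
            return Fixed(float(spec["value"]))
        raise ConfigError(f"unknown distribution kind {kind!r}")
    raise ConfigError(f"cannot interpret distribution spec {spec!r}")


@dataclass(frozen=True)
class MCSpec:
    """Monte Carlo plan: iteration count, mandatory seed, distributions.

    Distribution keys name what they perturb: ``supply_air``,
    ``interzone_flow``, ``room_volume``, or ``generation:<label>`` for the
    source strength of every segment with that label.
    """

    n_iterations: int
    seed: int
    distributions: dict

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ConfigError("n_iterations must be >= 1")
        object.__setattr__(
            self,
            "distributions",
            {k: parse_distribution(v) for k, v in self.distributions.items()},
        )


@dataclass(frozen=True)
class DrawSet:
    draws: pd.DataFrame
    truncation_counts: dict[str, int]


def sample_inputs(spec: MCSpec) -> DrawSet:
    """Seeded draws for every distribution (one column per parameter)."""
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, np.ndarray] = {}
    trunc: dict[str, int] = {}
    for name in sorted(spec.distributions):
        x, rejected = spec.distributions[name].sample(rng, spec.n_iterations)
        cols[name] = x
        trunc[name] = rejected
    return DrawSet(pd.DataFrame(cols), trunc)


@dataclass
class ExposureSummary:
    n_draws: int
    n_failed: int
    per_task: dict[str, dict[str, float]]
    full_shift_median_ppb: float
    full_shift_p95_ppb: float
    prob_exceed_rel: float
    prob_task_exceed_stel: float
    full_shift_median_batch_se: float
    truncation_counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "n_failed": self.n_failed,
            "per_task": self.per_task,
            "full_shift_median_ppb": self.full_shift_median_ppb,
            "full_shift_p95_ppb": self.full_shift_p95_ppb,
            "prob_exceed_rel": self.prob_exceed_rel,
            "prob_task_exceed_stel": self.prob_task_exceed_stel,
            "full_shift_median_batch_se": self.full_shift_median_batch_se,
            "truncation_counts": self.truncation_counts,
        }


def _apply_draw(system: TwoZoneSystem, schedule: Schedule,
                row: pd.Series) -> tuple[TwoZoneSystem, Schedule]:
    sys_kwargs = {}
    gen_overrides = {}
    for name, value in row.items():
        if name in ("supply_air", "interzone_flow", "room_volume", "nf_volume"):
            sys_kwargs[name] = float(value)
        elif name.startswith("generation:"):
            gen_overrides[name.split(":", 1)[1]] = float(value)
        else:
            raise ConfigError(f"distribution {name!r} does not map to any model input")
    if sys_kwargs:
        system = replace(system, **sys_kwargs)
    if gen_overrides:
        schedule = schedule.scaled_generation(gen_overrides)
    return system, schedule


def _batch_se_of_median(values: np.ndarray, n_batches: int = 10) -> float:
    if values.size < 2 * n_batches:
        n_batches = max(2, values.size // 2)
    batches = np.array_split(values, n_batches)
    meds = np.array([np.median(b) for b in batches])
    return float(meds.std(ddof=1) / math.sqrt(len(meds)))


def run_mc(
    schedule,
    system: TwoZoneSystem,
    spec: MCSpec,
    geometry: NearFieldGeometry | None = None,
    dt_min: float = 0.1,
    rel_ppb: float = DIACETYL_REL_PPB,
    stel_ppb: float = DIACETYL_STEL_PPB,
    max_failure_fraction: float = 0.01,
) -> ExposureSummary:
    """Propagate input uncertainty through the full shift simulation.

    Per draw, the schedule's per-label generation rates and the system's
    ventilation parameters are replaced by the sampled values and the shift
    is re-simulated; draw failures are skipped and counted, and the run
    aborts if more than ``max_failure_fraction`` of draws fail.
    """
    from .scenario import build_schedule  # late import to avoid cycle at module load

    schedule = build_schedule(schedule)
    if geometry is not None:
        system = replace(system, interzone_flow=geometry.beta,
                         nf_volume=geometry.volume)
    drawset = sample_inputs(spec)
    n = spec.n_iterations

    task_vals: dict[str, list[float]] = {}
    shift_vals: list[float] = []
    n_rel, n_stel, n_failed = 0, 0, 0

    for i in range(n):
        row = drawset.draws.iloc[i]
        try:
            sys_i, sched_i = _apply_draw(system, schedule, row)
            profile = simulate_schedule(sched_i, sys_i, dt_min=dt_min)
        except ConfigError:
            raise
        except Exception:
            n_failed += 1
            continue
        fs = full_shift_twa(profile)
        shift_vals.append(fs)
        if fs > rel_ppb:
            n_rel += 1
        draw_max_task = 0.0
        for label, twas in profile.per_task_twa.items():
            locs = {r.location for r in profile.segment_results if r.label == label}
            if NEAR_FIELD not in locs:
                continue
            task_vals.setdefault(label, []).append(float(np.mean(twas)))
            draw_max_task = max(draw_max_task, max(twas))
        if draw_max_task > stel_ppb:
            n_stel += 1

    if n_failed > max_failure_fraction * n:
        raise MonteCarloError(
            f"{n_failed}/{n} Monte Carlo draws failed (> {max_failure_fraction:.0%})"
        )
    if not shift_vals:
        raise MonteCarloError("no successful Monte Carlo draws")

    shift_arr = np.asarray(shift_vals)
    per_task = {
        label: {
            "median": float(np.percentile(v, 50)),
            "p95": float(np.percentile(v, 95)),
        }
        for label, v in task_vals.items()
    }
    n_ok = len(shift_vals)
    return ExposureSummary(
        n_draws=n,
        n_failed=n_failed,
        per_task=per_task,
        full_shift_median_ppb=float(np.percentile(shift_arr, 50)),
        full_shift_p95_ppb=float(np.percentile(shift_arr, 95)),
        prob_exceed_rel=n_rel / n_ok,
        prob_task_exceed_stel=n_stel / n_ok,
        full_shift_median_batch_se=_batch_se_of_median(shift_arr),
        truncation_counts=drawset.truncation_counts,
    )


def mc_steady_state(system: TwoZoneSystem, spec: MCSpec,
                    generation_key: str = "generation:task") -> dict[str, float]:
    """Steady-state near-field concentration (ppb) under MC inputs.

    A lightweight mode for long tasks: per draw the near-field steady state
    G * (1/Q + 1/beta) is evaluated directly instead of simulating a shift.
    Returns median, p95 and the batch SE of the median.
    """
    drawset = sample_inputs(spec)
    conv = mass_to_ppb(1.0, system.molar_mass)
    n = spec.n_iterations
    cols = drawset.draws
    for name in cols.columns:
        if name not in (generation_key, "supply_air", "interzone_flow"):
            raise ConfigError(f"distribution {name!r} does not map to a steady-state input")
    g = cols[generation_key].to_numpy() if generation_key in cols else np.full(n, system.generation)
    q = cols["supply_air"].to_numpy() if "supply_air" in cols else np.full(n, system.supply_air)
    b = cols["interzone_flow"].to_numpy() if "interzone_flow" in cols else np.full(n, system.interzone_flow)
    vals = g * (1.0 / q + 1.0 / b) * conv
    return {
        "median": float(np.percentile(vals, 50)),
        "p95": float(np.percentile(vals, 95)),
        "batch_se_median": _batch_se_of_median(vals),
    }


@dataclass
class SensitivityResult:
    table: pd.DataFrame            # beta, inv_beta, c_nf_ppb
    slope_ppb_m3_min: float        # d C_nf / d (1/beta): the generation in ppb units
    intercept_ppb: float           # G/Q in ppb
    max_abs_residual_ppb: float

    def fold_change(self, beta_lo: float, beta_hi: float) -> float:
        """Concentration ratio C(beta_lo) / C(beta_hi) between two grid points."""
        t = self.table.set_index("beta")["c_nf_ppb"]
        return float(t.loc[beta_lo] / t.loc[beta_hi])


def sensitivity_beta(system: TwoZoneSystem, beta_grid) -> SensitivityResult:
    """Steady-state near-field concentration across an inter-zone-flow grid.

    The reduced steady-state form C_N = G/Q + G * (1/beta) is exactly
    linear in 1/beta; the least-squares line is reported (slope = G,
    intercept = G/Q, both in ppb units) together with residuals, which are
    zero up to round-off.
    """
    betas = np.asarray(list(beta_grid), dtype=float)
    if betas.size == 0 or np.any(betas <= 0):
        raise InvalidParameterError("beta grid must be nonempty and positive")
    conv = mass_to_ppb(1.0, system.molar_mass)
    c = np.array([
        steady_state(replace(system, interzone_flow=float(b))).c_nf * conv
        for b in betas
    ])
    table = pd.DataFrame({"beta": betas, "inv_beta": 1.0 / betas, "c_nf_ppb": c})
    if betas.size >= 2:
        slope, intercept = np.polyfit(1.0 / betas, c, 1)
        resid = c - (slope / betas + intercept)
        max_resid = float(np.abs(resid).max())
    else:
        slope = math.nan
        intercept = float(c[0])
        max_resid = 0.0
    return SensitivityResult(table, float(slope), float(intercept), max_resid)
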