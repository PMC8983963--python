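"""Emission-chamber kinetics: the first-order decaying-source model.

A small dynamic emission chamber holds a mass ``m`` of roasted coffee and is
swept with clean air at flow ``Q``.  The exhaust concentration traces a
buildup-and-decay curve: the specific emission rate (SER) of the coffee
starts at an initial value ``EF0`` and decays exponentially at rate ``k``
toward a steady-state value ``EFss``, while the chamber air exchanges at
rate ``N = Q/V``.  The resulting chamber concentration is

    C(t) = L * EF0 * (exp(-k t) - exp(-N t)) / (N - k)
         + L * EFss * (1 - exp(-N t)) / N

with ``L = m/V`` the loading factor (kg of material per m3 of chamber).
Both terms vanish at t = 0 and the second converges to the steady-state
concentration ``L * EFss / N`` implied by a constant residual SER.

Fitting this curve to timed concentration samples yields (EF0, EFss, k);
the peak of the fitted curve gives the maximum SER

    EFmax = Cmax * N / L = Cmax * Q / m

and a transient mass-balance correction for incomplete chamber response
inflates it slightly to

    EFbuildup = EFmax / (1 - exp(-N * tmax))  >=  EFmax.

Units throughout: concentrations mg/m3, SERs mg kg-1 hr-1, times hr,
N and k hr-1, L kg/m3.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import (
    DegenerateParameterError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "ChamberTrial",
    "EmissionFit",
    "air_exchange_rate",
    "loading_factor",
    "model_concentration",
    "fit_emission_curve",
    "peak_concentration",
    "closed_form_t_max",
    "ef_max",
    "ef_buildup",
    "DEFAULT_EF0_STARTS",
    "DEFAULT_EFSS_STARTS",
    "DEFAULT_K_STARTS",
]

#: Multi-start grids for the nonlinear fit: initial and steady-state SER
#: starts span 0.1-5 in steps of 1, the decay-rate starts span 0.1-4.
DEFAULT_EF0_STARTS: tuple[float, ...] = (0.1, 1.1, 2.1, 3.1, 4.1)
DEFAULT_EFSS_STARTS: tuple[float, ...] = (0.1, 1.1, 2.1, 3.1, 4.1)
DEFAULT_K_STARTS: tuple[float, ...] = (0.1, 1.1, 2.1, 3.1)

#: Grid resolution (hr) of the initial peak scan before polishing.
PEAK_GRID_HR: float = 1e-4


@dataclass(frozen=True)
class ChamberTrial:
    """One emission test: chamber geometry, coffee mass, timed samples.

    ``samples`` holds (midpoint time hr, concentration mg/m3, duration min)
    triples ordered by time.  Optional ``roast_level`` / ``physical_form``
    metadata travel with the trial so downstream summaries can group fits.
    """

    trial_id: str
    analyte: str
    chamber_volume_ml: float
    flow_ml_min: float
    sample_mass_g: float
    samples: tuple[tuple[float, float, float], ...]
    roast_level: str | None = None
    physical_form: str | None = None

    def __post_init__(self) -> None:
        if self.chamber_volume_ml <= 0 or self.flow_ml_min <= 0:
            raise InvalidParameterError("chamber volume and flow must be > 0")
        if self.sample_mass_g <= 0:
            raise InvalidParameterError("sample mass must be > 0")
        times = self.times_hr
        if np.any(np.diff(times) <= 0):
            raise InvalidParameterError("sample midpoint times must be strictly increasing")
        if np.any(times <= 0):
            raise InvalidParameterError("sample midpoint times must be positive")
        if np.any(self.concentrations_mg_m3 < 0):
            raise InvalidParameterError("concentrations must be >= 0")

    @property
    def times_hr(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def concentrations_mg_m3(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)

    @property
    def durations_min(self) -> np.ndarray:
        return np.array([s[2] for s in self.samples], dtype=float)

    @property
    def air_exchange_hr(self) -> float:
        return air_exchange_rate(self.flow_ml_min, self.chamber_volume_ml)

    @property
    def loading_kg_m3(self) -> float:
        return loading_factor(self.sample_mass_g, self.chamber_volume_ml)


@dataclass
class EmissionFit:
    """Fitted source parameters and the derived peak/buildup emission factors."""

    trial_id: str
    analyte: str
    ef0: float
    ef_ss: float
    k: float
    air_exchange: float
    loading: float
    c_max: float
    t_max: float
    ef_max: float
    ef_buildup: float
    sse: float
    converged: bool
    boundary_max: bool = False
    n_starts_converged: int = 0
    roast_level: str | None = None
    physical_form: str | None = None

    def as_dict(self) -> dict:
        return {
            "trial_id": self.trial_id,
            "analyte": self.analyte,
            "ef0": self.ef0,
            "ef_ss": self.ef_ss,
            "k": self.k,
            "air_exchange": self.air_exchange,
            "loading": self.loading,
            "c_max": self.c_max,
            "t_max": self.t_max,
            "ef_max": self.ef_max,
            "ef_buildup": self.ef_buildup,
            "sse": self.sse,
            "converged": self.converged,
            "boundary_max": self.boundary_max,
            "n_starts_converged": self.n_starts_converged,
            "roast_level": self.roast_level,
            "physical_form": self.physical_form,
        }


def air_exchange_rate(flow_ml_min: float, chamber_volume_ml: float) -> float:
    """Air changes per hour: N = 60 * flow / volume.

    39.4 mL/min through a 114 mL chamber gives ~20.7 hr-1.
    """
    if flow_ml_min <= 0 or chamber_volume_ml <= 0:
        raise InvalidParameterError("flow and volume must be > 0")
    return 60.0 * flow_ml_min / chamber_volume_ml


def loading_factor(sample_mass_g: float, chamber_volume_ml: float) -> float:
    """Loading factor L (kg/m3): sample mass over chamber volume.

    5.2 g in 114 mL gives ~45.6 kg/m3.
    """
    if sample_mass_g <= 0 or chamber_volume_ml <= 0:
        raise InvalidParameterError("mass and volume must be > 0")
    # g/mL == kg/L, so multiply by 1000 L/m3.
    return sample_mass_g / chamber_volume_ml * 1000.0


def _phi(x: np.ndarray) -> np.ndarray:
    """(1 - exp(-x)) / x, stable near x = 0 (limit 1)."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-8
    safe = np.where(small, 1.0, x)
    out = -np.expm1(-safe) / safe
    return np.where(small, 1.0 - x / 2.0 + x * x / 6.0, out)


def model_concentration(ef0, ef_ss, k, n_air, loading, t):
    """Chamber concentration (mg/m3) of the decaying source at time(s) ``t`` (hr).

    The buildup/decay difference quotient is evaluated in the numerically
    stable form ``exp(-k t) * t * phi((N-k) t)`` so the fit can approach
    (without reaching) the removable k = N singularity.  Exact (or
    near-machine) coincidence of k and N is rejected; callers that land
    there should perturb k.
    """
    if k <= 0:
        raise InvalidParameterError("decay rate k must be > 0")
    if n_air <= 0 or loading <= 0:
        raise InvalidParameterError("air exchange rate and loading must be > 0")
    if abs(k - n_air) <= 1e-12 * max(abs(n_air), 1.0):
        raise DegenerateParameterError("k == N: decaying-source form is singular")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    buildup = loading * ef0 * np.exp(-k * t) * t * _phi((n_air - k) * t)
    asymptote = loading * ef_ss * (-np.expm1(-n_air * t)) / n_air
    c = buildup + asymptote
    if not np.all(np.isfinite(c)):
        raise InvalidParameterError("model concentration is non-finite")
    return float(c) if c.ndim == 0 else c


def closed_form_t_max(k: float, n_air: float) -> float:
    """Peak time ln(N/k)/(N - k) of the pure decaying source (EFss = 0)."""
    if k <= 0 or n_air <= 0:
        raise InvalidParameterError("k and N must be > 0")
    if abs(k - n_air) <= 1e-12 * max(abs(n_air), 1.0):
        raise DegenerateParameterError("k == N has no closed-form peak time")
    return math.log(n_air / k) / (n_air - k)


def peak_concentration(
    ef0: float,
    ef_ss: float,
    k: float,
    n_air: float,
    loading: float,
    t_end: float,
) -> tuple[float, float, bool]:
    """Maximum of the fitted curve on (0, t_end].

    Returns ``(c_max, t_max, boundary)``.  The search scans a uniform grid
    at :data:`PEAK_GRID_HR` resolution then polishes the best interior
    bracket with bounded scalar minimization.  A curve still rising at
    ``t_end`` (pure-asymptote case, EF0 = 0) reports the boundary value with
    ``boundary=True``.
    """
    if t_end <= 0:
        raise InvalidParameterError("t_end must be > 0")
    n_grid = max(int(round(t_end / PEAK_GRID_HR)), 8)
    ts = np.linspace(t_end / n_grid, t_end, n_grid)
    cs = model_concentration(ef0, ef_ss, k, n_air, loading, ts)
    i = int(np.argmax(cs))
    if i == n_grid - 1:
        return float(cs[i]), float(ts[i]), True
    lo = ts[i - 1] if i > 0 else ts[0] / 2.0
    hi = ts[i + 1]
    res = optimize.minimize_scalar(
        lambda t: -model_concentration(ef0, ef_ss, k, n_air, loading, t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    t_max = float(res.x)
    c_max = float(-res.fun)
    return c_max, t_max, False


def ef_max(c_max: float, flow_m3_hr: float, sample_mass_kg: float) -> float:
    """Peak SER (mg kg-1 hr-1): EFmax = Cmax * Q / m (== Cmax * N / L)."""
    if flow_m3_hr <= 0 or sample_mass_kg <= 0:
        raise InvalidParameterError("flow and mass must be > 0")
    if c_max < 0:
        raise InvalidParameterError("c_max must be >= 0")
    return c_max * flow_m3_hr / sample_mass_kg


def ef_buildup(ef_max_value: float, n_air: float, t_max: float) -> float:
    """Buildup-corrected SER: EFmax / (1 - exp(-N tmax)) >= EFmax.

    The chamber has only equilibrated to a fraction (1 - exp(-N tmax)) of a
    constant source by the peak time, so the source strength consistent with
    the observed peak is the measured EFmax divided by that fraction.  The
    correction vanishes (ratio -> 1) as N * tmax grows.
    """
    if n_air <= 0:
        raise InvalidParameterError("air exchange rate must be > 0")
    if t_max <= 0:
        raise InvalidParameterError("t_max must be > 0 (buildup correction undefined)")
    return ef_max_value / (-np.expm1(-n_air * t_max))


def _fit_residuals(params: np.ndarray, t: np.ndarray, c_obs: np.ndarray,
                   n_air: float, loading: float) -> np.ndarray:
    ef0, ef_ss, k = params
    return model_concentration(ef0, ef_ss, k, n_air, loading, t) - c_obs


def fit_emission_curve(
    trial: ChamberTrial,
    ef0_starts: tuple[float, ...] = DEFAULT_EF0_STARTS,
    efss_starts: tuple[float, ...] = DEFAULT_EFSS_STARTS,
    k_starts: tuple[float, ...] = DEFAULT_K_STARTS,
) -> EmissionFit:
    """Least-squares fit of (EF0, EFss, k) to a chamber trial.

    N and L are fixed from the trial's measured geometry, never fitted.
    Every combination of the start grids seeds a bounded trust-region
    least-squares solve (parameters constrained nonnegative, k > 0); the
    converged solution with the lowest SSE wins, ties broken toward the
    smallest k.  Starts that land on k = N are nudged by 1e-6 relative.
    """
    t = trial.times_hr
    c_obs = trial.concentrations_mg_m3
    if len(t) < 4:
        raise InsufficientDataError(
            f"trial {trial.trial_id}: need >= 4 samples for a 3-parameter fit, got {len(t)}"
        )
    n_air = trial.air_exchange_hr
    loading = trial.loading_kg_m3

    if np.all(c_obs == 0.0):
        # Zero source fits exactly; k is unidentifiable, report a nominal 1.
        t_end = float(t[-1])
        return EmissionFit(
            trial_id=trial.trial_id, analyte=trial.analyte,
            ef0=0.0, ef_ss=0.0, k=1.0,
            air_exchange=n_air, loading=loading,
            c_max=0.0, t_max=t_end, ef_max=0.0, ef_buildup=0.0,
            sse=0.0, converged=True, boundary_max=True,
            roast_level=trial.roast_level, physical_form=trial.physical_form,
        )

    best = None
    n_converged = 0
    for ef0_0, efss_0, k_0 in itertools.product(ef0_starts, efss_starts, k_starts):
        if abs(k_0 - n_air) <= 1e-12 * n_air:
            k_0 = k_0 * (1.0 + 1e-6)
        try:
            res = optimize.least_squares(
                _fit_residuals,
                x0=np.array([ef0_0, efss_0, k_0], dtype=float),
                bounds=(np.array([0.0, 0.0, 1e-9]), np.array([np.inf] * 3)),
                args=(t, c_obs, n_air, loading),
                ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=200,
            )
        except (DegenerateParameterError, InvalidParameterError):
            continue
        if not res.success:
            continue
        n_converged += 1
        sse = float(2.0 * res.cost)
        k_hat = float(res.x[2])
        key = (sse, k_hat)
        if best is None or key < (best[0], best[1]):
            best = (sse, k_hat, res.x)
        if sse < 1e-20:
            break

    if best is None:
        return EmissionFit(
            trial_id=trial.trial_id, analyte=trial.analyte,
            ef0=math.nan, ef_ss=math.nan, k=math.nan,
            air_exchange=n_air, loading=loading,
            c_max=math.nan, t_max=math.nan, ef_max=math.nan, ef_buildup=math.nan,
            sse=math.inf, converged=False, n_starts_converged=0,
            roast_level=trial.roast_level, physical_form=trial.physical_form,
        )

    # Polish the winning start at tight tolerances.
    sse, _, x = best
    try:
        res = optimize.least_squares(
            _fit_residuals, x0=np.asarray(x, dtype=float),
            bounds=(np.array([0.0, 0.0, 1e-9]), np.array([np.inf] * 3)),
            args=(t, c_obs, n_air, loading),
            ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=400,
        )
        if res.success and 2.0 * res.cost <= sse:
            sse, x = float(2.0 * res.cost), res.x
    except (DegenerateParameterError, InvalidParameterError):
        pass
    ef0_hat, efss_hat, k_hat = (float(v) for v in x)
    k_hat = max(k_hat, 1e-9)
    t_end = float(t[-1])
    c_max, t_max, boundary = peak_concentration(
        ef0_hat, efss_hat, k_hat, n_air, loading, t_end
    )
    efmax_hat = ef_max(
        c_max,
        flow_m3_hr=trial.flow_ml_min * 60.0 / 1e6,
        sample_mass_kg=trial.sample_mass_g / 1000.0,
    )
    efb_hat = ef_buildup(efmax_hat, n_air, t_max) if t_max > 0 else math.nan
    return EmissionFit(
        trial_id=trial.trial_id, analyte=trial.analyte,
        ef0=ef0_hat, ef_ss=efss_hat, k=k_hat,
        air_exchange=n_air, loading=loading,
        c_max=c_max, t_max=t_max, ef_max=efmax_hat, ef_buildup=efb_hat,
        sse=sse, converged=True, boundary_max=boundary,
        n_starts_converged=n_converged,
        roast_level=trial.roast_level, physical_form=trial.physical_form,
    )
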