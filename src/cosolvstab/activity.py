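"""Initial-rate extraction and activity-solvent model fitting.

Specific initial activities are computed from the linear phase of NAD(P)H
depletion followed at 340 nm: the slope of the best linear window of the
absorbance trace is converted to a molar rate through Lambert-Beer's law
and normalised by the enzyme mass concentration. Activity-versus-solvent
profiles are then fitted with the Gaussian-boost + logistic-decay model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import (
    R_GAS,
    ActivityModelParams,
    celsius_to_kelvin,
    eval_activity,
)

__all__ = [
    "KineticTrace",
    "ActivityPoint",
    "ActivityFit",
    "ActivityFitOptions",
    "InitialRate",
    "initial_rate",
    "relative_activity",
    "fit_activity_model",
    "NoLinearRangeError",
    "DEFAULT_EXTINCTION_NADPH",
]

#: Molar extinction coefficient of NAD(P)H at 340 nm, M^-1 cm^-1.
#: A standard literature value, used as the default and overridable
#: everywhere an extinction coefficient is accepted.
DEFAULT_EXTINCTION_NADPH = 6220.0


class NoLinearRangeError(RuntimeError):
    """No window of the kinetic trace meets the linearity criterion."""


@dataclass(frozen=True)
class KineticTrace:
    """A340 time course of one well."""

    enzyme: str
    solvent: str
    c_solv: float
    temperature_c: float
    times: np.ndarray
    a340: np.ndarray
    enzyme_conc: float  # mg ml^-1
    path_length: float  # cm
    extinction_coeff: float = DEFAULT_EXTINCTION_NADPH  # M^-1 cm^-1

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.a340, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "a340", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise ValueError("times and a340 must be 1-D and equally long")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be > 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")
        if self.extinction_coeff <= 0:
            raise ValueError("extinction_coeff must be > 0")


@dataclass(frozen=True)
class InitialRate:
    """Specific initial activity and the window it was read from."""

    specific_activity: float  # µmol min^-1 mg^-1
    slope: float  # A s^-1, signed
    window: tuple[int, int]  # [start, stop) indices into the trace
    r_squared: float
    increasing: bool  # absorbance rising instead of falling


def _linreg(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of an ordinary least-squares line.

    A perfectly flat trace has zero total variance; it is a perfect fit of
    a zero-slope line, so R^2 is reported as 1.
    """
    if np.ptp(y) == 0:  # flat trace: perfect zero-slope fit
        return 0.0, float(y[0]), 1.0
    slope, intercept = np.polyfit(t, y, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def initial_rate(
    trace: KineticTrace,
    min_r_squared: float = 0.99,
    min_window_fraction: float = 0.3,
    dead_time_s: float = 0.0,
) -> InitialRate:
    """Specific initial activity from the best linear window of a trace.

    A sliding-window search maximises the window length subject to
    R^2 >= ``min_r_squared`` and window >= ``min_window_fraction`` of the
    trace (after discarding ``dead_time_s``); among equally long windows
    the earliest wins. The slope (A s^-1) is converted via Lambert-Beer to
    a molar rate |slope| / (epsilon * l) and then to
    µmol min^-1 per mg enzyme. A rising absorbance is flagged but its
    magnitude still reported.
    """
    live = trace.times >= dead_time_s
    t = trace.times[live]
    y = trace.a340[live]
    n = t.size
    if n < 5:
        raise ValueError("need >= 5 points after the dead time")
    min_len = max(5, int(math.ceil(min_window_fraction * n)))

    chosen = None
    for length in range(n, min_len - 1, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            slope, _, r2 = _linreg(t[sl], y[sl])
            if r2 >= min_r_squared:
                chosen = (start, start + length, slope, r2)
                break
        if chosen:
            break
    if chosen is None:
        raise NoLinearRangeError(
            f"no window of >= {min_len} points reaches R^2 >= {min_r_squared}"
        )
    start, stop, slope, r2 = chosen
    rate_molar = abs(slope) / (trace.extinction_coeff * trace.path_length)  # mol L^-1 s^-1
    # mol/L/s -> µmol/L/min, then per mg/L of enzyme (mg/ml * 1000)
    specific = rate_molar * 1e6 * 60.0 / (trace.enzyme_conc * 1000.0)
    return InitialRate(
        specific_activity=float(specific),
        slope=slope,
        window=(start, stop),
        r_squared=r2,
        increasing=slope > 0,
    )


@dataclass(frozen=True)
class ActivityPoint:
    """One (concentration, activity) measurement with replicate statistics."""

    c_solv: float
    temperature_c: float
    specific_activity: float  # µmol min^-1 mg^-1 (or relative %, unit-agnostic)
    sem: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.c_solv < 0:
            raise ValueError("c_solv must be >= 0")
        if self.specific_activity < 0:
            raise ValueError("specific_activity must be >= 0")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def relative_activity(
    points: Sequence[ActivityPoint], reference: ActivityPoint | None = None
) -> list[ActivityPoint]:
    """Normalise activities so the co-solvent-free point reads 100 %.

    The reference defaults to the point at c_solv = 0. SEMs are propagated
    with first-order Gaussian error propagation:
    sem_rel = rel * sqrt((sem/a)^2 + (sem_ref/a_ref)^2). Values above 100
    indicate activity boosted beyond the aqueous condition.
    """
    if reference is None:
        zeros = [p for p in points if p.c_solv == 0]
        if not zeros:
            raise ValueError("no reference point at c_solv = 0")
        reference = zeros[0]
    a_ref = reference.specific_activity
    if a_ref <= 0:
        raise ValueError("reference activity must be > 0")
    out = []
    for p in points:
        rel = 100.0 * p.specific_activity / a_ref
        if p.specific_activity > 0:
            sem = rel * math.sqrt(
                (p.sem / p.specific_activity) ** 2 + (reference.sem / a_ref) ** 2
            )
        else:
            sem = 100.0 * p.sem / a_ref
        out.append(
            ActivityPoint(
                c_solv=p.c_solv,
                temperature_c=p.temperature_c,
                specific_activity=rel,
                sem=sem,
                n_replicates=p.n_replicates,
            )
        )
    return out


@dataclass(frozen=True)
class ActivityFitOptions:
    """Options for the activity-solvent model fit.

    The L2 penalty weights apply to the raw (unscaled) parameter values;
    set ``regularization=False`` to fit by plain least squares, e.g. for
    parameter-recovery studies.
    """

    regularization: bool = True
    lambda_c_a_max: float = 0.01
    lambda_xi: float = 0.001
    sigma_lower: float = 10.0
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 4000
    ca50_start_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class ActivityFit:
    params: ActivityModelParams
    cost: float
    converged: bool
    n_points: int


def _activity_residuals(z, m_scale, c, y, t_k, opts: ActivityFitOptions):
    xi, nu, sigma, c_a_max, c_a50, m_scaled = z
    p = ActivityModelParams(
        xi=xi, nu=nu, sigma=max(sigma, opts.sigma_lower),
        c_a_max=min(c_a_max, 100.0), c_a50=min(c_a50, 100.0),
        m_folding=m_scaled * m_scale, temperature_k=t_k,
    )
    resid = eval_activity(p, c) - y
    if opts.regularization:
        penalty = np.array(
            [math.sqrt(opts.lambda_c_a_max) * c_a_max, math.sqrt(opts.lambda_xi) * xi]
        )
        return np.concatenate([resid, penalty])
    return resid


def fit_activity_model(
    points: Sequence[ActivityPoint], options: ActivityFitOptions | None = None
) -> ActivityFit:
    """Fit the activity-solvent model to a fixed-temperature profile.

    Minimises sum((model - observed)^2) plus, when regularisation is on,
    0.01 * c_a_max^2 + 0.001 * xi^2 (raw parameter values), over
    (xi, nu, sigma, c_a_max, c_a50, m_folding) with xi, nu, c_a_max,
    c_a50 >= 0, sigma >= 10, c_a_max and c_a50 <= 100; m_folding is
    unbounded and rescaled to order one before optimisation.

    Deterministic multi-start: c_a50 at fixed fractions of the largest
    concentration, c_a_max at the argmax of the observed activity, nu at
    the activity nearest c = 0, xi at 0 and at (peak - baseline) * sigma *
    sqrt(2*pi). Lowest cost wins; ties go to the earliest start.
    """
    opts = options or ActivityFitOptions()
    if len(points) < 6:
        raise ValueError(f"need >= 6 concentration points, got {len(points)}")
    temps = {p.temperature_c for p in points}
    if len(temps) != 1:
        raise ValueError(f"points mix temperatures: {sorted(temps)}")
    pts = sorted(points, key=lambda p: p.c_solv)
    c = np.array([p.c_solv for p in pts])
    y = np.array([p.specific_activity for p in pts])
    t_k = celsius_to_kelvin(pts[0].temperature_c)

    c_range = float(c.max() - c.min()) or 1.0
    m_scale = R_GAS * t_k / c_range

    nu0 = max(float(y[0]), 1e-6)
    c_a_max0 = float(np.clip(c[int(np.argmax(y))], 0.0, 100.0))
    sigma0 = max(opts.sigma_lower, c_range / 4.0)
    boost = max(float(y.max()) - nu0, 0.0)
    xi_starts = (0.0, boost * sigma0 * math.sqrt(2.0 * math.pi))
    m0 = math.log(81.0) * R_GAS * t_k / (0.25 * c_range) / m_scale

    lower = np.array([0.0, 0.0, opts.sigma_lower, 0.0, 0.0, -np.inf])
    upper = np.array([np.inf, np.inf, np.inf, 100.0, 100.0, np.inf])
    best = None
    for frac in opts.ca50_start_fractions:
        for xi0 in xi_starts:
            z0 = np.array([xi0, nu0, sigma0, c_a_max0, frac * float(c.max()), m0])
            z0 = np.clip(z0, lower, upper)
            try:
                res = least_squares(
                    _activity_residuals, z0, bounds=(lower, upper),
                    args=(m_scale, c, y, t_k, opts),
                    xtol=opts.xtol, ftol=opts.ftol, gtol=opts.gtol,
                    max_nfev=opts.max_nfev, method="trf",
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-15:
                best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    xi, nu, sigma, c_a_max, c_a50, m_scaled = best.x
    params = ActivityModelParams(
        xi=xi, nu=nu, sigma=max(sigma, opts.sigma_lower),
        c_a_max=min(c_a_max, 100.0), c_a50=min(c_a50, 100.0),
        m_folding=m_scaled * m_scale, temperature_k=t_k,
    )
    return ActivityFit(
        params=params,
        cost=float(2.0 * best.cost),
        converged=bool(best.success),
        n_points=len(pts),
    )
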