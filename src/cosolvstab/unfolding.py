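"""Thermal-ramp analysis and isothermal c_U50 fitting.

A thermal ramp records a fluorescence signal (nanoDSF F350/330 ratio or
single-channel FMN fluorescence) while the sample is heated. Two analyses
are supported:

* melting temperature extraction: the inflection point of the (smoothed)
  melt curve, read as the temperature of maximum absolute first derivative;
* isothermal slicing: reading the signal at one fixed temperature across
  ramps recorded at different co-solvent concentrations yields a
  concentration-resolved unfolding curve, to which the extended two-state
  model is fitted, giving the half-unfolding concentration c_U50 at that
  temperature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

from .models import (
    R_GAS,
    UnfoldingModelParams,
    celsius_to_kelvin,
    eval_unfolding_signal,
)

__all__ = [
    "ThermalRamp",
    "TmResult",
    "IsothermalSlice",
    "UnfoldingFit",
    "FitOptions",
    "extract_tm",
    "build_isothermal_slice",
    "fit_unfolding",
    "cu50_vs_temperature",
    "NoTransitionError",
]

CHANNELS = ("ratio_350_330", "fmn_fluorescence")


class NoTransitionError(RuntimeError):
    """The melt curve shows no detectable unfolding transition."""


@dataclass(frozen=True)
class ThermalRamp:
    """One heating experiment at a fixed co-solvent condition."""

    enzyme: str
    solvent: str
    c_solv: float
    channel: str
    temperatures: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", s)
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("temperatures and signal must be 1-D and equally long")
        if t.size < 10:
            raise ValueError(f"a ramp needs >= 10 points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal must be finite")
        if self.c_solv < 0:
            raise ValueError("c_solv must be >= 0")


@dataclass(frozen=True)
class TmResult:
    """Melting temperature with boundary/uncertainty flags.

    ``tm_c`` is the temperature of maximum |dS/dT|. When that maximum sits
    on the first or last sample of the ramp the true midpoint lies outside
    the scanned range; ``at_boundary`` is set and ``bound`` holds the
    inequality (e.g. "> 90.0 °C") while ``tm_c`` keeps the numeric sentinel.
    """

    tm_c: float
    at_boundary: bool = False
    bound: str | None = None


def extract_tm(
    ramp: ThermalRamp,
    smoothing_window: int = 7,
    min_amplitude_ratio: float = 3.0,
) -> TmResult:
    """Melting temperature as the inflection point of the melt curve.

    The signal is smoothed with a quadratic Savitzky-Golay filter over
    ``smoothing_window`` points (odd), differentiated against temperature,
    and the temperature of maximum absolute derivative returned. A
    transition is only accepted when the derivative peak clearly stands
    out above the baseline drift: peak |dS/dT| must exceed
    ``min_amplitude_ratio`` times the median |dS/dT|. A purely linear or
    flat trace therefore raises :class:`NoTransitionError`.
    """
    if smoothing_window % 2 == 0 or smoothing_window < 5:
        raise ValueError("smoothing_window must be odd and >= 5")
    t = ramp.temperatures
    s = ramp.signal
    window = min(smoothing_window, t.size if t.size % 2 == 1 else t.size - 1)
    smoothed = savgol_filter(s, window_length=window, polyorder=2)
    deriv = np.gradient(smoothed, t)
    mag = np.abs(deriv)
    peak = float(mag.max())
    baseline = float(np.median(mag))
    # flat curve: amplitude indistinguishable from floating-point noise
    amplitude_floor = 1e-9 * max(1.0, float(np.abs(s).max()))
    if peak <= 0 or np.ptp(smoothed) <= amplitude_floor:
        raise NoTransitionError("signal is flat: no transition detected")
    if peak < min_amplitude_ratio * baseline:
        raise NoTransitionError(
            "derivative peak does not stand out above baseline drift: "
            "no transition detected"
        )
    idx = int(mag.argmax())
    tm = float(t[idx])
    if idx == 0:
        return TmResult(tm_c=tm, at_boundary=True, bound=f"< {tm:g} °C")
    if idx == t.size - 1:
        return TmResult(tm_c=tm, at_boundary=True, bound=f"> {tm:g} °C")
    return TmResult(tm_c=tm)


@dataclass(frozen=True)
class IsothermalSlice:
    """Signal versus co-solvent concentration at one fixed temperature."""

    enzyme: str
    solvent: str
    temperature_c: float
    c_solv: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.c_solv, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        order = np.argsort(c)
        c, s = c[order], s[order]
        object.__setattr__(self, "c_solv", c)
        object.__setattr__(self, "signal", s)
        if c.size < 6:
            raise ValueError(f"an isothermal slice needs >= 6 points, got {c.size}")
        if np.any(c < 0):
            raise ValueError("c_solv must be >= 0")
        if np.unique(c).size != c.size:
            raise ValueError("c_solv values must be distinct")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal must be finite")

    @property
    def n_points(self) -> int:
        return int(self.c_solv.size)


def build_isothermal_slice(
    ramps: Sequence[ThermalRamp], temperature_c: float
) -> IsothermalSlice:
    """Read the signal of each ramp at one temperature by linear interpolation.

    All ramps must share enzyme, solvent and channel, differ in co-solvent
    concentration, and cover the requested temperature.
    """
    if not ramps:
        raise ValueError("no ramps given")
    keys = {(r.enzyme, r.solvent, r.channel) for r in ramps}
    if len(keys) != 1:
        raise ValueError(f"ramps mix conditions: {sorted(keys)}")
    concs = [r.c_solv for r in ramps]
    if len(set(concs)) != len(concs):
        raise ValueError("duplicate c_solv among ramps: ambiguous condition")
    points = []
    for r in ramps:
        if not (r.temperatures[0] <= temperature_c <= r.temperatures[-1]):
            raise ValueError(
                f"temperature {temperature_c} °C outside ramp range "
                f"[{r.temperatures[0]}, {r.temperatures[-1]}] for "
                f"{r.enzyme}/{r.solvent} at {r.c_solv} %(v/v)"
            )
        points.append((r.c_solv, float(np.interp(temperature_c, r.temperatures, r.signal))))
    points.sort()
    enzyme, solvent, _ = next(iter(keys))
    c, s = zip(*points)
    return IsothermalSlice(
        enzyme=enzyme,
        solvent=solvent,
        temperature_c=temperature_c,
        c_solv=np.array(c),
        signal=np.array(s),
    )


@dataclass(frozen=True)
class FitOptions:
    """Options controlling the bounded least-squares fits.

    ``analyzable_fraction``: minimal transition amplitude (evaluated at the
    fitted midpoint) as a fraction of the observed signal range for a fit
    to count as an analyzable unfolding curve.
    """

    analyzable_fraction: float = 0.2
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 2000
    cu50_start_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)


@dataclass(frozen=True)
class UnfoldingFit:
    params: UnfoldingModelParams
    residual_sum_squares: float
    converged: bool
    analyzable: bool
    n_points: int

    @property
    def c_u50(self) -> float | None:
        """Half-unfolding concentration; only reported for analyzable fits."""
        return self.params.c_u50 if self.analyzable else None


def _unfolding_residuals(z, scales, c, y, temperature_k):
    a_f, b_f, a_u, b_u, m, cu = z * scales
    p = UnfoldingModelParams(
        alpha_f=a_f, beta_f=b_f, alpha_u=a_u, beta_u=b_u,
        m_folding=m, c_u50=min(cu, 100.0), temperature_k=temperature_k,
    )
    return eval_unfolding_signal(p, c) - y


def fit_unfolding(slc: IsothermalSlice, options: FitOptions | None = None) -> UnfoldingFit:
    """Fit the extended two-state model to an isothermal unfolding curve.

    Sum-of-squares cost over the six model parameters, all bounded below by
    zero and c_u50 additionally bounded above by 100 %(v/v). Parameters are
    rescaled to order one before optimisation (signal range for the
    baseline terms, RT/c-range for m_folding, c-range for c_u50).
    Deterministic multi-start: c_u50 is started at fixed fractions of the
    largest observed concentration, the baselines at straight lines through
    the first/last two points, and m_folding at a logistic-slope heuristic;
    the lowest-cost solution wins, ties going to the earliest start.
    """
    opts = options or FitOptions()
    c = slc.c_solv
    y = slc.signal
    t_k = celsius_to_kelvin(slc.temperature_c)

    c_range = float(c.max() - c.min()) or 1.0
    sig_scale = float(np.ptp(y)) or max(abs(float(np.mean(y))), 1.0)
    # characteristic scales keeping all optimizer variables O(1)
    scales = np.array([
        max(abs(float(y[0])), sig_scale),      # alpha_f
        sig_scale / c_range,                   # beta_f
        max(abs(float(y[-1])), sig_scale),     # alpha_u
        sig_scale / c_range,                   # beta_u
        R_GAS * t_k / c_range,                 # m_folding
        c_range,                               # c_u50
    ])

    # baseline starts from the first/last two points, clipped into bounds
    def _line(ci, yi):
        slope = (yi[1] - yi[0]) / (ci[1] - ci[0])
        intercept = yi[0] - slope * ci[0]
        return max(intercept, 0.0), max(slope, 0.0)

    a_f0, b_f0 = _line(c[:2], y[:2])
    a_u0, b_u0 = _line(c[-2:], y[-2:])
    # m heuristic: 10-90% transition spanning a quarter of the grid
    m0 = R_GAS * t_k * np.log(81.0) / (0.25 * c_range)

    lower = np.zeros(6)
    upper = np.array([np.inf, np.inf, np.inf, np.inf, np.inf, 100.0]) / scales
    best = None
    best_start = -1
    for i, frac in enumerate(opts.cu50_start_fractions):
        cu0 = frac * float(c.max())
        z0 = np.array([a_f0, b_f0, a_u0, b_u0, m0, cu0]) / scales
        z0 = np.clip(z0, lower + 1e-12, upper)
        try:
            res = least_squares(
                _unfolding_residuals, z0, bounds=(lower, upper),
                args=(scales, c, y, t_k),
                xtol=opts.xtol, ftol=opts.ftol, gtol=opts.gtol,
                max_nfev=opts.max_nfev, method="trf",
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
            best_start = i
    if best is None:
        raise RuntimeError("all optimizer starts failed")

    a_f, b_f, a_u, b_u, m, cu = best.x * scales
    params = UnfoldingModelParams(
        alpha_f=a_f, beta_f=b_f, alpha_u=a_u, beta_u=b_u,
        m_folding=m, c_u50=min(cu, 100.0), temperature_k=t_k,
    )
    rss = float(2.0 * best.cost)
    converged = bool(best.success)

    # a fit is analyzable only when it actually resolves a transition:
    # baseline separation at the fitted midpoint versus observed range
    mid = params.c_u50
    amplitude = abs(
        (params.alpha_u + params.beta_u * mid) - (params.alpha_f + params.beta_f * mid)
    )
    observed_range = float(np.ptp(y))
    analyzable = bool(
        converged
        and observed_range > 0
        and amplitude >= opts.analyzable_fraction * observed_range
    )
    del best_start  # tie-break bookkeeping only
    return UnfoldingFit(
        params=params,
        residual_sum_squares=rss,
        converged=converged,
        analyzable=analyzable,
        n_points=slc.n_points,
    )


def cu50_vs_temperature(fits: Sequence[UnfoldingFit]) -> list[tuple[float, float]]:
    """Tabulate (temperature_C, c_u50) from analyzable converged fits.

    Sorted by temperature; monotonicity is reported as observed, never
    enforced. This table is the boundary of the operating window.
    """
    if not fits:
        raise ValueError("no fits given")
    rows = []
    for f in fits:
        if not (f.converged and f.analyzable):
            raise ValueError("all fits must be converged and analyzable")
        rows.append((f.params.temperature_c, f.params.c_u50))
    rows.sort()
    return rows
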