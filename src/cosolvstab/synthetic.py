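"""Synthetic data generation with the statistical structure the models assume.

Generates the three raw data shapes the fitters consume — thermal ramps,
isothermal unfolding slices and activity profiles, plus kinetic A340
traces — from known ("true") parameters, with seeded Gaussian noise, so
every analysis stage can be exercised and parameter recovery verified
without instrument data.

Defaults mirror the experimental design the models were built for:
concentrations span 0-45 % (v/v) on a 2.5 % grid, ramps run 20-90 °C,
activity points carry three replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .activity import ActivityPoint, KineticTrace, DEFAULT_EXTINCTION_NADPH
from .models import (
    ActivityModelParams,
    UnfoldingModelParams,
    eval_activity,
    eval_unfolding_signal,
)
from .unfolding import IsothermalSlice, ThermalRamp

__all__ = [
    "NoiseSpec",
    "ScenarioSpec",
    "DEFAULT_CONC_GRID",
    "generate_isothermal_slice",
    "generate_activity_profile",
    "generate_thermal_ramp",
    "generate_kinetic_trace",
]

#: 0-45 % (v/v) in 2.5 % steps: 19 concentrations.
DEFAULT_CONC_GRID = tuple(np.arange(0.0, 45.0 + 1e-9, 2.5))


@dataclass(frozen=True)
class NoiseSpec:
    """Seeded Gaussian measurement noise.

    ``sd`` is either an absolute standard deviation in signal units or,
    when ``relative_to_amplitude`` is set, a fraction of the generating
    curve's amplitude (max - min of the noise-free values). The same seed
    and parameters always reproduce the identical dataset.
    """

    sd: float = 0.0
    relative_to_amplitude: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def absolute_sd(self, clean: np.ndarray) -> float:
        if not self.relative_to_amplitude:
            return self.sd
        return self.sd * float(np.ptp(clean))


_NO_NOISE = NoiseSpec()


def generate_isothermal_slice(
    params: UnfoldingModelParams,
    conc_grid=DEFAULT_CONC_GRID,
    noise: NoiseSpec = _NO_NOISE,
    enzyme: str = "synthetic",
    solvent: str = "synthetic",
) -> IsothermalSlice:
    """Unfolding curve versus co-solvent concentration from known truths."""
    c = np.asarray(conc_grid, dtype=float)
    clean = np.asarray(eval_unfolding_signal(params, c), dtype=float)
    sd = noise.absolute_sd(clean)
    signal = clean + noise.rng().normal(0.0, sd, size=clean.shape) if sd > 0 else clean
    return IsothermalSlice(
        enzyme=enzyme,
        solvent=solvent,
        temperature_c=params.temperature_c,
        c_solv=c,
        signal=signal,
    )


def generate_activity_profile(
    params: ActivityModelParams,
    conc_grid=DEFAULT_CONC_GRID,
    noise: NoiseSpec = _NO_NOISE,
    n_replicates: int = 3,
) -> list[ActivityPoint]:
    """Activity profile with per-concentration replicate noise.

    Each concentration receives ``n_replicates`` noisy draws around the
    model value; the point carries their mean and standard error. Noisy
    means are clipped at zero (an assay cannot report negative activity).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    c = np.asarray(conc_grid, dtype=float)
    clean = np.asarray(eval_activity(params, c), dtype=float)
    sd = noise.absolute_sd(clean)
    rng = noise.rng()
    points = []
    for ci, mu in zip(c, clean):
        if sd > 0 and n_replicates >= 1:
            draws = mu + rng.normal(0.0, sd, size=n_replicates)
            mean = max(float(draws.mean()), 0.0)
            sem = float(draws.std(ddof=1) / math.sqrt(n_replicates)) if n_replicates > 1 else 0.0
        else:
            mean, sem = max(float(mu), 0.0), 0.0
        points.append(
            ActivityPoint(
                c_solv=float(ci),
                temperature_c=params.temperature_c,
                specific_activity=mean,
                sem=sem,
                n_replicates=n_replicates,
            )
        )
    return points


def generate_thermal_ramp(
    tm_c: float,
    transition_width: float = 2.0,
    baseline_folded: tuple[float, float] = (0.85, 0.0),
    baseline_unfolded: tuple[float, float] = (1.05, 0.0),
    noise: NoiseSpec = _NO_NOISE,
    t_min: float = 20.0,
    t_max: float = 90.0,
    step: float = 0.5,
    enzyme: str = "synthetic",
    solvent: str = "none",
    c_solv: float = 0.0,
    channel: str = "ratio_350_330",
) -> ThermalRamp:
    """Melt curve: logistic transition in temperature over linear baselines.

    The constant-rate heating of the instrument is emulated as a uniform
    temperature grid. ``tm_c`` may lie outside [t_min, t_max] (20-120 °C
    is deliberately representable) to produce boundary cases. Baselines
    are (intercept, slope-per-°C) pairs, anchored at t_min. With equal
    baselines the curve carries no transition at all.
    """
    if not (20.0 <= tm_c <= 120.0):
        raise ValueError("tm_c must be within 20-120 °C")
    if transition_width <= 0:
        raise ValueError("transition_width must be > 0")
    t = np.arange(t_min, t_max + step / 2, step)
    f = 1.0 / (1.0 + np.exp(-(t - tm_c) / transition_width))
    lo = baseline_folded[0] + baseline_folded[1] * (t - t_min)
    hi = baseline_unfolded[0] + baseline_unfolded[1] * (t - t_min)
    clean = (1.0 - f) * lo + f * hi
    sd = noise.absolute_sd(clean)
    signal = clean + noise.rng().normal(0.0, sd, size=clean.shape) if sd > 0 else clean
    return ThermalRamp(
        enzyme=enzyme,
        solvent=solvent,
        c_solv=c_solv,
        channel=channel,
        temperatures=t,
        signal=signal,
    )


def generate_kinetic_trace(
    true_rate: float,
    enzyme_conc: float = 0.01,
    extinction_coeff: float = DEFAULT_EXTINCTION_NADPH,
    path_length: float = 0.5,
    duration_s: float = 240.0,
    n_points: int = 49,
    a0: float = 0.62,
    curvature_tau_s: float | None = None,
    noise: NoiseSpec = _NO_NOISE,
    enzyme: str = "synthetic",
    solvent: str = "none",
    c_solv: float = 0.0,
    temperature_c: float = 25.0,
) -> KineticTrace:
    """A340 depletion trace whose initial slope encodes a known rate.

    ``true_rate`` is the specific activity in µmol min^-1 mg^-1; the
    Lambert-Beer chain is inverted to get the absorbance slope. With
    ``curvature_tau_s`` set, the decay turns exponential with that time
    constant after half the trace, so linear-range selection has a curved
    tail to avoid. Absorbance is floored at zero (substrate depletion).
    """
    if true_rate < 0:
        raise ValueError("true_rate must be >= 0")
    t = np.linspace(0.0, duration_s, n_points)
    rate_molar = true_rate * enzyme_conc * 1000.0 / (1e6 * 60.0)  # mol L^-1 s^-1
    slope = -extinction_coeff * path_length * rate_molar  # A s^-1
    a = a0 + slope * t
    if curvature_tau_s is not None:
        t_knee = duration_s / 2.0
        tail = t > t_knee
        a_knee = a0 + slope * t_knee
        a[tail] = a_knee + slope * curvature_tau_s * (
            1.0 - np.exp(-(t[tail] - t_knee) / curvature_tau_s)
        )
    a = np.maximum(a, 0.0)
    sd = noise.absolute_sd(a)
    if sd > 0:
        a = a + noise.rng().normal(0.0, sd, size=a.shape)
    return KineticTrace(
        enzyme=enzyme,
        solvent=solvent,
        c_solv=c_solv,
        temperature_c=temperature_c,
        times=t,
        a340=a,
        enzyme_conc=enzyme_conc,
        path_length=path_length,
        extinction_coeff=extinction_coeff,
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """A full synthetic study: one enzyme/solvent over a temperature grid.

    The true half-unfolding concentration decreases linearly with
    temperature (``cu50_slope_per_c`` %(v/v) per °C, negative by default),
    emulating the observation that hotter conditions unfold at lower
    co-solvent concentrations. Activity truths reuse the unfolding
    midpoint for c_a50 shifted by ``ca50_offset``.
    """

    enzyme: str = "synthetic"
    solvent: str = "ethanol"
    temperatures_c: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0, 45.0)
    conc_grid: tuple[float, ...] = DEFAULT_CONC_GRID
    cu50_at_25c: float = 30.0
    cu50_slope_per_c: float = -0.6
    m_folding: float = 1500.0
    alpha_f: float = 0.85
    beta_f: float = 0.0005
    alpha_u: float = 1.05
    beta_u: float = 0.002
    nu: float = 100.0
    xi: float = 800.0
    sigma: float = 10.0
    c_a_max: float = 7.5
    ca50_offset: float = -2.0
    n_replicates: int = 3
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if not self.temperatures_c or not self.conc_grid:
            raise ValueError("temperature and concentration grids must be nonempty")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def true_cu50(self, temperature_c: float) -> float:
        return self.cu50_at_25c + self.cu50_slope_per_c * (temperature_c - 25.0)

    def unfolding_params(self, temperature_c: float) -> UnfoldingModelParams:
        return UnfoldingModelParams.from_celsius(
            alpha_f=self.alpha_f, beta_f=self.beta_f,
            alpha_u=self.alpha_u, beta_u=self.beta_u,
            m_folding=self.m_folding,
            c_u50=self.true_cu50(temperature_c),
            temperature_c=temperature_c,
        )

    def activity_params(self, temperature_c: float) -> ActivityModelParams:
        return ActivityModelParams.from_celsius(
            xi=self.xi, nu=self.nu, sigma=self.sigma,
            c_a_max=self.c_a_max,
            c_a50=max(self.true_cu50(temperature_c) + self.ca50_offset, 0.0),
            m_folding=self.m_folding,
            temperature_c=temperature_c,
        )

    def _noise_for(self, offset: int) -> NoiseSpec:
        return replace(self.noise, seed=self.noise.seed + offset)

    def generate_slices(self) -> list[IsothermalSlice]:
        return [
            generate_isothermal_slice(
                self.unfolding_params(t), self.conc_grid,
                noise=self._noise_for(i),
                enzyme=self.enzyme, solvent=self.solvent,
            )
            for i, t in enumerate(self.temperatures_c)
        ]

    def generate_ramps(
        self, t_min: float = 20.0, t_max: float = 90.0, step: float = 1.0
    ) -> list[ThermalRamp]:
        """One thermal ramp per concentration, consistent with the slices.

        The signal at every (c, T) sample follows the unfolding model with
        the temperature-dependent half-unfolding concentration (clipped at
        zero once the linear trend would turn negative), so slicing the
        ramps at any temperature reproduces the model's isothermal curve.
        """
        temps = np.arange(t_min, t_max + step / 2, step)
        rng = self.noise.rng()
        ramps = []
        for c in self.conc_grid:
            clean = np.array([
                eval_unfolding_signal(
                    UnfoldingModelParams.from_celsius(
                        alpha_f=self.alpha_f, beta_f=self.beta_f,
                        alpha_u=self.alpha_u, beta_u=self.beta_u,
                        m_folding=self.m_folding,
                        c_u50=min(max(self.true_cu50(t), 0.0), 100.0),
                        temperature_c=t,
                    ),
                    c,
                )
                for t in temps
            ])
            sd = self.noise.absolute_sd(clean)
            signal = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean
            ramps.append(
                ThermalRamp(
                    enzyme=self.enzyme, solvent=self.solvent, c_solv=float(c),
                    channel="ratio_350_330", temperatures=temps, signal=signal,
                )
            )
        return ramps

    def generate_activity_profiles(self) -> dict[float, list[ActivityPoint]]:
        return {
            t: generate_activity_profile(
                self.activity_params(t), self.conc_grid,
                noise=self._noise_for(1000 + i),
                n_replicates=self.n_replicates,
            )
            for i, t in enumerate(self.temperatures_c)
        }
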